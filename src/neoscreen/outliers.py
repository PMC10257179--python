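"""Iterative rank-based exclusion of outlier litters among control animals.

Litters share a dam and environment, so a litter-level shock can drag every
control pup in it up or down together and bias the pooled control estimate.
The procedure guards against this with a four-step loop on the control arm:

1. Kruskal-Wallis test across litters; stop if the distributions are not
   detectably different (p above the gate level).
2. Pick the most deviant litter j — the one whose average midrank is farthest
   from the overall mean rank (n+1)/2 — and form the contrast
   c_j = -1, c_i = 1/(K-1) otherwise, giving the statistic
   T = (sum_i c_i Rbar_i / SE)^2 with SE = sqrt(n(n+1)/12 * sum_i c_i^2/n_i).
3. Permutation test: reshuffle the pooled observations over the litter sizes
   many times, recompute T (re-selecting the deviant litter each time), and
   take p = fraction of permuted T strictly exceeding the observed T.
4. If p is below the exclusion level, drop litter j entirely and repeat.

All statistics are rank-based (midranks under ties), hence invariant under
strictly monotone transformations of the outcome.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class DegenerateInputError(ValueError):
    pass


class CapacityError(ValueError):
    pass


@dataclass(frozen=True)
class RankSummary:
    """Per-litter midrank summary of a pooled control sample."""

    labels: tuple[str, ...]
    sizes: tuple[int, ...]  # n_i
    mean_ranks: tuple[float, ...]  # Rbar_i
    n: int

    @classmethod
    def from_values(cls, values_by_litter: dict[str, np.ndarray]) -> "RankSummary":
        labels = tuple(sorted(values_by_litter))
        if len(labels) < 2:
            raise DegenerateInputError("need at least 2 litters")
        arrays = [np.asarray(values_by_litter[l], dtype=float) for l in labels]
        if any(a.size == 0 for a in arrays):
            raise DegenerateInputError("every litter must be non-empty")
        pooled = np.concatenate(arrays)
        ranks = stats.rankdata(pooled)  # midranks
        sizes = tuple(int(a.size) for a in arrays)
        out, pos = [], 0
        for s in sizes:
            out.append(float(ranks[pos : pos + s].mean()))
            pos += s
        return cls(labels, sizes, tuple(out), int(pooled.size))


def kruskal_wallis(values_by_litter: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across litters."""
    groups = [np.asarray(v, dtype=float) for _, v in sorted(values_by_litter.items())]
    if len(groups) < 2:
        raise DegenerateInputError("Kruskal-Wallis needs at least 2 litters")
    if any(g.size == 0 for g in groups):
        raise DegenerateInputError("every litter must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def most_deviant_litter(summary: RankSummary, one_sided: bool = False) -> str:
    """Label of the litter whose mean rank deviates most from (n+1)/2.

    By default the absolute deviation is maximised, catching abnormally low
    as well as abnormally high litters; ``one_sided=True`` maximises the
    signed deviation (high litters only). Ties break toward the larger
    litter, then the lexicographically smallest label.
    """
    centre = (summary.n + 1) / 2.0
    dev = np.asarray(summary.mean_ranks) - centre
    key = dev if one_sided else np.abs(dev)
    best = key.max()
    cand = [i for i in range(len(summary.labels)) if key[i] >= best - 1e-9]
    cand.sort(key=lambda i: (-summary.sizes[i], summary.labels[i]))
    return summary.labels[cand[0]]


@dataclass(frozen=True)
class ContrastResult:
    deviant_litter: str
    contrasts: tuple[float, ...]
    numerator: float  # sum_i c_i * Rbar_i
    se: float
    statistic: float  # T


def contrast_statistic(summary: RankSummary, j: str) -> ContrastResult:
    """Distance of litter ``j`` from the rest on the rank scale.

    T = (sum_i c_i Rbar_i / SE)^2 with c_j = -1, c_i = 1/(K-1) otherwise and
    SE = sqrt(n(n+1)/12 * sum_i c_i^2 / n_i). For K = 2 this is algebraically
    the Kruskal-Wallis H (absent ties).
    """
    if j not in summary.labels:
        raise KeyError(f"unknown litter {j!r}")
    k = len(summary.labels)
    jdx = summary.labels.index(j)
    c = np.full(k, 1.0 / (k - 1))
    c[jdx] = -1.0
    n = summary.n
    se2 = n * (n + 1) / 12.0 * np.sum(c**2 / np.asarray(summary.sizes, dtype=float))
    if se2 <= 0:
        raise DegenerateInputError("zero standard error")
    num = float(np.dot(c, summary.mean_ranks))
    se = math.sqrt(se2)
    return ContrastResult(j, tuple(c), num, se, (num / se) ** 2)


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_perm: int
    p_value: float
    mode: str  # random | exhaustive
    tie_fraction: float  # permuted T within tolerance of observed T
    degenerate: bool  # all permuted T tie with the observed T


def _stat_for_ranks(
    rank_matrix: np.ndarray, sizes: np.ndarray, one_sided: bool, frozen_j: int | None
) -> np.ndarray:
    """Step-2 statistic for each row of permuted midranks (vectorised).

    ``rank_matrix`` has one permutation per row; columns 0..n_1-1 belong to
    litter 1, the next n_2 to litter 2, and so on. Tie-breaks in the deviant-
    litter selection fall back to a per-row pass on the rare tied rows.
    """
    n = rank_matrix.shape[1]
    k = sizes.size
    bounds = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    rbar = np.stack(
        [rank_matrix[:, bounds[i] : bounds[i + 1]].mean(axis=1) for i in range(k)],
        axis=1,
    )
    dev = rbar - (n + 1) / 2.0
    # T_j for every candidate deviant litter j
    total = rbar.sum(axis=1, keepdims=True)
    num = (total - rbar) / (k - 1) - rbar  # sum_i c_i Rbar_i, per j
    inv = 1.0 / sizes
    se2 = n * (n + 1) / 12.0 * ((inv.sum() - inv) / (k - 1) ** 2 + inv)
    t_all = num**2 / se2

    if frozen_j is not None:
        return t_all[:, frozen_j]

    key = dev if one_sided else np.abs(dev)
    j_sel = np.argmax(key, axis=1)
    # repair rows where the max is tied: larger litter first, then label order
    best = key[np.arange(key.shape[0]), j_sel]
    tied = (np.isclose(key, best[:, None], atol=1e-9).sum(axis=1)) > 1
    for row in np.nonzero(tied)[0]:
        cand = np.nonzero(np.isclose(key[row], best[row], atol=1e-9))[0]
        j_sel[row] = min(cand, key=lambda i: (-sizes[i], i))
    return t_all[np.arange(t_all.shape[0]), j_sel]


def permutation_pvalue(
    values_by_litter: dict[str, np.ndarray],
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "random",
    one_sided: bool = False,
    reselect: bool = True,
    exhaustive_cap: int = 200_000,
) -> PermutationResult:
    """Permutation p-value for the deviant-litter contrast statistic.

    Observations are reshuffled over the fixed litter sizes; because the
    statistic depends on the data only through midranks, the pooled midrank
    vector is permuted directly. By default the deviant litter is re-selected
    within each permutation (a valid null for a data-selected contrast);
    ``reselect=False`` freezes the observed litter instead. The p-value uses
    the strict inequality count(T_perm > T_obs) / N.
    """
    summary = RankSummary.from_values(values_by_litter)
    j_obs = most_deviant_litter(summary, one_sided=one_sided)
    t_obs = contrast_statistic(summary, j_obs).statistic

    labels = summary.labels
    sizes = np.asarray(summary.sizes, dtype=float)
    pooled = np.concatenate(
        [np.asarray(values_by_litter[l], dtype=float) for l in labels]
    )
    ranks = stats.rankdata(pooled)
    frozen = None if reselect else labels.index(j_obs)

    if mode == "exhaustive":
        sizes_int = [int(s) for s in summary.sizes]
        total = math.factorial(summary.n)
        for s in sizes_int:
            total //= math.factorial(s)
        if total > exhaustive_cap:
            raise CapacityError(
                f"{total} distinct assignments exceed the cap {exhaustive_cap}; "
                "use mode='random'"
            )
        perms = np.array(
            [np.concatenate(a) for a in _assignments(summary.n, sizes_int)], dtype=int
        )
        rank_matrix = ranks[perms]
        n_draws = total
    elif mode == "random":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, summary.n)), axis=1)
        rank_matrix = ranks[order]
        n_draws = n_perm
    else:
        raise ValueError("mode must be 'random' or 'exhaustive'")

    t_perm = _stat_for_ranks(rank_matrix, sizes, one_sided, frozen)
    p = float(np.mean(t_perm > t_obs))
    tie_frac = float(np.mean(np.isclose(t_perm, t_obs, atol=1e-9)))
    return PermutationResult(
        observed=t_obs,
        n_perm=n_draws,
        p_value=p,
        mode=mode,
        tie_fraction=tie_frac,
        degenerate=bool(tie_frac == 1.0),
    )


def _assignments(n: int, sizes: list[int]):
    """All distinct splits of indices 0..n-1 into ordered groups of the given
    sizes (within-group order fixed ascending)."""

    def rec(remaining: tuple[int, ...], sizes: list[int]):
        if not sizes:
            yield []
            return
        for combo in itertools.combinations(remaining, sizes[0]):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in rec(rest, sizes[1:]):
                yield [np.asarray(combo, dtype=int)] + tail

    yield from rec(tuple(range(n)), sizes)


@dataclass(frozen=True)
class ExclusionIteration:
    kw_h: float
    kw_p: float
    deviant_litter: str | None
    contrast: ContrastResult | None
    permutation: PermutationResult | None
    action: str  # stopped_at_kw | stopped_at_permutation | excluded | stopped_single_litter


@dataclass
class ExclusionTrace:
    iterations: list[ExclusionIteration] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def iterative_exclusion(
    values_by_litter: dict[str, np.ndarray],
    alpha_kw: float = 0.05,
    alpha_perm: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "random",
    one_sided: bool = False,
    reselect: bool = True,
) -> ExclusionTrace:
    """Run the four-step exclusion loop until it is forced to stop.

    Each pass re-runs the Kruskal-Wallis gate on the surviving litters, picks
    the most deviant litter, and excludes it only when the permutation test
    rejects. Deterministic for a given ``seed``; iteration r consumes
    ``seed + r`` so traces replay bit-for-bit.
    """
    current = {k: np.asarray(v, dtype=float) for k, v in values_by_litter.items()}
    trace = ExclusionTrace()
    rounds = 0
    while True:
        if len(current) < 2:
            trace.iterations.append(
                ExclusionIteration(0.0, 1.0, None, None, None, "stopped_single_litter")
            )
            return trace
        h, p_kw = kruskal_wallis(current)
        if p_kw > alpha_kw:
            trace.iterations.append(
                ExclusionIteration(h, p_kw, None, None, None, "stopped_at_kw")
            )
            return trace
        summary = RankSummary.from_values(current)
        j = most_deviant_litter(summary, one_sided=one_sided)
        contrast = contrast_statistic(summary, j)
        perm = permutation_pvalue(
            current,
            n_perm=n_perm,
            seed=seed + rounds,
            mode=mode,
            one_sided=one_sided,
            reselect=reselect,
        )
        if perm.p_value > alpha_perm:
            trace.iterations.append(
                ExclusionIteration(h, p_kw, j, contrast, perm, "stopped_at_permutation")
            )
            return trace
        if perm.degenerate:
            # every permuted T ties with the observed T; a strict-inequality
            # p of 0 here is saturation, not evidence — stop and flag
            trace.iterations.append(
                ExclusionIteration(h, p_kw, j, contrast, perm, "stopped_degenerate")
            )
            return trace
        trace.iterations.append(
            ExclusionIteration(h, p_kw, j, contrast, perm, "excluded")
        )
        trace.excluded.append(j)
        current = {k: v for k, v in current.items() if k != j}
        rounds += 1
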