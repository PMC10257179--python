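"""Decision quantities from posterior draws and per-experiment comparisons.

A treatment's effect is summarised by the posterior median of beta, a 95%
credible interval from the 2.5th/97.5th sample percentiles, and the
probability of efficacy Pr(beta < 0 | data) — the Monte-Carlo fraction of
posterior draws below zero (negative beta = less brain loss = protection).
Per-experiment nonparametric comparisons (median + range, two-sided rank-sum
p-value) accompany the model-based summaries, and a ranked table places the
concurrent-control and pooled-control analyses side by side.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTROL_LABEL, TrialDataset
from .model import PosteriorDraws


def prob_efficacy(beta_draws: np.ndarray) -> float:
    """Monte-Carlo Pr(beta < 0): strict fraction of draws below zero."""
    draws = np.asarray(beta_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one draw")
    return float(np.mean(draws < 0.0))


def posterior_summary(beta_draws: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Posterior median and central 95% credible interval.

    Sample 2.5/50/97.5 percentiles with linear interpolation between order
    statistics.
    """
    draws = np.asarray(beta_draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least two draws")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return float(med), (float(lo), float(hi))


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration with midranks.

    Counts allocations whose rank-sum deviates from its null mean by at least
    the observed amount.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, n1 = pooled.size, a.size
    expected = n1 * (n + 1) / 2.0
    w_obs = float(ranks[:n1].sum())
    d_obs = abs(w_obs - expected)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = float(ranks[list(combo)].sum())
        total += 1
        if abs(w - expected) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def _normal_two_sided_p(a: np.ndarray, b: np.ndarray) -> float:
    """Normal-approximation rank-sum p with tie and continuity corrections."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, n1 = pooled.size, a.size
    n2 = n - n1
    w = float(ranks[:n1].sum())
    expected = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w - expected) - 0.5) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(max(z, 0.0)))


@dataclass(frozen=True)
class GroupComparison:
    experiment_id: str
    treatment: str
    control_median: float
    control_range: tuple[float, float]
    control_n: int
    treatment_median: float
    treatment_range: tuple[float, float]
    treatment_n: int
    p_value: float
    degenerate: bool = False


def rank_sum_comparison(
    control: np.ndarray,
    treated: np.ndarray,
    method: str = "auto",
) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value with midranks.

    ``auto`` enumerates exactly for combined n <= 20 and otherwise uses the
    Normal approximation with tie and continuity corrections. Degenerate
    input (every pooled value identical) returns p = 1.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if method == "auto":
        method = "exact" if pooled.size <= 20 else "normal"
    if method == "exact":
        return _exact_two_sided_p(a, b)
    if method == "normal":
        return _normal_two_sided_p(a, b)
    if method == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown method {method!r}")


def compare_groups(dataset: TrialDataset, method: str = "auto") -> list[GroupComparison]:
    """Per-experiment control-vs-treated comparisons (median, range, p)."""
    out: list[GroupComparison] = []
    for exp in dataset.experiments:
        sub = dataset.experiment(exp)
        ctrl = sub[sub["treatment"] == CONTROL_LABEL]["area_loss_pct"].to_numpy(float)
        for trt in sorted(set(sub["treatment"]) - {CONTROL_LABEL}):
            vals = sub[sub["treatment"] == trt]["area_loss_pct"].to_numpy(float)
            pooled = np.concatenate([ctrl, vals])
            degenerate = bool(np.all(pooled == pooled[0]))
            out.append(
                GroupComparison(
                    experiment_id=exp,
                    treatment=trt,
                    control_median=float(np.median(ctrl)),
                    control_range=(float(ctrl.min()), float(ctrl.max())),
                    control_n=int(ctrl.size),
                    treatment_median=float(np.median(vals)),
                    treatment_range=(float(vals.min()), float(vals.max())),
                    treatment_n=int(vals.size),
                    p_value=rank_sum_comparison(ctrl, vals, method=method),
                    degenerate=degenerate,
                )
            )
    return out


@dataclass(frozen=True)
class EfficacySummary:
    treatment: str
    analysis: str  # pooled | concurrent
    effect_estimate: float  # posterior median of beta, percentage points
    cri_95: tuple[float, float]
    pr_efficacy: float
    significant: bool  # 95% CrI excludes 0


def summarize_treatment(draws: PosteriorDraws, treatment: str) -> EfficacySummary:
    beta = draws.beta_draws(treatment)
    med, cri = posterior_summary(beta)
    return EfficacySummary(
        treatment=treatment,
        analysis=draws.analysis,
        effect_estimate=med,
        cri_95=cri,
        pr_efficacy=prob_efficacy(beta),
        significant=bool(cri[0] > 0.0 or cri[1] < 0.0),
    )


def build_report(
    pooled: PosteriorDraws,
    concurrent: dict[str, PosteriorDraws] | None = None,
    dataset: TrialDataset | None = None,
    comparison_method: str = "auto",
) -> pd.DataFrame:
    """Ranked efficacy table, one row per treatment.

    Pooled-analysis summaries always appear; concurrent-control summaries are
    merged in where a per-experiment fit is supplied, and group medians with
    rank-sum p-values where the dataset is supplied. Rows are sorted by
    pooled Pr(efficacy), best first. Treatments without a pooled fit appear
    as absent rows (NaN summaries).
    """
    conc_by_trt: dict[str, EfficacySummary] = {}
    for fit in (concurrent or {}).values():
        for trt in fit.treatment_labels:
            conc_by_trt[trt] = summarize_treatment(fit, trt)

    comparisons = {
        (c.treatment): c for c in (compare_groups(dataset, comparison_method) if dataset else [])
    }

    treatments = sorted(
        set(pooled.treatment_labels) | set(conc_by_trt) | set(comparisons)
    )
    rows = []
    for trt in treatments:
        row: dict = {"treatment": trt}
        if trt in pooled.treatment_labels:
            s = summarize_treatment(pooled, trt)
            row.update(
                pooled_effect=round(s.effect_estimate, 2),
                pooled_cri_low=round(s.cri_95[0], 2),
                pooled_cri_high=round(s.cri_95[1], 2),
                pooled_pr_efficacy_pct=round(100.0 * s.pr_efficacy, 2),
                pooled_significant=s.significant,
            )
        else:
            row.update(
                pooled_effect=np.nan,
                pooled_cri_low=np.nan,
                pooled_cri_high=np.nan,
                pooled_pr_efficacy_pct=np.nan,
                pooled_significant=False,
            )
        if trt in conc_by_trt:
            s = conc_by_trt[trt]
            row.update(
                concurrent_effect=round(s.effect_estimate, 2),
                concurrent_cri_low=round(s.cri_95[0], 2),
                concurrent_cri_high=round(s.cri_95[1], 2),
                concurrent_pr_efficacy_pct=round(100.0 * s.pr_efficacy, 2),
                concurrent_significant=s.significant,
            )
        if trt in comparisons:
            c = comparisons[trt]
            row.update(
                experiment_id=c.experiment_id,
                control_median=round(c.control_median, 2),
                treatment_median=round(c.treatment_median, 2),
                rank_sum_p=round(c.p_value, 4),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["pooled_pr_efficacy_pct", "treatment"],
        ascending=[False, True],
        na_position="last",
    ).reset_index(drop=True)
    return table


def write_report(table: pd.DataFrame, csv_path=None, json_path=None) -> None:
    """Emit the ranked table as CSV and/or JSON (deterministic byte output)."""
    if csv_path is not None:
        table.to_csv(csv_path, index=False, float_format="%.4f")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                json.loads(table.to_json(orient="records")), fh, indent=2, sort_keys=True
            )
            fh.write("\n")
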