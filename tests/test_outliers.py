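import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoscreen import (
    RankSummary,
    contrast_statistic,
    iterative_exclusion,
    kruskal_wallis,
    most_deviant_litter,
    permutation_pvalue,
)
from neoscreen.outliers import CapacityError, DegenerateInputError


def oracle_midranks(values: np.ndarray) -> np.ndarray:
    """Independent midrank computation: rank = #below + (#equal + 1)/2."""
    return np.array(
        [np.sum(values < v) + (np.sum(values == v) + 1) / 2.0 for v in values]
    )


def oracle_kw(groups: list[np.ndarray]) -> float:
    """Brute-force tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    ranks = oracle_midranks(pooled)
    n = pooled.size
    h, pos = 0.0, 0
    for g in groups:
        rbar = ranks[pos : pos + g.size].mean()
        h += g.size * (rbar - (n + 1) / 2.0) ** 2
        pos += g.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis({"A": np.array([1, 2, 3.0]), "B": np.array([4, 5, 6.0])})
        assert h == pytest.approx(162 / 42, abs=1e-10)
        assert 0 < p < 1

    def test_all_equal_gives_zero_and_one(self):
        h, p = kruskal_wallis({"A": np.array([5.0, 5.0]), "B": np.array([5.0, 5.0])})
        assert (h, p) == (0.0, 1.0)

    def test_single_litter_rejected(self):
        with pytest.raises(DegenerateInputError):
            kruskal_wallis({"A": np.array([1.0, 2.0])})

    def test_matches_brute_force_oracle_with_ties(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 5))
            groups = {
                f"L{i}": rng.integers(0, 6, size=int(rng.integers(3, 8))).astype(float)
                for i in range(k)
            }
            vals = list(groups.values())
            pooled = np.concatenate(vals)
            if np.all(pooled == pooled[0]):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(oracle_kw(vals), abs=1e-10)

    @given(
        data=st.lists(
            st.lists(st.integers(0, 50), min_size=2, max_size=6),
            min_size=2,
            max_size=4,
        ),
        shift=st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, data, shift):
        groups = {f"L{i}": np.array(g, dtype=float) for i, g in enumerate(data)}
        pooled = np.concatenate(list(groups.values()))
        if np.all(pooled == pooled[0]):
            return
        transformed = {k: np.exp(v / 10.0) + shift for k, v in groups.items()}
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis(transformed)
        assert h1 == pytest.approx(h2, abs=1e-9)


class TestMostDeviantLitter:
    def test_tie_breaks_to_lexicographically_first(self):
        s = RankSummary(("A", "B"), (3, 3), (2.0, 5.0), 6)
        # deviations are -1.5 and +1.5: tie on |.|, equal sizes, pick "A"
        assert most_deviant_litter(s) == "A"

    def test_absolute_deviation_beats_signed(self):
        s = RankSummary(("A", "B", "C"), (3, 3, 2), (3.0, 3.0, 7.5), 9)
        assert most_deviant_litter(s) == "C"  # |2.5| > |2|
        # a low litter can be the most deviant in absolute terms
        s2 = RankSummary(("A", "B", "C"), (3, 3, 2), (2.0, 6.0, 5.0), 9)
        assert most_deviant_litter(s2) == "A"  # |-3| > |1|, |0|
        assert most_deviant_litter(s2, one_sided=True) == "B"

    def test_far_shifted_litter_always_selected(self, rng):
        for _ in range(20):
            groups = {f"L{i}": rng.normal(0, 1, 8) for i in range(4)}
            groups["L2"] = groups["L2"] + 50.0
            s = RankSummary.from_values(groups)
            # brute force: litter with max |mean rank - centre|
            centre = (s.n + 1) / 2
            best = max(
                range(4), key=lambda i: abs(s.mean_ranks[i] - centre)
            )
            assert most_deviant_litter(s) == s.labels[best] == "L2"


class TestContrastStatistic:
    def test_hand_computed_example(self):
        s = RankSummary.from_values(
            {"A": np.array([1, 2, 3.0]), "B": np.array([4, 5, 6.0])}
        )
        res = contrast_statistic(s, "B")
        assert res.numerator == pytest.approx(-3.0)
        assert res.se == pytest.approx(np.sqrt(7 / 3), abs=1e-12)
        assert res.statistic == pytest.approx(27 / 7, abs=1e-12)
        assert sum(res.contrasts) == pytest.approx(0.0, abs=1e-12)

    def test_equals_kruskal_wallis_for_two_litters(self, rng):
        """For K = 2 the contrast statistic reduces algebraically to H
        (checked on 100 random tie-free instances)."""
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, size=2)
            groups = {"A": rng.random(int(n1)), "B": rng.random(int(n2))}
            h, _ = kruskal_wallis(groups)
            s = RankSummary.from_values(groups)
            j = most_deviant_litter(s)
            t = contrast_statistic(s, j).statistic
            assert t == pytest.approx(h, abs=1e-10)

    def test_equal_mean_ranks_give_zero(self):
        s = RankSummary(("A", "B"), (2, 2), (2.5, 2.5), 4)
        assert contrast_statistic(s, "A").statistic == 0.0


class TestPermutationPvalue:
    VALUES = {"A": np.array([1.0, 2.0]), "B": np.array([9.0, 10.0])}

    def test_exhaustive_enumeration_matches_hand_oracle(self):
        """All C(4,2)=6 assignments of {1,2,9,10} to two litters of 2 give
        permuted T in {2.4, .6, 0, 0, .6, 2.4}; none strictly exceeds the
        observed 2.4, so p = 0."""
        res = permutation_pvalue(self.VALUES, mode="exhaustive")
        assert res.observed == pytest.approx(2.4, abs=1e-12)
        assert res.n_perm == 6
        assert res.p_value == 0.0
        assert not res.degenerate

    def test_identical_values_degenerate_flag(self):
        vals = {"A": np.array([3.0, 3.0]), "B": np.array([3.0, 3.0])}
        res = permutation_pvalue(vals, mode="exhaustive")
        assert res.p_value == 0.0
        assert res.degenerate

    def test_random_mode_agrees_with_exhaustive(self):
        exact = permutation_pvalue(self.VALUES, mode="exhaustive")
        rand = permutation_pvalue(self.VALUES, n_perm=10_000, seed=5, mode="random")
        tol = 3 * np.sqrt(max(exact.p_value * (1 - exact.p_value), 1e-4) / 10_000)
        assert abs(rand.p_value - exact.p_value) <= tol

    def test_random_matches_exhaustive_on_richer_instance(self, rng):
        vals = {
            "A": rng.normal(0, 1, 4),
            "B": rng.normal(0, 1, 3),
            "C": rng.normal(2, 1, 3),
        }
        exact = permutation_pvalue(vals, mode="exhaustive")
        rand = permutation_pvalue(vals, n_perm=20_000, seed=9, mode="random")
        tol = 3 * np.sqrt(max(exact.p_value * (1 - exact.p_value), 1e-3) / 20_000)
        assert abs(rand.p_value - exact.p_value) <= tol

    def test_exhaustive_cap(self):
        vals = {f"L{i}": np.arange(8, dtype=float) + i for i in range(5)}
        with pytest.raises(CapacityError):
            permutation_pvalue(vals, mode="exhaustive", exhaustive_cap=100)

    def test_seeded_reproducibility(self):
        a = permutation_pvalue(self.VALUES, n_perm=500, seed=3)
        b = permutation_pvalue(self.VALUES, n_perm=500, seed=3)
        assert a == b


class TestIterativeExclusion:
    def test_single_litter_stops_immediately(self):
        trace = iterative_exclusion({"A": np.array([1.0, 2.0])})
        assert trace.excluded == []
        assert trace.iterations[0].action == "stopped_single_litter"

    def test_homogeneous_litters_rarely_trigger(self, rng):
        groups = {f"L{i}": rng.normal(40, 5, 10) for i in range(5)}
        trace = iterative_exclusion(groups, n_perm=2000, seed=1)
        assert trace.n_excluded <= 1  # near-null data: at most a rare false call

    def test_shifted_litter_excluded_first(self, rng):
        hits = 0
        for rep in range(20):
            groups = {f"L{i}": rng.normal(40, 5, 10) for i in range(5)}
            groups["L3"] = groups["L3"] + 20.0  # +4 sigma
            trace = iterative_exclusion(groups, n_perm=2000, seed=100 + rep)
            if trace.excluded and trace.excluded[0] == "L3":
                hits += 1
        assert hits >= 18

    def test_trace_replays_bit_for_bit(self, rng):
        groups = {f"L{i}": rng.normal(40, 5, 8) for i in range(4)}
        groups["L0"] = groups["L0"] + 15.0
        t1 = iterative_exclusion(groups, n_perm=1000, seed=42)
        t2 = iterative_exclusion(groups, n_perm=1000, seed=42)
        assert t1.excluded == t2.excluded
        assert [i.action for i in t1.iterations] == [i.action for i in t2.iterations]
        for a, b in zip(t1.iterations, t2.iterations):
            if a.permutation:
                assert a.permutation.p_value == b.permutation.p_value

    def test_exclusion_bounded_and_excluded_never_return(self, rng):
        groups = {f"L{i}": rng.normal(40 + 15 * i, 2, 6) for i in range(4)}
        trace = iterative_exclusion(groups, n_perm=1000, seed=3)
        assert trace.n_excluded <= 3
        assert len(set(trace.excluded)) == len(trace.excluded)
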