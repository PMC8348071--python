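import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrcine import (
    InsufficientDataError,
    PairedCohortTable,
    cohen_kappa,
    icc_absolute,
    median_range,
    paired_t,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(diffs):
    """Exhaustive two-sided signed-rank p over all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    dev = abs(w_obs - mu)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= dev - 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_all_ties_is_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p_value == 1.0

    def test_matches_brute_force_on_8_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.integers(-3, 4, size=8)
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d.astype(float))
            assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d))

    def test_exact_equals_enumeration_small_n_property(self):
        """DP-based exact null must equal 2^n enumeration for n <= 10."""
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            d = rng.integers(-4, 5, size=n)
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d.astype(float))
            assert res.method == "wilcoxon (exact)"
            assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d))

    def test_swap_negates_statistic_and_keeps_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        b = a + rng.normal(0.3, 1.0, size=30)
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_agrees_with_scipy_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(9)
        d = rng.normal(0.4, 1.0, size=18)
        ours = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, alternative="two-sided", mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pratt_zero_handling_is_material(self):
        # zeros push the non-zero ranks up under Pratt, changing the null
        d = np.array([1.0, 0.0, -2.0, -1.0, -3.0, -3.0, -3.0, -2.0, 2.0, 1.0])
        wil = wilcoxon_signed_rank(d, zero_method="wilcox")
        pratt = wilcoxon_signed_rank(d, zero_method="pratt")
        assert wil.n_effective == pratt.n_effective == 9
        assert pratt.extra["w_plus"] > wil.extra["w_plus"]
        assert wil.p_value == pytest.approx(0.125)
        assert pratt.p_value == pytest.approx(0.171875)

    def test_null_type_one_error_rate(self):
        """Type-I error within [0.03, 0.07] at alpha 0.05, n=71, 2000 reps."""
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            d = rng.normal(size=71)
            if wilcoxon_signed_rank(d).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestPairedT:
    def test_identical_samples_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate

    def test_hand_computed_example(self):
        # differences [1,2,3,4]: mean 2.5, sd 1.2910, t = 3.873
        res = paired_t([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(3.873, abs=1e-3)
        assert res.p_value == pytest.approx(0.0305, abs=1e-3)

    def test_power_at_study_scale_shift(self):
        """A 0.012 px^-1 sharpness gap (sd 0.02, n=71) is detected >95% of
        the time at alpha 0.05."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 1000
        for _ in range(reps):
            diffs = rng.normal(0.012, 0.02, size=71)
            base = rng.normal(0.042, 0.01, size=71)
            if paired_t(base + diffs, base).p_value < 0.05:
                hits += 1
        assert hits / reps > 0.95


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_absolute(x).statistic == pytest.approx(1.0)

    def test_constant_offset_penalized_by_absolute_agreement(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        x = np.column_stack([a, a + 2.0])
        icc2 = icc_absolute(x, model="icc2").statistic
        icc3 = icc_absolute(x, model="icc3").statistic
        assert icc2 < 1.0
        assert icc3 == pytest.approx(1.0)

    def test_variance_components_recovered(self):
        # between-subject sd 1.0, rater noise sd 0.25: ICC ~ 1/(1+0.0625)
        rng = np.random.default_rng(11)
        n = 500
        subject = rng.normal(0, 1.0, size=n)
        x = np.column_stack(
            [subject + rng.normal(0, 0.25, n), subject + rng.normal(0, 0.25, n)]
        )
        expected = 1.0 / (1.0 + 0.25**2)
        assert icc_absolute(x).statistic == pytest.approx(expected, abs=0.05)

    def test_agrees_with_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(21)
        subject = rng.normal(0, 1.0, size=30)
        x = np.column_stack(
            [subject + rng.normal(0, 0.3, 30), subject + rng.normal(0, 0.3, 30)]
        )
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(30), 2),
                "raters": np.tile(["a", "b"], 30),
                "scores": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        )
        # two-way random, absolute agreement, single measure
        sel = ref["Type"].astype(str).str.contains("A,1|ICC2", regex=True)
        icc2_ref = float(ref.loc[sel, "ICC"].iloc[0])
        assert icc_absolute(x).statistic == pytest.approx(icc2_ref, abs=1e-9)

    def test_degenerate_between_subject_variance(self):
        x = np.full((10, 2), 3.0)
        assert icc_absolute(x).degenerate


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 2, 3, 1], [1, 2, 3, 1]).statistic == 1.0

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, size=4000)
        b = rng.integers(0, 4, size=4000)
        assert abs(cohen_kappa(a, b).statistic) < 0.05

    def test_printed_two_by_two_table(self):
        # confusion a=30, b=10, c=10, d=50: po=0.8, pe=0.52, kappa=0.5833
        a = [0] * 40 + [1] * 60
        b = [0] * 30 + [1] * 10 + [0] * 10 + [1] * 50
        assert cohen_kappa(a, b).statistic == pytest.approx(0.58333, abs=1e-4)

    def test_linear_weights_reduce_to_unweighted_for_binary(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, size=200)
        b = np.where(rng.random(200) < 0.8, a, 1 - a)
        assert cohen_kappa(a, b, weights="linear").statistic == pytest.approx(
            cohen_kappa(a, b).statistic
        )

    def test_single_category_degenerate(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]).degenerate


class TestMedianRange:
    def test_odd_n(self):
        assert median_range([1, 2, 3]) == {"median": 2.0, "min": 1.0, "max": 3.0}

    def test_even_n_midpoint_convention(self):
        assert median_range([1, 2, 3, 4])["median"] == 2.5

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            median_range([])


class TestPairedCohortTable:
    def test_crosstab_round_trip(self):
        counts = [[2, 1, 0], [1, 3, 1], [0, 0, 2]]
        table = PairedCohortTable.from_crosstab(counts, [1, 2, 3])
        np.testing.assert_array_equal(table.crosstab(), counts)
        assert table.n_patients == 10

    def test_equal_or_better_directions(self):
        counts = [[1, 2], [3, 4]]
        higher = PairedCohortTable.from_crosstab(counts, [1, 2], better="higher")
        lower = PairedCohortTable.from_crosstab(counts, [1, 2], better="lower")
        assert higher.equal_or_better()[0] == 1 + 2 + 4
        assert lower.equal_or_better()[0] == 1 + 3 + 4

    def test_inconsistent_marginals_rejected(self):
        from arrcine import FixtureError

        with pytest.raises(FixtureError):
            PairedCohortTable.from_crosstab([[1, 0], [0, 1]], [1, 2], n_patients=5)

    def test_long_csv_round_trip(self, tmp_path):
        table = PairedCohortTable.from_crosstab(
            [[2, 1], [0, 3]], [1, 2], better="higher"
        )
        path = tmp_path / "pairs.csv"
        table.to_long_csv(path)
        back = PairedCohortTable.from_long_csv(path, [1, 2])
        np.testing.assert_array_equal(back.scores_ref, table.scores_ref)
        np.testing.assert_array_equal(back.scores_rt, table.scores_rt)


@given(
    st.lists(
        st.tuples(st.integers(1, 4), st.integers(1, 4)), min_size=2, max_size=10
    )
)
@settings(max_examples=200, deadline=None)
def test_wilcoxon_exact_matches_enumeration_property(pairs):
    """Implementation equals exhaustive enumeration for all small inputs."""
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if np.all(a == b):
        return
    res = wilcoxon_signed_rank(a, b)
    assert res.p_value == pytest.approx(brute_force_wilcoxon_p(a - b))
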