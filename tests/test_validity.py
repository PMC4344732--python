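import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import icv_sparse as icv
from icv_sparse.validity import (
    _icc_rows,
    _offsets_matrix,
    _pearson_rows,
    icc_from_anova,
    two_way_anova,
)


def icc_oracle(x, y):
    """From-scratch two-way ANOVA ICC(A,1) by explicit sums of squares."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ssr = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestSampleCombinations:
    def test_spacing_one_yields_all_zero_offsets(self):
        combos = icv.sample_combinations(5, 1, count=10, seed=0)
        assert all(np.all(c.offsets == 0) for c in combos)

    def test_fixed_seed_reproduces_combinations(self):
        a = _offsets_matrix(icv.sample_combinations(7, 4, 50, seed=3))
        b = _offsets_matrix(icv.sample_combinations(7, 4, 50, seed=3))
        assert np.array_equal(a, b)

    def test_offsets_uniform_at_spacing_two(self):
        combos = icv.sample_combinations(5, 2, count=4000, seed=1)
        m = _offsets_matrix(combos)
        for subject in range(5):
            ones = m[:, subject].sum()
            chi2 = (ones - 2000) ** 2 / 2000 + ((4000 - ones) - 2000) ** 2 / 2000
            assert chi2 < stats.chi2.ppf(0.99, df=1)

    def test_offsets_within_range_enforced(self):
        with pytest.raises(ValueError):
            icv.CombinationSample(np.array([0, 5]), spacing_n=4)


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icv.icc_single_absolute(x, x) == pytest.approx(1.0)

    def test_constant_bias_penalized_while_pearson_blind(self):
        x = np.arange(10.0)
        y = x + 50.0
        assert icv.icc_single_absolute(x, y) < 1.0
        assert stats.pearsonr(x, y).statistic == pytest.approx(1.0)

    def test_random_and_mixed_models_share_point_estimate(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 12))
        assert icv.icc_single_absolute(x, y, "random") == icv.icc_single_absolute(
            x, y, "mixed"
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_explicit_sum_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 12)
        x = rng.normal(10, 3, n)
        y = x + rng.normal(0, 1, n)
        assert icv.icc_single_absolute(x, y) == pytest.approx(
            icc_oracle(x, y), abs=1e-12
        )

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(5)
        x = rng.normal(1.5e6, 1e5, 15)
        y = x + rng.normal(0, 4e4, 15)
        table = pd.DataFrame({
            "target": np.repeat(np.arange(15), 2),
            "rater": np.tile(["truth", "estimate"], 15),
            "score": np.column_stack([x, y]).ravel(),
        })
        ref = pg.intraclass_corr(
            table, targets="target", raters="rater", ratings="score"
        )
        icc2 = ref.loc[ref.Type.isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icv.icc_single_absolute(x, y) == pytest.approx(icc2, abs=1e-9)

    def test_vectorized_rows_match_scalar(self):
        rng = np.random.default_rng(7)
        x = rng.normal(100, 10, 9)
        Y = x[None, :] + rng.normal(0, 3, (20, 9))
        vec = _icc_rows(x, Y)
        for i in range(20):
            assert vec[i] == pytest.approx(icv.icc_single_absolute(x, Y[i]), abs=1e-12)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            icv.icc_single_absolute(np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            icv.icc_single_absolute(np.arange(2.0), np.arange(2.0))

    def test_anova_decomposition_fields(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(8, 2))
        anova = two_way_anova(data)
        assert anova.n_targets == 8 and anova.k_raters == 2
        assert min(anova.ms_rows, anova.ms_cols, anova.ms_err) >= 0
        assert icc_from_anova(anova) == pytest.approx(
            icc_oracle(data[:, 0], data[:, 1]), abs=1e-12
        )


class TestJaccard:
    def test_hand_cases(self):
        assert icv.jaccard_volumes([1.0], [1.0]) == 1.0
        assert icv.jaccard_volumes([1.0], [2.0]) == 0.5
        assert icv.jaccard_volumes([100.0, 200.0], [110.0, 190.0]) == pytest.approx(
            290 / 310
        )

    @given(
        x=st.lists(st.floats(0.1, 1e6), min_size=1, max_size=20),
        y_scale=st.floats(0.5, 2.0),
        c=st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_scale_equivariance(self, x, y_scale, c):
        x = np.array(x)
        y = x * y_scale
        assert icv.jaccard_volumes(x, y) == pytest.approx(
            icv.jaccard_volumes(y, x)
        )
        assert icv.jaccard_volumes(c * x, c * y) == pytest.approx(
            icv.jaccard_volumes(x, y), rel=1e-9
        )

    def test_nonpositive_volumes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            icv.jaccard_volumes([1.0, 0.0], [1.0, 1.0])


class TestPercentageError:
    def test_signed_definition(self):
        assert icv.percentage_error(100.0, 100.0) == 0.0
        assert icv.percentage_error(105.0, 100.0) == pytest.approx(5.0)
        assert icv.percentage_error(90.0, 100.0) == pytest.approx(-10.0)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            icv.percentage_error(1.0, 0.0)


class TestPearsonInvariance:
    def test_invariant_under_positive_affine_maps(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        Y = np.array([[2.0, 7.0, 1.0, 8.0, 2.0, 8.0]])
        base = _pearson_rows(x, Y)[0]
        assert _pearson_rows(x, 3.0 * Y + 11.0)[0] == pytest.approx(base)
        assert _pearson_rows(2.0 * x + 5.0, Y)[0] == pytest.approx(base)


class TestCompareInterpolators:
    def test_identical_mapes_give_zero_t(self, monkeypatch):
        from icv_sparse import validity

        monkeypatch.setattr(
            validity, "offset_estimates", lambda p, n, m: np.full(n, p.total_volume)
        )
        prof = [
            icv.generate_profile(1.5e6, 100, rng=np.random.default_rng(i))
            for i in range(4)
        ]
        rec = validity.compare_interpolators(prof, 10)
        assert rec.t == 0.0 and rec.mean_diff == 0.0 and rec.p == 1.0

    def test_uniform_spline_advantage_detected(self, monkeypatch):
        from icv_sparse import validity

        def fake(profile, n, method):
            err = 0.02 if method == "constant" else 0.01
            return profile.total_volume * (1 + err) * np.ones(n)

        monkeypatch.setattr(validity, "offset_estimates", fake)
        prof = [
            icv.generate_profile(1.5e6, 100, rng=np.random.default_rng(i))
            for i in range(6)
        ]
        rec = validity.compare_interpolators(prof, 10)
        assert rec.mean_diff == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_paired_t_on_real_estimates(self, small_cohort):
        rec = icv.compare_interpolators(small_cohort, 24, "sagittal")
        mape = {}
        for method in ("constant", "spline"):
            mape[method] = np.array([
                np.abs(icv.percentage_error(
                    icv.offset_estimates(s.profiles["sagittal"], 24, method),
                    s.true_volume,
                )).mean()
                for s in small_cohort
            ])
        ref = stats.ttest_rel(mape["constant"], mape["spline"])
        assert rec.t == pytest.approx(ref.statistic, rel=1e-9)
        assert rec.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert rec.mean_diff == pytest.approx(
            (mape["constant"] - mape["spline"]).mean()
        )

    def test_tiny_cohort_rejected(self):
        prof = [icv.generate_profile(1.5e6, 100, rng=np.random.default_rng(0))]
        with pytest.raises(ValueError, match="3"):
            icv.compare_interpolators(prof, 10)


class TestEvaluate:
    def test_spacing_one_metrics_are_perfect(self, small_cohort):
        rep = icv.evaluate(
            small_cohort, spacings=[1], orientations=("sagittal",),
            methods=("constant", "linear"), count=5, seed=0,
        )
        for method in ("constant", "linear"):
            for q in (5, 50, 95):
                assert rep.percentile(1, "sagittal", method, "icc", q) == pytest.approx(1.0, abs=1e-9)
                assert rep.percentile(1, "sagittal", method, "jaccard", q) == pytest.approx(1.0, abs=1e-9)
                assert rep.percentile(1, "sagittal", method, "abs_pct_error", q) == pytest.approx(0.0, abs=1e-9)

    def test_full_grid_report_dimensions(self, small_cohort):
        rep = icv.evaluate(small_cohort, count=3, seed=1)
        # 49 spacings x 3 orientations x 3 methods = 441 settings,
        # each with 5 percentiles of 4 metrics
        assert len(rep.percentiles) == 441 * 5 * 4
        assert len(rep.means) == 441 * 4
        assert len(rep.paired_tests) == 49 * 3
        grp = rep.percentiles.groupby(["spacing", "orientation", "method", "metric"])
        # percentile curves non-decreasing in the percentile order
        for _, g in grp:
            v = g.sort_values("percentile").value.to_numpy()
            assert np.all(np.diff(v) >= -1e-12)

    def test_error_grows_with_spacing(self, small_cohort):
        rep = icv.evaluate(small_cohort, spacings=[2, 50], count=50, seed=2)
        for orientation in icv.ORIENTATIONS:
            for method in icv.METHODS:
                lo = rep.percentile(2, orientation, method, "abs_pct_error", 50)
                hi = rep.percentile(50, orientation, method, "abs_pct_error", 50)
                assert hi > lo

    def test_method_results_independent_of_method_set(self, small_cohort):
        full = icv.evaluate(
            small_cohort, spacings=[10], orientations=("coronal",), count=40, seed=3
        )
        only = icv.evaluate(
            small_cohort, spacings=[10], orientations=("coronal",),
            methods=("spline",), count=40, seed=3,
        )
        a = full.percentiles[full.percentiles.method == "spline"].reset_index(drop=True)
        b = only.percentiles.reset_index(drop=True)
        assert a.equals(b)

    def test_monte_carlo_converges_to_exhaustive_toy_distribution(self):
        # 3 subjects at spacing 10: all 10^3 = 1000 combinations can be
        # enumerated by brute force; the Monte-Carlo percentiles must
        # approach the percentiles of that exhaustive distribution
        cohort = icv.generate_cohort(icv.PopulationSpec(n_female=2, n_male=1, seed=5))
        x = np.array([s.true_volume for s in cohort])
        E = np.array([
            icv.offset_estimates(s.profiles["sagittal"], 10, "constant")
            for s in cohort
        ])
        exhaustive = np.array([
            icv.icc_single_absolute(x, E[np.arange(3), list(offsets)])
            for offsets in itertools.product(range(10), repeat=3)
        ])
        combos = icv.sample_combinations(3, 10, count=20000, seed=4)
        O = _offsets_matrix(combos)
        mc = _icc_rows(x, E[np.arange(3)[None, :], O])
        atoms = np.sort(exhaustive)
        # every Monte-Carlo draw realizes one of the exhaustive values
        assert np.all(np.min(np.abs(mc[:, None] - atoms[None, :]), axis=1) < 1e-12)
        spread = np.percentile(atoms, 97.5) - np.percentile(atoms, 2.5)
        for q in (5, 25, 50, 75, 95):
            assert np.percentile(mc, q) == pytest.approx(
                np.percentile(atoms, q), abs=0.05 * spread
            )

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown method"):
            icv.evaluate(small_cohort, spacings=[2], methods=("pchip",))

    def test_report_round_trips_to_disk(self, tmp_path, small_cohort):
        rep = icv.evaluate(
            small_cohort, spacings=[5], orientations=("sagittal",), count=10, seed=0
        )
        rep.save(tmp_path)
        assert (tmp_path / "percentiles.csv").exists()
        assert (tmp_path / "paired_tests.csv").exists()
        assert (tmp_path / "manifest.json").exists()
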