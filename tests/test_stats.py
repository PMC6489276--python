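import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lungdelta.stats import (
    VoxelPairTable,
    bin_by_dose,
    compare_groups,
    compute_delta,
    fit_zero_intercept,
    per_patient_results,
    pooled_results,
    spearman_correlation,
)
from lungdelta.volumes import BinaryMask

from conftest import make_volume


def pairs_from(dose, delta, patient_id="p", timepoint="12w"):
    return VoxelPairTable(
        data=pd.DataFrame(
            {
                "dose": np.asarray(dose, dtype=float),
                "delta_hu": np.asarray(delta, dtype=float),
                "patient_id": patient_id,
                "timepoint": timepoint,
            }
        ),
        excluded={},
    )


# ------------------------------------------------------------------ regression

class TestZeroInterceptFit:
    def test_exact_line_through_origin(self):
        res = fit_zero_intercept(pairs_from([10, 20, 30], [20, 40, 60]))
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.stderr == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        # slope = (5*10 + 10*5) / (25 + 100) = 100/125
        res = fit_zero_intercept(pairs_from([5, 10], [10, 5]))
        assert res.slope == pytest.approx(0.8, abs=1e-12)

    def test_null_response_gives_zero_slope(self):
        res = fit_zero_intercept(pairs_from([5, 15, 30], [0, 0, 0]))
        assert res.slope == 0.0

    def test_all_zero_dose_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            fit_zero_intercept(pairs_from([0, 0, 0], [1, 2, 3]))

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 50)
            d = rng.uniform(0, 74, n)
            y = rng.normal(0, 50, n)
            res = fit_zero_intercept(pairs_from(d, y))
            assert res.slope == pytest.approx(float(d @ y) / float(d @ d), abs=1e-10)

    def test_inference_matches_statsmodels_no_constant(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        for _ in range(5):
            d = rng.uniform(1, 74, 40)
            y = 1.5 * d + rng.normal(0, 30, 40)
            res = fit_zero_intercept(pairs_from(d, y))
            ols = sm.OLS(y, d).fit()
            assert res.slope == pytest.approx(ols.params[0], abs=1e-10)
            assert res.stderr == pytest.approx(ols.bse[0], abs=1e-10)
            assert res.p_value == pytest.approx(ols.pvalues[0], abs=1e-10)


# ------------------------------------------------------------------ correlation

def brute_force_spearman(x, y):
    """Independent oracle: average ranks then Pearson."""
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_correlation(pairs_from([1, 2, 3, 4], [10, 20, 30, 40]))
        assert res.rho == pytest.approx(1.0)

    def test_reversed_monotone(self):
        res = spearman_correlation(pairs_from([1, 2, 3, 4], [40, 30, 20, 10]))
        assert res.rho == pytest.approx(-1.0)

    def test_ties_match_rank_pearson_oracle(self):
        d = [0, 5, 5, 10, 15, 20, 20, 30]
        y = [3, -1, 4, 9, 2, 12, 8, 30]
        res = spearman_correlation(pairs_from(d, y))
        assert res.rho == pytest.approx(brute_force_spearman(d, y), abs=1e-10)

    def test_constant_dose_reported_undefined(self):
        res = spearman_correlation(pairs_from([5, 5, 5, 5], [1, 2, 3, 4]))
        assert res.rho is None and res.p_value is None

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            spearman_correlation(pairs_from([1, 2], [1, 2]))


# ------------------------------------------------------------------ binning

class TestDoseBinning:
    def test_hand_binned_means(self):
        bins = bin_by_dose(pairs_from([2.0, 7.5, 9.9], [10.0, 20.0, 30.0]), width=5.0)
        assert len(bins) == 2
        assert (bins[0].bin_lower, bins[0].n_voxels, bins[0].mean_delta) == (0.0, 1, 10.0)
        assert (bins[1].bin_lower, bins[1].n_voxels, bins[1].mean_delta) == (5.0, 2, 25.0)

    def test_boundary_dose_goes_to_upper_bin(self):
        bins = bin_by_dose(pairs_from([5.0, 1.0], [1.0, 1.0]), width=5.0)
        by_lower = {b.bin_lower: b for b in bins}
        assert by_lower[5.0].n_voxels == 1

    def test_ci_half_width_matches_closed_form(self):
        rng = np.random.default_rng(3)
        n = 10_000
        pairs = pairs_from(rng.uniform(10, 14.9, n), rng.normal(30, 60, n))
        (b,) = bin_by_dose(pairs, width=5.0)
        half = (b.ci95_high - b.ci95_low) / 2
        assert half == pytest.approx(1.96 * 60 / np.sqrt(n), rel=0.15)

    def test_empty_table_gives_empty_list(self):
        empty = VoxelPairTable(
            data=pd.DataFrame(columns=["dose", "delta_hu", "patient_id", "timepoint"]),
            excluded={},
        )
        assert bin_by_dose(empty) == []

    def test_every_row_lands_in_exactly_one_bin(self):
        rng = np.random.default_rng(5)
        pairs = pairs_from(rng.uniform(0, 74, 5000), rng.normal(0, 10, 5000))
        bins = bin_by_dose(pairs)
        assert sum(b.n_voxels for b in bins) == 5000

    def test_last_bin_truncated_at_max_dose(self):
        bins = bin_by_dose(pairs_from([72.0, 73.5], [0.0, 0.0]), width=5.0)
        assert bins[-1].truncated and bins[-1].bin_upper == 73.5


# ------------------------------------------------------------------ delta extraction

class TestComputeDelta:
    def _setup(self):
        shape = (8, 8, 8)
        planning = make_volume(np.full(shape, -800.0))
        analysis = BinaryMask(np.zeros(shape, dtype=bool), (1, 1, 1), label="analysis")
        analysis.values[2:6, 2:6, 2:6] = True  # 64 voxels
        dose = make_volume(np.full(shape, 10.0), kind="dose")
        return planning, analysis, dose

    def test_self_subtraction_is_zero(self):
        planning, analysis, dose = self._setup()
        pairs = compute_delta(planning, planning, analysis, dose)
        assert pairs.n == 64
        assert (pairs.data["delta_hu"] == 0).all()

    def test_uniform_offset_recovered(self):
        planning, analysis, dose = self._setup()
        followup = planning.with_values(planning.values + 50.0)
        pairs = compute_delta(planning, followup, analysis, dose)
        assert pairs.n == 64
        assert (pairs.data["delta_hu"] == 50.0).all()

    def test_validity_mask_bookkeeping_conserved(self):
        planning, analysis, dose = self._setup()
        validity = BinaryMask(np.ones_like(analysis.values), (1, 1, 1), label="analysis")
        validity.values[2, 2:6, 2:6] = False  # knocks out 16 analysis voxels
        pairs = compute_delta(planning, planning, analysis, dose, validity=validity)
        assert pairs.n == 64 - 16
        assert pairs.excluded["invalid_after_registration"] == 16
        total = pairs.n + pairs.excluded["invalid_after_registration"]
        assert total == int(analysis.values.sum())

    def test_geometry_mismatch_rejected(self):
        planning, analysis, dose = self._setup()
        other = make_volume(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="geometry"):
            compute_delta(planning, other, analysis, dose)


# ------------------------------------------------------------------ cohort level

class TestCohortStats:
    def test_noise_free_per_patient_slopes_recovered(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 74, 2000)
        tables = {
            f"p{i}": pairs_from(d, slope * d, patient_id=f"p{i}")
            for i, slope in enumerate((0.0, 1.5, 3.0))
        }
        df = per_patient_results(tables, timepoint="12w")
        np.testing.assert_allclose(sorted(df["slope"]), [0.0, 1.5, 3.0], atol=1e-6)
        assert df.attrs["cohort_summary"]["slope_min"] == pytest.approx(0.0, abs=1e-9)
        assert df.attrs["cohort_summary"]["slope_max"] == pytest.approx(3.0, abs=1e-9)

    def test_single_patient_cohort_degenerate_summary(self):
        tab = pairs_from([10, 20], [15, 30])
        df = per_patient_results({"only": tab})
        s = df.attrs["cohort_summary"]
        assert s["slope_min"] == s["slope_max"] == pytest.approx(1.5)

    def test_identical_patients_pool_to_same_slope(self):
        d = np.linspace(1, 74, 500)
        tab = pairs_from(d, 2.0 * d + np.sin(d))
        single = fit_zero_intercept(tab)
        pooled, _, _ = pooled_results([tab, tab, tab])[0], None, None
        assert pooled.slope == pytest.approx(single.slope, abs=1e-12)

    def test_unit_slope_mean_delta_equals_mean_dose(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 74, 3000)
        _, _, mean_delta = pooled_results([pairs_from(d, 1.0 * d)])
        assert mean_delta == pytest.approx(d.mean(), abs=1e-9)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 74, 500)
        y = 1.5 * d + rng.normal(0, 20, 500)
        t1 = pairs_from(d, y)
        perm = rng.permutation(500)
        t2 = pairs_from(d[perm], y[perm])
        r1, c1, m1 = pooled_results([t1])
        r2, c2, m2 = pooled_results([t2])
        assert r1.slope == pytest.approx(r2.slope, abs=1e-12)
        assert c1.rho == pytest.approx(c2.rho, abs=1e-12)
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_patient_weighting_averages_slopes(self):
        d = np.linspace(1, 50, 100)
        tabs = [pairs_from(d, 1.0 * d), pairs_from(d, 3.0 * d)]
        reg, _, _ = pooled_results(tabs, weighting="patient")
        assert reg.slope == pytest.approx(2.0, abs=1e-9)


# ------------------------------------------------------------------ group comparison

def welch_oracle(a, b):
    """Textbook Welch formulae, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


class TestCompareGroups:
    def test_identical_groups_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = compare_groups(a, a.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_welch_oracle(self):
        a = np.array([28.1, 35.2, 22.9, 41.0, 30.5, 27.7])
        b = np.array([33.0, 39.9, 41.2, 29.4, 44.1])
        t, p = compare_groups(a, b)
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_power_at_unit_effect(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            compare_groups(rng.normal(0, 1, 500), rng.normal(1, 1, 500))[1] < 0.001
            for _ in range(20)
        )
        assert rejections == 20

    def test_degenerate_equal_constants(self):
        t, p = compare_groups([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)
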