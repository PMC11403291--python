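import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from drugprofiler.errors import InputError, NotQuantifiableError
from drugprofiler.steroidomics import (
    fit_calibration,
    normalize_to_internal_standard,
    quantify_samples,
    remove_outliers,
    select_calibration,
    treatment_fold_and_test,
    validate_calibration,
)
from drugprofiler.synthetic import CalibrationSpec, simulate_calibration_and_samples


def points(conc, resp):
    return pd.DataFrame({"nominal_conc": conc, "norm_response": resp})


def exact_line(n=8, a=1.0, b=0.0):
    conc = np.array([0.5, 1, 2, 4, 8, 16, 32, 64], dtype=float)[:n]
    return points(conc, a * conc + b)


class TestNormalization:
    def test_ratio_examples(self):
        assert normalize_to_internal_standard(500, 500) == 1.0
        assert normalize_to_internal_standard(750, 500) == 1.5

    def test_missing_internal_standard_flagged(self):
        with pytest.raises(InputError):
            normalize_to_internal_standard(100, 0)


class TestFitCalibration:
    def test_exact_straight_line(self):
        m = fit_calibration(points([1, 2, 4, 8], [1, 2, 4, 8]), "straight")
        assert m.coefficients[0] == pytest.approx(1.0, abs=1e-12)
        assert m.coefficients[1] == pytest.approx(0.0, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0)

    def test_exact_quadratic_recovery(self):
        conc = np.array([1, 2, 4, 8, 16, 32], dtype=float)
        m = fit_calibration(points(conc, 0.1 * conc**2 + conc), "quadratic")
        np.testing.assert_allclose(m.coefficients, [0.1, 1.0, 0.0], atol=1e-9)

    def test_weighting_irrelevant_at_zero_residual(self):
        conc = np.array([1, 2, 4, 8, 16, 32], dtype=float)
        pts = points(conc, 0.1 * conc**2 + conc)
        unw = fit_calibration(pts, "quadratic", "none")
        wgt = fit_calibration(pts, "quadratic", "inverse_concentration")
        np.testing.assert_allclose(unw.coefficients, wgt.coefficients, atol=1e-9)

    def test_insufficient_points(self):
        with pytest.raises(InputError):
            fit_calibration(points([1, 2, 4], [1, 2, 4]), "straight")
        with pytest.raises(InputError):
            fit_calibration(points([1, 2, 4, 8], [1, 2, 4, 8]), "quadratic")


class TestValidation:
    def test_exact_model_valid_and_idempotent(self):
        m = validate_calibration(fit_calibration(exact_line(), "straight"))
        assert m.valid
        assert np.nanmax(m.back_calc_errors) == pytest.approx(0.0, abs=1e-9)
        again = validate_calibration(m)
        assert again.valid and np.allclose(
            again.back_calc_errors, m.back_calc_errors, equal_nan=True
        )

    def test_single_bad_point_invalidates(self):
        pts = exact_line()
        pts.loc[3, "norm_response"] *= 1.25  # 25% response error > 15% rule
        m = validate_calibration(fit_calibration(pts, "straight"))
        assert not m.valid

    def test_vacuous_tolerance(self):
        pts = exact_line()
        pts.loc[3, "norm_response"] *= 1.25
        m = validate_calibration(fit_calibration(pts, "straight"), tolerance=1.0)
        assert m.valid


class TestOutlierRemoval:
    def test_clean_data_removes_nothing(self):
        m = remove_outliers(exact_line(), "straight")
        assert m.valid and m.n_removed == 0

    def test_single_gross_outlier_removed(self):
        pts = exact_line()
        pts.loc[5, "norm_response"] *= 3.0
        m = remove_outliers(pts, "straight")
        assert m.valid
        assert m.n_removed == 1
        assert not m.retained[5]

    def test_three_outliers_exceed_budget(self):
        pts = exact_line()
        for i in (2, 5, 7):
            pts.loc[i, "norm_response"] *= 3.0
        m = remove_outliers(pts, "straight")
        assert not m.valid  # 3/8 = 37.5% > 25% budget

    def test_retained_fraction_never_below_75pct(self):
        for seed in range(20):
            cal, _ = simulate_calibration_and_samples(
                CalibrationSpec(noise_cv=0.08, n_outliers=seed % 4, seed=seed)
            )
            pts = points(cal["nominal_conc"],
                         cal["analyte_response"] / cal["is_response"])
            m = remove_outliers(pts, "straight")
            assert m.n_retained >= int(np.ceil(0.75 * m.n_total))


class TestSelection:
    def test_exact_line_tie_breaks_to_straight_unweighted(self):
        m = select_calibration(exact_line())
        assert (m.family, m.weighting) == ("straight", "none")
        assert m.r_squared == pytest.approx(1.0)

    def test_saturating_quadratic_selects_quadratic_family(self):
        """With 2% noise on a curved response, the quadratic family wins the
        R^2 comparison in the majority of seeds."""
        wins = 0
        for seed in range(20):
            cal, _ = simulate_calibration_and_samples(
                CalibrationSpec(true_coefficients=(-0.004, 1.0, 0.0),
                                noise_cv=0.02, seed=seed)
            )
            pts = points(cal["nominal_conc"],
                         cal["analyte_response"] / cal["is_response"])
            if select_calibration(pts).family == "quadratic":
                wins += 1
        assert wins > 10

    def test_flat_responses_not_quantifiable(self):
        with pytest.raises(NotQuantifiableError):
            select_calibration(points([1, 2, 4, 8, 16], np.ones(5)))

    @given(k=st.floats(0.1, 100))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_unit_equivariance(self, k):
        """Scaling nominal concentrations by k scales quantified sample
        concentrations by exactly k (straight family)."""
        conc = np.array([0.5, 1, 2, 4, 8, 16, 32, 64])
        resp = 2.0 * conc + 0.1
        base = select_calibration(points(conc, resp))
        scaled = select_calibration(points(conc * k, resp))
        q1 = quantify_samples(base, [3.0]).iloc[0]["concentration"]
        q2 = quantify_samples(scaled, [3.0]).iloc[0]["concentration"]
        assert q2 == pytest.approx(k * q1, rel=1e-6)


class TestQuantification:
    def test_identity_line(self):
        m = select_calibration(exact_line())
        assert quantify_samples(m, [2.5]).iloc[0]["concentration"] == pytest.approx(2.5)

    def test_quadratic_monotone_branch_root(self):
        conc = np.array([0.25, 0.5, 1, 2, 4, 8], dtype=float)
        m = select_calibration(points(conc, 0.1 * conc**2 + conc))
        row = quantify_samples(m, [1.1]).iloc[0]
        # root of 0.1 x^2 + x - 1.1 = 0 on the monotone branch
        assert row["concentration"] == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_flagged_but_reported(self):
        m = select_calibration(exact_line())
        row = quantify_samples(m, [0.1]).iloc[0]
        assert row["flag"] == "out_of_range"
        assert row["concentration"] == pytest.approx(0.1)

    def test_invalid_model_rejected(self):
        m = fit_calibration(exact_line(), "straight")  # never validated
        with pytest.raises(InputError):
            quantify_samples(m, [1.0])


class TestTreatmentStats:
    def test_identical_groups(self):
        fold, t, p = treatment_fold_and_test([1, 2, 3], [1, 2, 3])
        assert (fold, t, p) == (1.0, 0.0, 1.0)

    def test_constant_sixfold_effect(self):
        fold, _, _ = treatment_fold_and_test([1, 1, 1], [6.5, 6.5, 6.5])
        assert fold == pytest.approx(6.5)

    def test_matches_brute_force_welch(self):
        """Agreement with a from-scratch Welch computation
        (Welch-Satterthwaite degrees of freedom)."""
        v = np.array([4.1, 5.2, 3.9, 4.8])
        t_ = np.array([6.3, 7.1, 6.8])
        fold, tstat, p = treatment_fold_and_test(v, t_)
        sv, st_ = v.var(ddof=1) / v.size, t_.var(ddof=1) / t_.size
        t_expected = (t_.mean() - v.mean()) / np.sqrt(sv + st_)
        df = (sv + st_) ** 2 / (sv**2 / (v.size - 1) + st_**2 / (t_.size - 1))
        p_expected = 2 * stats.t.sf(abs(t_expected), df)
        assert tstat == pytest.approx(t_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_zero_vehicle_mean(self):
        with pytest.raises(InputError):
            treatment_fold_and_test([0, 0], [1, 2])


class TestEndToEndRecovery:
    @pytest.mark.parametrize("true_fold", [2.0, 6.5, 10.0])
    def test_fold_recovery_across_seeds(self, true_fold):
        """Full pipeline at 5% CV recovers the treatment fold within 15% in
        at least 90 of 100 seeded runs."""
        ok = 0
        for seed in range(100):
            cal, samp = simulate_calibration_and_samples(
                CalibrationSpec(noise_cv=0.05, true_fold=true_fold, seed=seed)
            )
            pts = points(cal["nominal_conc"],
                         cal["analyte_response"] / cal["is_response"])
            model = select_calibration(pts)
            norm = samp["analyte_response"] / samp["is_response"]
            q = quantify_samples(model, norm, groups=samp["group"].tolist())
            v = q.loc[q["group"] == "vehicle", "concentration"]
            t_ = q.loc[q["group"] == "treatment", "concentration"]
            fold, _, _ = treatment_fold_and_test(v, t_)
            ok += abs(fold - true_fold) / true_fold <= 0.15
        assert ok >= 90
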