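"""Multivariable Cox, nomogram, time-dependent ROC, DeLong, calibration."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import oracles
from radsurv.prognostic import (
    build_nomogram,
    calibration,
    code_clinical,
    delong_compare,
    fit_cox,
    timedep_auc_nne,
)
from radsurv.synthetic import SimCohortSpec, simulate_cohort


@pytest.fixture(scope="module")
def ph_cohort():
    spec = SimCohortSpec(n=500, beta={"f000": 0.5, "f002": 0.7},
                         n_features=4, seed=21)
    return simulate_cohort(spec)


@pytest.fixture(scope="module")
def ph_fit(ph_cohort):
    return fit_cox(ph_cohort.features, ph_cohort)


class TestCoxFit:
    def test_single_covariate_matches_lifelines(self, ph_cohort):
        from lifelines import CoxPHFitter
        df = pd.DataFrame({"x": ph_cohort.features["f000"],
                           "T": ph_cohort.times, "E": ph_cohort.events})
        res = fit_cox(df[["x"]], ph_cohort)
        ll = CoxPHFitter().fit(df, "T", "E")  # Efron ties; untied times here
        assert res.coefficients["x"] == pytest.approx(
            float(ll.params_["x"]), abs=1e-4)
        assert res.standard_errors["x"] == pytest.approx(
            float(ll.standard_errors_["x"]), rel=1e-3)

    def test_parameter_recovery_within_015(self):
        errs = []
        truth = {"f000": 0.5, "f002": 0.7}
        for seed in range(5):
            spec = SimCohortSpec(n=500, beta=truth, n_features=4, seed=seed)
            co = simulate_cohort(spec)
            res = fit_cox(co.features, co)
            for k, b in truth.items():
                errs.append(abs(res.coefficients[k] - b))
            errs.append(abs(res.coefficients["f001"]))
        assert max(errs) < 0.15

    def test_null_covariates_stay_small(self):
        big = []
        for seed in range(10):
            co = simulate_cohort(SimCohortSpec(n=500, beta={}, n_features=3,
                                               seed=100 + seed))
            res = fit_cox(co.features, co)
            big.append(bool((res.coefficients.abs() < 0.2).all()))
        assert np.mean(big) >= 0.95

    def test_baseline_survival_monotone_from_one(self, ph_fit):
        assert ph_fit.baseline_survival_at(0.0) == 1.0
        s = [ph_fit.baseline_survival_at(t) for t in (6, 12, 24, 48)]
        assert all(b <= a for a, b in zip(s, s[1:]))

    def test_no_events_rejected(self):
        df = pd.DataFrame({"x": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            fit_cox(df, (np.array([1.0, 2.0, 3.0]), np.zeros(3, int)))


class TestClinicalCoding:
    def test_raw_values_dichotomized(self):
        raw = pd.DataFrame({
            "figo_stage": ["III", "IV"],
            "postop_ca125": [20.0, 120.0],
            "residual": [0.0, 1.5],
            "tumor_side": ["unilateral", "bilateral"],
            "menopause": ["menopause", "premenopausal"],
            "age": [55, 48],
        })
        coded = code_clinical(raw)
        for col in ("figo_stage", "postop_ca125", "residual",
                    "tumor_side", "menopause"):
            assert list(coded[col]) == [0, 1]
        assert list(coded["age"]) == [55, 48]

    def test_already_coded_passthrough(self):
        df = pd.DataFrame({"figo_stage": [0, 1, 0], "age": [50, 60, 70]})
        pd.testing.assert_frame_equal(code_clinical(df), df)


class TestNomogram:
    def test_zero_beta_gives_flat_points(self, ph_fit, ph_cohort):
        ranges = {c: (float(ph_cohort.features[c].min()),
                      float(ph_cohort.features[c].max()))
                  for c in ph_cohort.features.columns}
        nom = build_nomogram(ph_fit, ranges)
        # f003 has a near-zero coefficient: its span is tiny
        span3 = abs(nom.points("f003", ranges["f003"][1]) -
                    nom.points("f003", ranges["f003"][0]))
        span0 = abs(nom.points("f000", ranges["f000"][1]) -
                    nom.points("f000", ranges["f000"][0]))
        assert span3 < span0

    def test_dominant_variable_spans_0_to_100(self, ph_fit, ph_cohort):
        ranges = {c: (float(ph_cohort.features[c].min()),
                      float(ph_cohort.features[c].max()))
                  for c in ph_cohort.features.columns}
        nom = build_nomogram(ph_fit, ranges)
        spans = []
        for name in ph_fit.coefficients.index:
            lo, hi = ranges[name]
            spans.append(abs(nom.points(name, hi) - nom.points(name, lo)))
        assert max(spans) == pytest.approx(100.0)
        all_pts = [nom.points(n, v) for n in ranges for v in ranges[n]]
        assert min(min(np.atleast_1d(p)) for p in all_pts) >= -1e-9

    def test_roundtrip_equals_direct_prediction(self, ph_fit, ph_cohort, rng):
        ranges = {c: (float(ph_cohort.features[c].min()),
                      float(ph_cohort.features[c].max()))
                  for c in ph_cohort.features.columns}
        nom = build_nomogram(ph_fit, ranges)
        sample = ph_cohort.features.sample(100, random_state=7)
        for t in (18.0, 36.0):
            direct = ph_fit.predict_survival(sample, t)
            via_points = nom.survival_from_points(nom.total_points(sample), t)
            np.testing.assert_allclose(via_points, direct, atol=5e-3)

    def test_zero_range_with_nonzero_beta_rejected(self, ph_fit, ph_cohort):
        ranges = {c: (0.0, 1.0) for c in ph_cohort.features.columns}
        ranges["f000"] = (1.0, 1.0)
        with pytest.raises(ValueError):
            build_nomogram(ph_fit, ranges)


class TestTimeDependentROC:
    def test_perfect_separation_auc_one(self):
        t = np.array([5.0] * 10 + [50.0] * 10)
        e = np.ones(20, int)
        marker = np.r_[np.ones(10), np.zeros(10)]
        roc = timedep_auc_nne(marker, (t, e), 18.0)
        assert roc.auc == pytest.approx(1.0, abs=0.01)

    def test_reduces_to_binary_auc_without_censoring(self):
        co = simulate_cohort(SimCohortSpec(
            n=400, beta={"f000": 1.0}, n_features=2,
            censor_window=(1e9, 2e9), seed=3))
        m = co.features["f000"].to_numpy()
        label = ((co.events == 1) & (co.times <= 18.0)).astype(int)
        roc = timedep_auc_nne(m, co, 18.0)
        assert roc.auc == pytest.approx(roc_auc_score(label, m), abs=0.02)

    def test_anti_marker_symmetry(self, ph_cohort):
        m = ph_cohort.features["f000"].to_numpy()
        a = timedep_auc_nne(m, ph_cohort, 18.0).auc
        b = timedep_auc_nne(-m, ph_cohort, 18.0).auc
        assert a + b == pytest.approx(1.0, abs=0.01)

    def test_monotone_transform_invariance(self, ph_cohort):
        m = ph_cohort.features["f000"].to_numpy()
        a = timedep_auc_nne(m, ph_cohort, 18.0).auc
        b = timedep_auc_nne(np.exp(3 * m), ph_cohort, 18.0).auc
        assert a == pytest.approx(b, abs=1e-9)

    def test_no_events_by_horizon_rejected(self):
        t = np.array([30.0, 40.0, 50.0, 60.0])
        with pytest.raises(ValueError):
            timedep_auc_nne(np.arange(4.0), (t, np.ones(4, int)), 10.0)


class TestDeLong:
    def test_identical_markers_p_one(self, rng):
        m = rng.normal(size=100)
        y = (rng.random(100) < 0.4).astype(int)
        auc_a, auc_b, p = delong_compare(m, m.copy(), y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_variance_matches_placement_oracle(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        var = oracles.delong_variance(a, b, y)
        auc_a, auc_b, p = delong_compare(a, b, y)
        from scipy import stats as sps
        z = (auc_a - auc_b) / np.sqrt(var)
        assert p == pytest.approx(float(2 * sps.norm.sf(abs(z))), rel=1e-9)

    def test_null_calibration(self, rng):
        # independent noise markers: p below 0.10 in roughly 10% of replicates
        hits = 0
        reps = 200
        for _ in range(reps):
            y = np.r_[np.ones(40, int), np.zeros(60, int)]
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            _, _, p = delong_compare(a, b, y)
            hits += p < 0.10
        assert 0.04 * reps <= hits <= 0.16 * reps


class TestCalibration:
    def test_perfect_calibration_zero_chi2(self):
        # three risk groups whose predictions equal their observed
        # (uncensored) event fractions by the horizon exactly
        t = np.r_[np.where(np.arange(10) < 2, 10.0, 30.0),
                  np.where(np.arange(10) < 5, 10.0, 30.0),
                  np.where(np.arange(10) < 8, 10.0, 30.0)]
        e = np.ones(30, int)
        pred = np.r_[np.full(10, 0.2), np.full(10, 0.5), np.full(10, 0.8)]
        cal = calibration(pred, (t, e), 18.0)
        assert cal.hl_chi2 == pytest.approx(0.0, abs=1e-12)
        assert cal.hl_p == pytest.approx(1.0)

    def test_bin_counts(self):
        co = simulate_cohort(SimCohortSpec(n=100, beta={}, n_features=2,
                                           seed=6))
        cal = calibration(np.linspace(0.1, 0.9, 100), co, 18.0)
        assert len(cal.bins) <= 10
        assert (cal.bins["n"] >= 10).all()

    def test_insufficient_patients_rejected(self):
        co = simulate_cohort(SimCohortSpec(n=15, beta={}, n_features=2, seed=8))
        with pytest.raises(ValueError):
            calibration(np.full(15, 0.5), co, 18.0)

    def test_type_i_error_near_nominal(self):
        # well-specified predictions: HL rejects ~5% of the time
        rejections = 0
        reps = 120
        k, scale = 1.5, 18.0 / np.log(2.0) ** (1 / 1.5)
        for seed in range(reps):
            co = simulate_cohort(SimCohortSpec(
                n=300, beta={"f000": 0.7}, n_features=2, seed=3000 + seed))
            lp = 0.7 * co.features["f000"].to_numpy()
            true_p = 1.0 - np.exp(-((18.0 / scale) ** k) * np.exp(lp))
            cal = calibration(true_p, co, 18.0)
            rejections += cal.hl_p < 0.05
        assert rejections / reps < 0.12


class TestCombinedModelDominance:
    def test_added_signal_raises_horizon_auc(self):
        wins = 0
        for seed in range(10):
            co = simulate_cohort(SimCohortSpec(
                n=300, beta={"f000": 0.6, "f001": 0.6}, n_features=3,
                seed=500 + seed))
            clin = co.features[["f000"]]
            both = co.features[["f000", "f001"]]
            auc_clin = timedep_auc_nne(
                fit_cox(clin, co).linear_predictor(clin), co, 18.0).auc
            auc_both = timedep_auc_nne(
                fit_cox(both, co).linear_predictor(both), co, 18.0).auc
            wins += auc_both >= auc_clin
        assert wins >= 9
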