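"""LASSO-Cox signature fitting, scoring and survival validation."""

import numpy as np
import pandas as pd
import pytest

import oracles
from radsurv.signature import (
    Cohort,
    RadiomicSignatureModel,
    SignatureResults,
    SurvivalRecord,
    breslow_loglik,
    compute_signature,
    fit_lasso_cox,
    harrell_c,
    kaplan_meier,
    logrank_test,
    median_split,
)
from radsurv.synthetic import SimCohortSpec, simulate_cohort


@pytest.fixture(scope="module")
def planted_cohort():
    spec = SimCohortSpec(n=120, beta={"f000": 1.0, "f001": -1.0},
                         n_features=15, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="module")
def planted_fit(planted_cohort):
    return fit_lasso_cox(planted_cohort.features, planted_cohort)


class TestLassoCox:
    def test_full_shrinkage_above_lambda_max(self, planted_cohort):
        model = RadiomicSignatureModel(planted_cohort.features,
                                       planted_cohort.times,
                                       planted_cohort.events)
        probe = model._path(None, model.Z, model.time, model.event)
        lam_max = float(np.max(probe.alphas_))
        res = model.fit(lambda_grid=[10 * lam_max, 5 * lam_max])
        assert res.n_selected == 0

    def test_planted_features_recovered(self, planted_fit):
        assert {"f000", "f001"} <= set(planted_fit.coefficients.index)
        assert planted_fit.coefficients["f000"] > 0
        assert planted_fit.coefficients["f001"] < 0

    def test_active_set_shrinks_along_lambda_path(self, planted_cohort):
        model = RadiomicSignatureModel(planted_cohort.features,
                                       planted_cohort.times,
                                       planted_cohort.events)
        path = model._path(None, model.Z, model.time, model.event)
        sizes = (path.coef_ != 0).sum(axis=0)
        lams = np.asarray(path.alphas_)
        order = np.argsort(lams)[::-1]  # decreasing penalty
        sizes = sizes[order]
        # non-decreasing active set as the penalty relaxes, modulo rare swaps
        assert sizes[0] <= 2
        assert sizes[-1] >= sizes[0]
        assert np.sum(np.diff(sizes.astype(int)) < 0) <= len(sizes) // 10

    def test_cv_curve_minimum_at_selected_lambda(self, planted_fit):
        curve = planted_fit.cv_curve
        lam_at_min = float(
            curve.loc[curve["loocv_deviance"].idxmin(), "lambda"])
        assert lam_at_min == planted_fit.lambda_

    def test_standardization_roundtrip_preserves_signatures(self, planted_cohort,
                                                            planted_fit):
        # original-scale coefficients reproduce the standardized-fit linear
        # predictor up to one constant shift
        model = RadiomicSignatureModel(planted_cohort.features,
                                       planted_cohort.times,
                                       planted_cohort.events)
        sig_orig = np.asarray(planted_fit.signature(planted_cohort.features))
        beta_std = planted_fit.coefficients * planted_fit.sds[
            planted_fit.coefficients.index]
        cols = [model.feature_names.index(f)
                for f in planted_fit.coefficients.index]
        sig_std = model.Z[:, cols] @ beta_std.to_numpy()
        shift = sig_orig - sig_std
        np.testing.assert_allclose(shift, shift[0], atol=1e-10)

    def test_no_events_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)),
                         columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            RadiomicSignatureModel(X, np.arange(1.0, 21.0), np.zeros(20, int))

    def test_summary_lists_selected_features(self, planted_fit):
        text = planted_fit.summary()
        assert "lambda" in text
        for name in planted_fit.coefficients.index:
            assert name in text


class TestComputeSignature:
    def _result(self, coefs):
        s = pd.Series(coefs)
        return SignatureResults(None, 0.1, s, pd.DataFrame(),
                                s * 0.0, s * 0.0 + 1.0)

    def test_zero_features_zero_signature(self):
        res = self._result({"a": 2.0, "b": -1.0})
        fv = pd.Series({"a": 0.0, "b": 0.0, "c": 5.0})
        assert compute_signature(fv, res) == 0.0

    def test_published_zsv_coefficient_arithmetic(self):
        # one selected zone-size-variance feature with the published weight
        res = self._result({"Coiflet_LLL__GLSZM__Zone_size_variance":
                            5.47648232895881e-06})
        fv = pd.Series({"Coiflet_LLL__GLSZM__Zone_size_variance": 1e5})
        assert compute_signature(fv, res) == pytest.approx(0.547648232895881)

    def test_homogeneity(self, planted_fit, planted_cohort):
        sig1 = np.asarray(planted_fit.signature(planted_cohort.features))
        sig2 = np.asarray(planted_fit.signature(planted_cohort.features * 2))
        np.testing.assert_allclose(sig2, 2 * sig1, rtol=1e-12)

    def test_missing_feature_raises_key_error(self):
        res = self._result({"a": 1.0})
        with pytest.raises(KeyError):
            compute_signature(pd.Series({"b": 1.0}), res)


class TestMedianSplit:
    def test_basic_threshold(self):
        strat = median_split([3.0], float(np.median([1, 2, 3, 4])))
        assert strat.threshold == 2.5
        assert strat.groups[0] == "high"

    def test_validation_cohort_may_be_unbalanced(self):
        strat = median_split([-1.0, -2.0, -0.5], 0.0)
        assert (strat.groups == "low").all()

    def test_tie_goes_low(self):
        strat = median_split([2.5], 2.5)
        assert strat.groups[0] == "low"


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        km = kaplan_meier((np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])))
        assert float(km.predict(0.0)) == 1.0
        assert float(km.predict(1.0)) == pytest.approx(2 / 3)
        assert float(km.predict(2.0)) == pytest.approx(1 / 3)
        assert float(km.predict(3.0)) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = kaplan_meier((np.array([5.0, 8.0, 2.0]), np.zeros(3, int)))
        assert float(km.predict(10.0)) == 1.0

    def test_single_event_among_censored(self):
        km = kaplan_meier((np.array([5.0, 10.0]), np.array([1, 0])))
        assert float(km.predict(5.0)) == pytest.approx(0.5)


class TestLogrank:
    def test_identical_groups(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 0, 1, 1])
        chi2, p = logrank_test((t, e), (t.copy(), e.copy()))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        ta, ea = rng.exponential(10, 30), rng.integers(0, 2, 30)
        tb, eb = rng.exponential(20, 25), rng.integers(0, 2, 25)
        ea[0] = eb[0] = 1
        c1, _ = logrank_test((ta, ea), (tb, eb))
        c2, _ = logrank_test((tb, eb), (ta, ea))
        assert c1 == pytest.approx(c2, rel=1e-10)

    def test_six_patient_example_matches_risk_set_oracle(self):
        ta = np.array([1.0, 4.0, 6.0])
        ea = np.array([1, 1, 0])
        tb = np.array([2.0, 5.0, 7.0])
        eb = np.array([1, 0, 1])
        chi2, _ = logrank_test((ta, ea), (tb, eb))
        assert chi2 == pytest.approx(
            oracles.logrank_chi2(ta, ea, tb, eb), rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test((np.array([1.0]), np.array([0])),
                         (np.array([2.0]), np.array([0])))


class TestHarrellC:
    def test_perfect_risk_marker(self):
        t = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        c, _ = harrell_c(-t, (t, np.ones(5, int)), ci=False)
        assert c == 1.0

    def test_null_marker_near_half(self):
        spec = SimCohortSpec(n=1000, beta={}, n_features=2, seed=9)
        co = simulate_cohort(spec)
        c, _ = harrell_c(co.features["f000"].to_numpy(), co, ci=False)
        assert 0.45 <= c <= 0.55

    def test_five_record_set_matches_pair_enumeration(self, rng):
        t = np.array([2.0, 5.0, 3.0, 8.0, 4.0])
        e = np.array([1, 0, 1, 1, 1])
        m = np.array([0.3, 0.1, 0.3, -0.2, 0.9])
        c, _ = harrell_c(m, (t, e), ci=False)
        assert c == pytest.approx(oracles.harrell_c_pairs(m, t, e), abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self, planted_cohort, planted_fit):
        sig = np.asarray(planted_fit.signature(planted_cohort.features))
        c, (lo, hi) = harrell_c(sig, planted_cohort, n_boot=200, seed=1)
        assert lo <= c <= hi
        assert c > 0.6  # planted signal is informative


class TestCohortContainers:
    def test_record_validation(self):
        with pytest.raises(ValueError):
            SurvivalRecord(-1.0, 1)
        with pytest.raises(ValueError):
            SurvivalRecord(5.0, 2)

    def test_cohort_label_closed_set(self):
        rec = [SurvivalRecord(5.0, 1)]
        feats = pd.DataFrame({"f": [1.0]})
        with pytest.raises(ValueError):
            Cohort(rec, feats, "XYZ")

    def test_breslow_loglik_matches_direct_formula(self, rng):
        # untied continuous times: ll = sum_events [lp_i - log sum_risk exp(lp)]
        t = rng.exponential(10, 12)
        e = rng.integers(0, 2, 12)
        e[0] = 1
        lp = rng.normal(size=12)
        direct = sum(
            lp[i] - np.log(np.exp(lp[t >= t[i]]).sum())
            for i in range(12) if e[i] == 1
        )
        assert breslow_loglik(lp, t, e) == pytest.approx(direct, rel=1e-10)


class TestPowerProperties:
    def test_median_split_separates_planted_signal(self):
        spec = SimCohortSpec(n=100, beta={"f000": 1.0}, n_features=5, seed=77)
        co = simulate_cohort(spec)
        sig = co.features["f000"].to_numpy()
        strat = median_split(sig, float(np.median(sig)))
        _, p = logrank_test((co.times[strat.is_high], co.events[strat.is_high]),
                            (co.times[~strat.is_high], co.events[~strat.is_high]))
        assert p < 0.01

    def test_true_linear_predictor_dominates_components(self):
        spec = SimCohortSpec(n=400, beta={"f000": 0.8, "f001": 0.8},
                             n_features=4, seed=5)
        co = simulate_cohort(spec)
        lp = 0.8 * co.features["f000"] + 0.8 * co.features["f001"]
        c_lp, _ = harrell_c(lp.to_numpy(), co, ci=False)
        for col in co.features.columns:
            c_f, _ = harrell_c(co.features[col].to_numpy(), co, ci=False)
            assert c_lp >= c_f - 1e-9
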