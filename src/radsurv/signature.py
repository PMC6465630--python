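"""LASSO-Cox radiomic signature: selection, scoring, survival validation.

The signature is a per-patient scalar, the linear combination of the
radiomic features that keep a non-zero coefficient in an L1-penalized Cox
regression of progression-free survival.  The penalty is chosen as the
minimizer of the leave-one-out cross-validated partial-likelihood deviance
(the Verweij-van Houwelingen linear-predictor criterion).  Patients are
stratified into high/low recurrence-risk groups at the training-cohort
median signature.

The module is organised statsmodels-style: build a
:class:`RadiomicSignatureModel` from a feature matrix and survival data,
``fit()`` it, and use the returned :class:`SignatureResults` for scoring,
stratification and summaries.  Thin functional wrappers
(:func:`fit_lasso_cox`, :func:`compute_signature`, ...) expose the same
operations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

__all__ = [
    "SurvivalRecord",
    "Cohort",
    "RadiomicSignatureModel",
    "SignatureResults",
    "RiskStratification",
    "breslow_loglik",
    "fit_lasso_cox",
    "compute_signature",
    "median_split",
    "kaplan_meier",
    "logrank_test",
    "harrell_c",
]

COHORT_LABELS = ("TC", "IVC", "IEVC")


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time (months), event flag, covariates."""

    time: float
    event: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"time must be finite and > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class Cohort:
    """Aligned survival records and feature vectors, tagged TC/IVC/IEVC."""

    records: list[SurvivalRecord]
    features: pd.DataFrame
    label: str = "TC"

    def __post_init__(self) -> None:
        if self.label not in COHORT_LABELS:
            raise ValueError(f"label must be one of {COHORT_LABELS}")
        if len(self.records) != len(self.features):
            raise ValueError("records and features must be aligned")

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


def _surv_arrays(surv) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of SurvivalRecord, a Cohort, or a (time, event) pair."""
    if isinstance(surv, Cohort):
        return surv.times, surv.events
    if isinstance(surv, (list, tuple)) and len(surv) and isinstance(surv[0], SurvivalRecord):
        return (np.array([r.time for r in surv]),
                np.array([r.event for r in surv]))
    time, event = surv
    return np.asarray(time, dtype=float), np.asarray(event, dtype=int)


def breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow-tie Cox partial log-likelihood of linear predictors ``lp``."""
    order = np.argsort(time, kind="stable")
    t, d, x = time[order], event[order], lp[order]
    x = x - x.max()  # numerical guard; partial likelihood is shift-invariant
    risk = np.cumsum(np.exp(x)[::-1])[::-1]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])  # tie-group starts
    dd = np.add.reduceat(d, starts)
    has_event = dd > 0
    return float(x[d == 1].sum()
                 - (dd[has_event] * np.log(risk[starts[has_event]])).sum())


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class RadiomicSignatureModel:
    """L1-penalized Cox model over a radiomic feature matrix.

    Parameters
    ----------
    features : DataFrame, shape (n, p)
        One row per patient; columns are radiomic features.
    time, event : arrays
        Follow-up months and recurrence flags.

    Features are standardized internally (zero mean, unit variance);
    constant columns are dropped with a warning.  Reported coefficients are
    back-transformed to the original feature scale.
    """

    def __init__(self, features: pd.DataFrame, time, event):
        self.feature_names_all = list(features.columns)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if len(features) != len(self.time):
            raise ValueError("features and survival data must be aligned")
        if len(features) < 10:
            raise ValueError("need at least 10 patients")
        if self.event.sum() == 0:
            raise ValueError("no events; Cox fit is undefined")

        X = features.to_numpy(dtype=float)
        sds = X.std(axis=0)
        keep = sds > 0
        if not keep.all():
            dropped = [c for c, k in zip(features.columns, keep) if not k]
            warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...")
        self.feature_names = [c for c, k in zip(features.columns, keep) if k]
        self.X = X[:, keep]
        self.means = self.X.mean(axis=0)
        self.sds = self.X.std(axis=0)
        self.Z = (self.X - self.means) / self.sds

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "RadiomicSignatureModel":
        return cls(cohort.features, cohort.times, cohort.events)

    # -- internals ----------------------------------------------------------

    def _path(self, alphas: np.ndarray | None, X: np.ndarray, t, d):
        est = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            alphas=None if alphas is None else list(alphas),
            n_alphas=100,
            alpha_min_ratio=0.01,
            normalize=False,
            fit_baseline_model=False,
            max_iter=100000,
        )
        y = Surv.from_arrays(event=d.astype(bool), time=t)
        with warnings.catch_warnings():
            # the all-zero model at the top of the path is expected
            warnings.filterwarnings(
                "ignore", message="all coefficients are zero")
            est.fit(X, y)
        return est

    def _cv_deviance(self, alphas: np.ndarray) -> np.ndarray:
        """LOOCV partial-likelihood deviance per lambda.

        Verweij & van Houwelingen: for each left-out patient i,
        CV_i(lam) = l(full; beta_-i) - l(without i; beta_-i); the deviance
        is -2 times the sum over patients.
        """
        n = len(self.time)
        cv = np.zeros(len(alphas))
        idx = np.arange(n)
        for i in range(n):
            sub = idx != i
            t_s, d_s, Z_s = self.time[sub], self.event[sub], self.Z[sub]
            if d_s.sum() == 0:
                continue
            est = self._path(alphas, Z_s, t_s, d_s)
            # coxnet may stop the path early; align columns to the grid
            avail = np.log(np.asarray(est.alphas_))
            cols = np.abs(np.log(alphas)[:, None] - avail[None, :]).argmin(axis=1)
            coefs = est.coef_[:, cols]  # (p, n_alphas)
            lp_full = self.Z @ coefs
            lp_sub = Z_s @ coefs
            for k in range(len(alphas)):
                cv[k] += breslow_loglik(lp_full[:, k], self.time, self.event) - \
                    breslow_loglik(lp_sub[:, k], t_s, d_s)
        return -2.0 * cv

    # -- fitting ------------------------------------------------------------

    def fit(self, lambda_grid=None, seed: int | None = None) -> "SignatureResults":
        """Fit the penalty path and select lambda by minimum LOOCV deviance.

        ``lambda_grid`` defaults to 100 log-spaced values from the all-zero
        entry point lambda_max down to 0.01 * lambda_max.
        """
        if lambda_grid is None:
            probe = self._path(None, self.Z, self.time, self.event)
            alphas = np.asarray(probe.alphas_)
        else:
            alphas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
            if (alphas <= 0).any():
                raise ValueError("lambda grid must be positive")

        deviance = self._cv_deviance(alphas)
        best = int(np.argmin(deviance))
        lam = float(alphas[best])

        final = self._path(alphas, self.Z, self.time, self.event)
        col = int(np.abs(np.log(np.asarray(final.alphas_)) - np.log(lam)).argmin())
        beta_std = final.coef_[:, col]
        beta_orig = beta_std / self.sds
        nonzero = beta_std != 0
        coefficients = pd.Series(
            beta_orig[nonzero],
            index=[f for f, nz in zip(self.feature_names, nonzero) if nz],
            name="coefficient",
        )
        cv_curve = pd.DataFrame({"lambda": alphas, "loocv_deviance": deviance})
        return SignatureResults(
            model=self,
            lambda_=lam,
            coefficients=coefficients,
            cv_curve=cv_curve,
            means=pd.Series(self.means, index=self.feature_names),
            sds=pd.Series(self.sds, index=self.feature_names),
        )


@dataclass
class SignatureResults:
    """Fitted LASSO-Cox signature: selected features and their weights."""

    model: RadiomicSignatureModel | None
    lambda_: float
    coefficients: pd.Series  # original-scale, non-zero only
    cv_curve: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    @property
    def n_selected(self) -> int:
        return len(self.coefficients)

    def signature(self, features: pd.DataFrame | pd.Series) -> np.ndarray | float:
        """Per-patient signature: sum of coefficient * feature value."""
        return compute_signature(features, self)

    def summary(self) -> str:
        lines = [
            "LASSO-Cox radiomic signature",
            "=" * 46,
            f"lambda (min LOOCV deviance): {self.lambda_:.6g}",
            f"selected features:           {self.n_selected}",
            "",
            f"{'feature':<40s} {'coefficient':>14s}",
            "-" * 55,
        ]
        for name, beta in self.coefficients.items():
            lines.append(f"{name:<40s} {beta:>14.6g}")
        return "\n".join(lines)

    def to_json(self, tc_median: float | None = None) -> str:
        payload = {
            "lambda": self.lambda_,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "standardization": {
                "means": {k: float(v) for k, v in self.means.items()},
                "sds": {k: float(v) for k, v in self.sds.items()},
            },
        }
        if tc_median is not None:
            payload["tc_median"] = float(tc_median)
        return json.dumps(payload, sort_keys=True, indent=2)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_lasso_cox(features: pd.DataFrame, surv, lambda_grid=None) -> SignatureResults:
    """Fit the L1-penalized Cox path and pick lambda by LOOCV deviance."""
    time, event = _surv_arrays(surv)
    return RadiomicSignatureModel(features, time, event).fit(lambda_grid=lambda_grid)


def compute_signature(features: pd.DataFrame | pd.Series,
                      result: SignatureResults) -> np.ndarray | float:
    """Linearly-weighted combination of the selected features."""
    coef = result.coefficients
    if isinstance(features, pd.Series):
        missing = [f for f in coef.index if f not in features.index]
        if missing:
            raise KeyError(f"feature vector lacks {missing}")
        return float((features[coef.index] * coef).sum())
    missing = [f for f in coef.index if f not in features.columns]
    if missing:
        raise KeyError(f"feature table lacks {missing}")
    return features[coef.index].to_numpy(dtype=float) @ coef.to_numpy()


@dataclass
class RiskStratification:
    """High/low risk groups at the training-cohort median signature.

    Ties go to the low-risk group (signature must exceed the threshold to
    be high risk).
    """

    threshold: float
    groups: np.ndarray  # array of "high"/"low"

    @property
    def is_high(self) -> np.ndarray:
        return self.groups == "high"


def median_split(signatures: np.ndarray, tc_median: float) -> RiskStratification:
    """Assign high/low risk by the (training-cohort) median signature."""
    sig = np.asarray(signatures, dtype=float)
    groups = np.where(sig > tc_median, "high", "low")
    return RiskStratification(float(tc_median), groups)


def kaplan_meier(surv) -> KaplanMeierFitter:
    """Product-limit survival estimate (right censoring handled)."""
    time, event = _surv_arrays(surv)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    return kmf


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided p)."""
    ta, da = _surv_arrays(group_a)
    tb, db = _surv_arrays(group_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if da.sum() + db.sum() == 0:
        raise ValueError("no events; log-rank test undefined")
    res = _ll_logrank(ta, tb, event_observed_A=da, event_observed_B=db)
    return float(res.test_statistic), float(res.p_value)


def harrell_c(
    marker: np.ndarray,
    surv,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: bool = True,
) -> tuple[float, tuple[float, float] | None]:
    """Harrell's concordance index of a risk marker, with bootstrap 95% CI.

    Higher marker values are taken to indicate higher risk (earlier
    events).  Tied markers in usable pairs count 0.5.  The CI is a
    percentile bootstrap over patients (B = ``n_boot``).
    """
    time, event = _surv_arrays(surv)
    marker = np.asarray(marker, dtype=float)
    if len(marker) < 2 or event.sum() == 0:
        raise ValueError("need >= 2 patients and >= 1 event")
    c = float(concordance_index_censored(event.astype(bool), time, marker)[0])
    if not ci:
        return c, None
    rng = np.random.default_rng(seed)
    n = len(marker)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if event[idx].sum() == 0:
            continue
        try:
            boots.append(
                concordance_index_censored(
                    event[idx].astype(bool), time[idx], marker[idx])[0])
        except Exception:
            continue
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return c, (float(lo), float(hi))
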