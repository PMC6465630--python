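"""Multivariable Cox modelling, nomogram, time-dependent ROC, calibration.

The prognostic workflow combines the radiomic signature with seven
dichotomized/continuous clinical covariates (age, FIGO stage, pre- and
post-operative CA-125, residual tumor, tumor side, menopause status) in a
Breslow-tie Cox proportional hazards model, presents it as a nomogram
(covariate values -> points -> total points -> survival probability at the
18-month and 3-year horizons), and evaluates discrimination with a
time-dependent ROC built on the nearest-neighbor bivariate survival
estimator plus DeLong comparisons, and calibration with risk-binned
observed-vs-predicted curves and the Hosmer-Lemeshow test.

Statsmodels-style surface: :class:`ProportionalHazardsModel` ->
``fit()`` -> :class:`CoxResults`; nomogram/ROC/calibration hang off the
results object, with functional wrappers for each operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .signature import _surv_arrays, breslow_loglik, kaplan_meier

__all__ = [
    "CLINICAL_CUT_RULES",
    "code_clinical",
    "ProportionalHazardsModel",
    "CoxResults",
    "Nomogram",
    "TimeROC",
    "CalibrationResult",
    "fit_cox",
    "build_nomogram",
    "timedep_auc_nne",
    "default_nne_span",
    "delong_compare",
    "calibration",
    "hosmer_lemeshow",
]

#: Dichotomization rules for the clinical covariates (raw value -> 0/1).
CLINICAL_CUT_RULES = {
    "figo_stage": "III -> 0, IV -> 1",
    "postop_ca125": "<= 35 U/mL -> 0, > 35 -> 1",
    "residual": "0 cm -> 0, > 0 cm -> 1",
    "tumor_side": "unilateral -> 0, bilateral -> 1",
    "menopause": "menopause -> 0, premenopausal -> 1",
}


def code_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the standard 0/1 coding to raw clinical columns.

    Columns already coded 0/1 pass through unchanged; raw numeric columns
    (postop_ca125 in U/mL, residual in cm) and string columns (figo_stage
    "III"/"IV", tumor_side, menopause) are dichotomized per
    :data:`CLINICAL_CUT_RULES`.  Age and preoperative CA-125 stay
    continuous.
    """
    out = df.copy()
    def _binary(col, fn):
        if col in out and not set(pd.unique(out[col])) <= {0, 1}:
            out[col] = out[col].map(fn).astype(int)
    _binary("figo_stage", lambda v: 1 if str(v).strip().upper() == "IV" else 0)
    _binary("postop_ca125", lambda v: 1 if float(v) > 35 else 0)
    _binary("residual", lambda v: 1 if float(v) > 0 else 0)
    _binary("tumor_side", lambda v: 1 if str(v).strip().lower() == "bilateral" else 0)
    _binary("menopause", lambda v: 1 if str(v).strip().lower().startswith("pre") else 0)
    return out


# ---------------------------------------------------------------------------
# Cox model
# ---------------------------------------------------------------------------

class ProportionalHazardsModel:
    """Breslow-tie Cox proportional hazards model over named covariates."""

    def __init__(self, covariates: pd.DataFrame, time, event):
        self.covariate_names = list(covariates.columns)
        self.X = covariates.to_numpy(dtype=float)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if len(self.X) != len(self.time):
            raise ValueError("covariates and survival data must be aligned")
        if self.event.sum() == 0:
            raise ValueError("no events; Cox fit undefined")

    def fit(self) -> "CoxResults":
        est = CoxPHSurvivalAnalysis(ties="breslow")
        y = Surv.from_arrays(event=self.event.astype(bool), time=self.time)
        try:
            est.fit(self.X, y)
        except Exception as exc:
            raise RuntimeError(f"Cox fit failed (separation or collinearity?): {exc}")
        beta = np.asarray(est.coef_, dtype=float)
        se = self._wald_se(beta)
        lp = self.X @ beta
        times, s0 = _breslow_baseline(lp, self.time, self.event)
        return CoxResults(
            coefficients=pd.Series(beta, index=self.covariate_names),
            standard_errors=pd.Series(se, index=self.covariate_names),
            baseline_times=times,
            baseline_survival=s0,
            model=self,
        )

    def _wald_se(self, beta: np.ndarray) -> np.ndarray:
        """Observed-information standard errors under Breslow ties."""
        X, t, d = self.X, self.time, self.event
        order = np.argsort(t, kind="stable")
        Xo, to, do = X[order], t[order], d[order]
        w = np.exp(Xo @ beta)
        n, p = Xo.shape
        info = np.zeros((p, p))
        # suffix sums over the risk set (ties share the risk set at their time)
        sw = np.cumsum(w[::-1])[::-1]
        swx = np.cumsum((w[:, None] * Xo)[::-1], axis=0)[::-1]
        swxx = np.cumsum((w[:, None, None] * Xo[:, :, None] * Xo[:, None, :])[::-1],
                         axis=0)[::-1]
        i = 0
        while i < n:
            j = i
            while j < n and to[j] == to[i]:
                j += 1
            dd = do[i:j].sum()
            if dd > 0:
                xbar = swx[i] / sw[i]
                v = swxx[i] / sw[i] - np.outer(xbar, xbar)
                info += dd * v
            i = j
        cov = np.linalg.inv(info)
        return np.sqrt(np.diag(cov))


def _breslow_baseline(lp: np.ndarray, time: np.ndarray, event: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Breslow baseline survival S0 at the distinct event times (lp at x=0)."""
    order = np.argsort(time, kind="stable")
    t, d, w = time[order], event[order], np.exp(lp[order])
    sw = np.cumsum(w[::-1])[::-1]
    times, haz = [], []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dd = d[i:j].sum()
        if dd > 0:
            times.append(t[i])
            haz.append(dd / sw[i])
        i = j
    H0 = np.cumsum(haz)
    return np.asarray(times), np.exp(-H0)


@dataclass
class CoxResults:
    """Fitted Cox model: coefficients, Wald SEs, Breslow baseline survival."""

    coefficients: pd.Series
    standard_errors: pd.Series
    baseline_times: np.ndarray
    baseline_survival: np.ndarray
    model: ProportionalHazardsModel | None = None

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        cols = list(self.coefficients.index)
        return covariates[cols].to_numpy(dtype=float) @ self.coefficients.to_numpy()

    def baseline_survival_at(self, t: float) -> float:
        """Step-function S0(t); S0(0) = 1."""
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.baseline_survival[idx])

    def predict_survival(self, covariates: pd.DataFrame, t: float) -> np.ndarray:
        """S(t | x) = S0(t) ** exp(lp(x)) under proportional hazards."""
        s0 = self.baseline_survival_at(t)
        return s0 ** np.exp(self.linear_predictor(covariates))

    def summary(self) -> str:
        z = self.coefficients / self.standard_errors
        pvals = 2 * sps.norm.sf(np.abs(z))
        lines = [
            "Cox proportional hazards (Breslow ties)",
            "=" * 66,
            f"{'covariate':<22s} {'coef':>9s} {'HR':>9s} {'se':>8s} {'z':>7s} {'p':>8s}",
            "-" * 66,
        ]
        for name, p in zip(self.coefficients.index, pvals):
            b = self.coefficients[name]
            se = self.standard_errors[name]
            lines.append(
                f"{name:<22s} {b:>9.4f} {np.exp(b):>9.4f} {se:>8.4f} "
                f"{b / se:>7.2f} {p:>8.4f}")
        return "\n".join(lines)


def fit_cox(covariates: pd.DataFrame, surv) -> CoxResults:
    """Fit a Breslow-tie multivariable Cox model (see module docstring)."""
    time, event = _surv_arrays(surv)
    return ProportionalHazardsModel(code_clinical(covariates), time, event).fit()


# ---------------------------------------------------------------------------
# nomogram
# ---------------------------------------------------------------------------

@dataclass
class Nomogram:
    """Point-based rendering of a Cox model.

    Each covariate maps linearly to points in [0, 100]; the covariate with
    the largest |beta| * range spans exactly 0-100.  Total points map back
    to the linear predictor and hence to survival probabilities at the
    requested horizons through the Breslow baseline.
    """

    results: CoxResults
    value_ranges: dict[str, tuple[float, float]]
    horizons: tuple[float, ...] = (18.0, 36.0)
    scale: float = field(init=False)
    reference: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        beta = self.results.coefficients
        spans = {}
        self.reference = {}
        for name, b in beta.items():
            lo, hi = self.value_ranges[name]
            if hi < lo:
                raise ValueError(f"invalid range for {name}")
            if hi == lo and b != 0:
                raise ValueError(f"zero range for covariate {name} with beta != 0")
            spans[name] = abs(b) * (hi - lo)
            self.reference[name] = lo if b >= 0 else hi  # minimum-contribution end
        self.scale = max(spans.values())
        if self.scale <= 0:
            raise ValueError("all covariates have zero contribution range")

    def points(self, name: str, value) -> np.ndarray | float:
        """Points awarded for covariate ``name`` at ``value`` (0..100)."""
        b = self.results.coefficients[name]
        return 100.0 * b * (np.asarray(value, dtype=float) - self.reference[name]) / self.scale

    def total_points(self, covariates: pd.DataFrame) -> np.ndarray:
        tp = np.zeros(len(covariates))
        for name in self.results.coefficients.index:
            tp = tp + self.points(name, covariates[name].to_numpy())
        return tp

    def linear_predictor_from_points(self, total: np.ndarray | float) -> np.ndarray | float:
        offset = sum(
            self.results.coefficients[n] * self.reference[n]
            for n in self.results.coefficients.index
        )
        return np.asarray(total, dtype=float) * self.scale / 100.0 + offset

    def survival_from_points(self, total, t: float) -> np.ndarray | float:
        s0 = self.results.baseline_survival_at(t)
        return s0 ** np.exp(self.linear_predictor_from_points(total))

    def to_table(self, n_ticks: int = 11) -> pd.DataFrame:
        """Point table: tick values and their points for every covariate."""
        rows = []
        for name in self.results.coefficients.index:
            lo, hi = self.value_ranges[name]
            ticks = np.linspace(lo, hi, n_ticks) if hi > lo else np.array([lo])
            for v in ticks:
                rows.append({"variable": name, "value": float(v),
                             "points": float(self.points(name, v))})
        return pd.DataFrame(rows)


def build_nomogram(results: CoxResults,
                   value_ranges: dict[str, tuple[float, float]],
                   horizons: tuple[float, ...] = (18.0, 36.0)) -> Nomogram:
    """Build the point mapping of a fitted Cox model over covariate ranges."""
    missing = [n for n in results.coefficients.index if n not in value_ranges]
    if missing:
        raise ValueError(f"value_ranges lacks {missing}")
    return Nomogram(results, value_ranges, horizons)


# ---------------------------------------------------------------------------
# time-dependent ROC (nearest-neighbor estimator)
# ---------------------------------------------------------------------------

def default_nne_span(n: int) -> float:
    """Default smoothing span 0.25 * n**-0.2 of the NNE bivariate estimator."""
    return 0.25 * n ** (-0.20)


@dataclass
class TimeROC:
    """Cumulative-case/dynamic-control ROC at one horizon."""

    horizon: float
    cutpoints: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    span: float


def _nne_conditional_survival(marker: np.ndarray, time: np.ndarray,
                              event: np.ndarray, t: float, span: float) -> np.ndarray:
    """S(t | marker_i) by a nearest-neighbor weighted Kaplan-Meier.

    The neighborhood of patient i is the 2*lambda*n patients nearest in
    marker rank (a rank-based box kernel), making the estimator invariant
    under strictly monotone marker transforms.
    """
    n = len(marker)
    ranks = sps.rankdata(marker, method="average") / n
    surv = np.empty(n)
    for i in range(n):
        w = (np.abs(ranks - ranks[i]) <= span).astype(float)
        surv[i] = _weighted_km_at(time, event, w, t)
    return surv


def _weighted_km_at(time: np.ndarray, event: np.ndarray, w: np.ndarray,
                    t: float) -> float:
    sel = w > 0
    ts, ds, ws = time[sel], event[sel], w[sel]
    order = np.argsort(ts, kind="stable")
    ts, ds, ws = ts[order], ds[order], ws[order]
    at_risk = np.cumsum(ws[::-1])[::-1]
    s = 1.0
    i = 0
    n = len(ts)
    while i < n and ts[i] <= t:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        dw = ws[i:j][ds[i:j] == 1].sum()
        if dw > 0 and at_risk[i] > 0:
            s *= max(0.0, 1.0 - dw / at_risk[i])
        i = j
    return s


def timedep_auc_nne(marker, surv, t: float, span: float | None = None) -> TimeROC:
    """Time-dependent ROC at horizon ``t`` (months) via the NNE estimator.

    Cases are cumulative (event by t), controls dynamic (event-free at t);
    censoring before t is handled through the smoothed bivariate survival
    function S(c, t) = P(marker > c, T > t).  AUC by trapezoid.
    """
    time, event = _surv_arrays(surv)
    marker = np.asarray(marker, dtype=float)
    n = len(marker)
    if span is None:
        span = default_nne_span(n)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if event[time <= t].sum() == 0:
        raise ValueError(f"no events by t = {t}; ROC undefined")

    cond_surv = _nne_conditional_survival(marker, time, event, t, span)
    s_marg = float(cond_surv.mean())
    if s_marg >= 1.0:
        raise ValueError("event probability by t is zero")
    if s_marg <= 0.0:
        raise ValueError(f"no event-free patients at t = {t}; ROC undefined")

    cuts = np.unique(marker)
    # thresholds between observed values plus extremes
    cutpoints = np.concatenate([[-np.inf], (cuts[:-1] + cuts[1:]) / 2, [np.inf]])
    sens = np.empty(len(cutpoints))
    spec = np.empty(len(cutpoints))
    for k, c in enumerate(cutpoints):
        above = marker > c
        s_joint = float(cond_surv[above].sum()) / n
        p_above = float(above.mean())
        sens[k] = (p_above - s_joint) / (1.0 - s_marg)
        spec[k] = 1.0 - s_joint / s_marg
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ascending FPR, ties by ascending TPR
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return TimeROC(float(t), cutpoints, sens, spec, auc, float(span))


# ---------------------------------------------------------------------------
# DeLong comparison of two markers
# ---------------------------------------------------------------------------

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values (ties count 1/2)."""
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v_pos = wins.mean(axis=1)  # V10
    v_neg = wins.mean(axis=0)  # V01
    return float(wins.mean()), v_pos, v_neg


def delong_compare(marker_a, marker_b, label) -> tuple[float, float, float]:
    """Paired DeLong test comparing the AUCs of two markers.

    ``label`` is the binary outcome (1 = case).  Returns
    (auc_a, auc_b, two-sided p).  Identical markers (or zero variance of
    the difference with equal AUCs) return p = 1 by convention.
    """
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    y = np.asarray(label, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("label must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    pos, neg = y == 1, y == 0
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    auc_a, va_pos, va_neg = _placements(a[pos], a[neg])
    auc_b, vb_pos, vb_neg = _placements(b[pos], b[neg])
    m, n = int(pos.sum()), int(neg.sum())
    s10 = np.cov(np.vstack([va_pos, vb_pos]))  # 2x2
    s01 = np.cov(np.vstack([va_neg, vb_neg]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + \
          (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    d = auc_a - auc_b
    if var <= 0:
        if abs(d) < 1e-12:
            return auc_a, auc_b, 1.0
        raise ValueError("degenerate DeLong variance with distinct AUCs")
    z = d / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return auc_a, auc_b, p


# ---------------------------------------------------------------------------
# calibration + Hosmer-Lemeshow
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Risk-binned observed vs predicted event probabilities at a horizon."""

    horizon: float
    bins: pd.DataFrame  # columns: n, mean_predicted, observed
    hl_chi2: float
    hl_p: float


def hosmer_lemeshow(observed: np.ndarray, predicted: np.ndarray,
                    counts: np.ndarray) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square over g bins with g - 2 df."""
    e = np.clip(np.asarray(predicted, dtype=float), 1e-10, 1 - 1e-10)
    o = np.asarray(observed, dtype=float)
    n = np.asarray(counts, dtype=float)
    chi2 = float((n * (o - e) ** 2 / (e * (1 - e))).sum())
    df = max(len(n) - 2, 1)
    return chi2, float(sps.chi2.sf(chi2, df))


def calibration(predicted, surv, t: float, min_bin: int = 10) -> CalibrationResult:
    """Observed-vs-predicted event probabilities at horizon ``t``.

    ``predicted`` are per-patient event probabilities by ``t`` (i.e.
    1 - S(t|x)).  Patients are sorted by prediction and split into at most
    10 bins of at least ``min_bin`` patients; observed event probability
    per bin is 1 - KM(t) within the bin (handles censoring).
    """
    time, event = _surv_arrays(surv)
    pred = np.asarray(predicted, dtype=float)
    if ((pred < 0) | (pred > 1)).any():
        raise ValueError("predictions must be probabilities in [0, 1]")
    n = len(pred)
    if n < 2 * min_bin:
        raise ValueError(f"need at least {2 * min_bin} patients, got {n}")
    g = min(10, n // min_bin)
    order = np.argsort(pred, kind="stable")
    rows = []
    for chunk in np.array_split(order, g):
        km = kaplan_meier((time[chunk], event[chunk]))
        observed = 1.0 - float(km.predict(t))
        rows.append({
            "n": len(chunk),
            "mean_predicted": float(pred[chunk].mean()),
            "observed": observed,
        })
    bins = pd.DataFrame(rows)
    chi2, p = hosmer_lemeshow(bins["observed"].to_numpy(),
                              bins["mean_predicted"].to_numpy(),
                              bins["n"].to_numpy())
    return CalibrationResult(float(t), bins, chi2, p)
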