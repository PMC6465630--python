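"""Synthetic inputs for every pipeline stage: phantoms, raters, cohorts.

No patient CT data is distributed with studies of this kind, so the test
bed is built from three generators, each a pure function of its spec and
seed:

* textured ellipsoidal tumor phantoms whose interior is a Gaussian random
  field — the correlation length of the field (long for ``smooth``, short
  for ``rough``) provably orders GLCM contrast, giving a checkable link
  from image construction to feature behaviour;
* dual-rater masks derived from the true mask by independent boundary
  perturbations calibrated to a target discrepancy;
* survival cohorts from a Weibull proportional-hazards model with known
  coefficients and uniform administrative censoring over a follow-up
  window emulating an 18.8-81.8 month study horizon, plus clinical
  covariates drawn to match the pooled marginals of the study population
  (FIGO III 79%, menopause 71%, complete resection 42%, postoperative
  CA-125 <= 35 U/mL 54%, unilateral 50%; age and preoperative CA-125
  log-normal around medians 50 years and 713.6 U/mL).

The Weibull baseline (shape 1.5) is scaled so the median event time at a
zero linear predictor is ~18 months, the commonly quoted median PFS of
advanced HGSOC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import ContingencyTable
from .signature import Cohort, SurvivalRecord
from .volume_io import ImageVolume, ROIMask, RaterPair, mask_discrepancy

__all__ = [
    "PhantomSpec",
    "SimCohortSpec",
    "generate_phantom",
    "simulate_cohort",
    "simulate_clinical",
    "fixture_tables",
    "CLINICAL_MARGINALS",
]

#: Pooled binary marginals of the study population (probability of code 1).
CLINICAL_MARGINALS = {
    "figo_stage": 0.21,    # 1 = FIGO IV
    "postop_ca125": 0.46,  # 1 = > 35 U/mL
    "residual": 0.58,      # 1 = > 0 cm residual tumor
    "tumor_side": 0.50,    # 1 = bilateral
    "menopause": 0.29,     # 1 = premenopausal
}

#: Log-normal parameters (mu, sigma of log) fitted to printed median/IQR.
_AGE_LOGNORM = (np.log(50.0), np.log(57.0 / 44.5) / 1.349)
_CA125_LOGNORM = (np.log(713.6), np.log(2179.8 / 401.9) / 1.349)


@dataclass
class PhantomSpec:
    """Recipe for one textured tumor phantom."""

    shape: tuple[int, int, int] = (16, 16, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] | None = None
    semi_axes: tuple[float, float, float] = (6.0, 5.0, 4.0)
    texture_class: str = "smooth"  # 'smooth' (long correlation) or 'rough'
    tumor_mean: float = 40.0       # HU
    tumor_sd: float = 20.0         # HU, texture amplitude
    background: float = -50.0      # HU
    noise_sd: float = 2.0          # additive scanner-like noise, HU
    rater_discrepancy: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_class not in ("smooth", "rough"):
            raise ValueError("texture_class must be 'smooth' or 'rough'")
        if self.center is None:
            self.center = tuple((s - 1) / 2.0 for s in self.shape)
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        for c, a, s in zip(self.center, self.semi_axes, self.shape):
            if c - a < -0.5 or c + a > s - 0.5:
                raise ValueError("tumor ellipsoid exceeds the grid")


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape).astype(np.float64)
    q = sum(
        ((idx[a] - spec.center[a]) / spec.semi_axes[a]) ** 2 for a in range(3)
    )
    return q <= 1.0


def _gaussian_random_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _perturb_mask(mask: np.ndarray, n_flip: int, rng: np.random.Generator) -> np.ndarray:
    """Flip ``n_flip`` voxels in the boundary shell (inside or just outside)."""
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    shell = np.argwhere(inner | outer)
    n_flip = min(n_flip, len(shell) - 1)
    out = mask.copy()
    if n_flip > 0:
        pick = rng.choice(len(shell), size=n_flip, replace=False)
        for i, j, k in shell[pick]:
            out[i, j, k] = ~out[i, j, k]
    if not out.any():
        return mask.copy()
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ROIMask, RaterPair]:
    """Textured ellipsoidal tumor on a flat background, plus rater masks.

    Deterministic given the spec (including its seed).  Rater masks are the
    true mask with independent random boundary flips, the flip count chosen
    so the pair discrepancy lands within ~0.01 of
    ``spec.rater_discrepancy``.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec)
    sigma = 2.5 if spec.texture_class == "smooth" else 0.6
    texture = _gaussian_random_field(spec.shape, sigma, rng)
    vox = np.full(spec.shape, spec.background, dtype=np.float64)
    vox[mask] = spec.tumor_mean + spec.tumor_sd * texture[mask]
    vox += spec.noise_sd * rng.standard_normal(spec.shape)

    volume = ImageVolume(vox, spec.spacing)
    roi = ROIMask(mask, spec.spacing)

    # calibrate the flip count to the requested rater discrepancy
    target = spec.rater_discrepancy
    best_pair, best_err = None, np.inf
    for n_flip in range(0, int(mask.sum()) + 1):
        sub = np.random.default_rng(rng.integers(2**31))
        a = _perturb_mask(mask, n_flip, sub)
        b = _perturb_mask(mask, n_flip, sub)
        pair = RaterPair(ROIMask(a, spec.spacing), ROIMask(b, spec.spacing))
        err = abs(pair.discrepancy - target)
        if err < best_err:
            best_pair, best_err = pair, err
        if pair.discrepancy > target + 0.01 and n_flip > 2:
            break
    return volume, roi, best_pair


@dataclass
class SimCohortSpec:
    """Recipe for a simulated survival cohort with known hazard structure."""

    n: int = 100
    beta: dict[str, float] = field(default_factory=dict)
    n_features: int = 10
    feature_correlation: float = 0.2
    weibull_shape: float = 1.5
    weibull_scale: float | None = None  # months; default: median 18 at lp=0
    censor_window: tuple[float, float] = (18.8, 81.8)  # months
    label: str = "TC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.weibull_scale is None:
            self.weibull_scale = 18.0 / np.log(2.0) ** (1.0 / self.weibull_shape)
        if self.weibull_scale <= 0:
            raise ValueError("scale must be positive")
        lo, hi = self.censor_window
        if not lo < hi:
            raise ValueError("censor window must satisfy low < high")


def simulate_cohort(spec: SimCohortSpec) -> Cohort:
    """Correlated-normal features, Weibull PH event times, uniform censoring.

    Event times follow S(t | x) = exp(-(t/scale)^shape * exp(x beta));
    censoring is administrative, uniform over ``censor_window`` (an
    infinite upper bound yields no censoring).
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"f{i:03d}" for i in range(spec.n_features)]
    unknown = set(spec.beta) - set(names)
    if unknown:
        raise ValueError(f"beta refers to unknown features {sorted(unknown)}")
    rho = spec.feature_correlation
    cov = np.full((spec.n_features, spec.n_features), rho) + (1 - rho) * np.eye(spec.n_features)
    X = rng.multivariate_normal(np.zeros(spec.n_features), cov, size=spec.n,
                                method="cholesky")
    features = pd.DataFrame(X, columns=names)
    beta = np.array([spec.beta.get(nm, 0.0) for nm in names])
    lp = X @ beta

    E = rng.exponential(size=spec.n)
    T = spec.weibull_scale * (E / np.exp(lp)) ** (1.0 / spec.weibull_shape)
    lo, hi = spec.censor_window
    if np.isinf(hi):
        C = np.full(spec.n, np.inf)
    else:
        C = rng.uniform(lo, hi, size=spec.n)
    event = (T <= C).astype(int)
    time = np.where(event == 1, T, C)
    time = np.maximum(time, 1e-6)  # guard: strictly positive follow-up

    records = [SurvivalRecord(float(t), int(e)) for t, e in zip(time, event)]
    return Cohort(records, features, spec.label)


def simulate_clinical(n: int, seed: int = 0) -> pd.DataFrame:
    """Clinical covariate table with the study population's marginals.

    Binary covariates use the pooled study marginals
    (:data:`CLINICAL_MARGINALS`, 0/1 coding of
    :data:`radsurv.prognostic.CLINICAL_CUT_RULES`); age and preoperative
    CA-125 are log-normal fits to the printed median/IQR.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    rng = np.random.default_rng(seed)
    out = {"age": np.round(np.exp(rng.normal(*_AGE_LOGNORM, size=n))).astype(int),
           "preop_ca125": np.round(np.exp(rng.normal(*_CA125_LOGNORM, size=n)), 1)}
    for name, p1 in CLINICAL_MARGINALS.items():
        out[name] = (rng.random(n) < p1).astype(int)
    return pd.DataFrame(out)


def fixture_tables() -> dict[str, ContingencyTable]:
    """The printed categorical contingency tables of the study cohorts.

    2x2 tables cross each dichotomized covariate with recurrence over all
    142 patients; the 2x3 tables cross covariates with the three cohorts
    (training n=50, internal validation n=50, external validation n=42).
    """
    def t(counts, rows, cols):
        return ContingencyTable(np.array(counts), tuple(rows), tuple(cols))

    rec = ("recurrence", "no recurrence")
    coh = ("TC", "IVC", "IEVC")
    return {
        "postop_ca125_by_recurrence": t([[34, 42], [47, 19]],
                                        ("<=35", ">35"), rec),
        "figo_by_recurrence": t([[58, 54], [23, 7]], ("III", "IV"), rec),
        "residual_by_recurrence": t([[34, 26], [47, 35]], ("=0", ">0"), rec),
        "side_by_recurrence": t([[43, 28], [38, 33]],
                                ("unilateral", "bilateral"), rec),
        "menopause_by_recurrence": t([[59, 42], [22, 19]],
                                     ("menopause", "premenopausal"), rec),
        "recurrence_by_cohort": t([[20, 29, 32], [30, 21, 10]],
                                  ("yes", "no"), coh),
        "postop_ca125_by_cohort": t([[25, 28, 23], [25, 22, 19]],
                                    ("<=35", ">35"), coh),
        "figo_by_cohort": t([[43, 41, 28], [7, 9, 14]], ("III", "IV"), coh),
        "residual_by_cohort": t([[12, 14, 8], [38, 36, 34]], ("=0", ">0"), coh),
        "side_by_cohort": t([[23, 20, 23], [27, 30, 19]],
                            ("unilateral", "bilateral"), coh),
        "menopause_by_cohort": t([[37, 33, 31], [13, 17, 11]],
                                 ("menopause", "premenopausal"), coh),
    }
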