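"""First-order (histogram) statistics of the masked intensities.

17 features.  Entropy and uniformity are computed on the equal-width
discretization of :func:`radsurv.features.discretize`.  The "standard"
variants are computed after z-scoring the intensities and binning them on a
fixed [-4, 4] grid (values clipped), so that — unlike the plain variants,
whose min-max binning is affine-invariant — they respond to distribution
shape on a standardized scale.  Mass is the summed intensity of the region.

Degenerate-region sentinels (constant ROI): variance/skewness/kurtosis and
both entropies are 0, uniformity is 1.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize

__all__ = ["HISTOGRAM_FEATURES", "histogram_features"]

HISTOGRAM_FEATURES = (
    "Energy",
    "Entropy",
    "Standard_entropy",
    "Kurtosis",
    "Maximum",
    "Mean",
    "Mean_absolute_deviation",
    "Median",
    "Minimum",
    "Mass",
    "Range",
    "Root_mean_square",
    "Skewness",
    "Standard_deviation",
    "Uniformity",
    "Standard_uniformity",
    "Variance",
)

_ZSCORE_RANGE = 4.0


def _probabilities(levels: np.ndarray, ng: int) -> np.ndarray:
    counts = np.bincount(levels, minlength=ng + 1)[1:]
    return counts / counts.sum()


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _zscore_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        p = np.zeros(n_bins)
        p[0] = 1.0
        return p
    z = np.clip((x - x.mean()) / sd, -_ZSCORE_RANGE, np.nextafter(_ZSCORE_RANGE, -np.inf))
    idx = np.floor((z + _ZSCORE_RANGE) / (2 * _ZSCORE_RANGE) * n_bins).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return counts / counts.sum()


def histogram_features(
    image: np.ndarray, mask: np.ndarray, n_bins: int = 32
) -> dict[str, float]:
    """The 17 first-order features over the masked intensities."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(image, dtype=np.float64)[mask]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = float(np.sqrt(var))
    if var > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / sd**3
        kurt = m4 / var**2  # non-excess (normal -> 3)
    else:
        skew = 0.0
        kurt = 0.0

    droi = discretize(image, mask, n_bins)
    p = _probabilities(droi.levels, droi.ng)
    pz = _zscore_probs(x, n_bins)

    return {
        "Energy": float((x**2).sum()),
        "Entropy": _entropy(p),
        "Standard_entropy": _entropy(pz),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Mass": float(x.sum()),
        "Range": float(x.max() - x.min()),
        "Root_mean_square": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Standard_deviation": sd,
        "Uniformity": float((p**2).sum()),
        "Standard_uniformity": float((pz**2).sum()),
        "Variance": var,
    }
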