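"""Assembly of the full 620-feature vector per tumor.

Feature names follow the pattern ``{image}__{family}__{feature}`` with
``image`` one of ``Original`` or ``Coiflet_<subband>`` for the 8 stationary
Coiflet-1 subbands.  Shape features are mask-only and appear once, under
``Original``.  The order is fixed: Original histogram, Original shape,
Original GLCM/GLSZM/GLRLM/NGTDM, then the same minus shape for each
subband in the canonical LLL..HHH order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..volume_io import ImageVolume, ROIMask
from ..wavelet3d import SUBBAND_LABELS, swt3
from .discretize import discretize
from .firstorder import HISTOGRAM_FEATURES, histogram_features
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["FEATURE_NAMES", "FAMILY_COUNTS", "feature_names", "extract_all"]

logger = logging.getLogger(__name__)

FAMILY_COUNTS = {
    "Histogram": 17,
    "Shape": 8,
    "GLCM": 22,
    "GLSZM": 13,
    "GLRLM": 11,
    "NGTDM": 5,
}

_TEXTURE_FAMILIES = (
    ("GLCM", GLCM_FEATURES),
    ("GLSZM", GLSZM_FEATURES),
    ("GLRLM", GLRLM_FEATURES),
    ("NGTDM", NGTDM_FEATURES),
)


def feature_names() -> list[str]:
    """The canonical ordered names of the 620-feature panel."""
    names: list[str] = []
    for img in ("Original", *(f"Coiflet_{s}" for s in SUBBAND_LABELS)):
        names += [f"{img}__Histogram__{f}" for f in HISTOGRAM_FEATURES]
        if img == "Original":
            names += [f"Original__Shape__{f}" for f in SHAPE_FEATURES]
        for fam, feats in _TEXTURE_FAMILIES:
            names += [f"{img}__{fam}__{f}" for f in feats]
    return names


FEATURE_NAMES: list[str] = feature_names()
assert len(FEATURE_NAMES) == 620


def _image_block(image: np.ndarray, mask: np.ndarray, prefix: str,
                 n_bins: int) -> dict[str, float]:
    out = {}
    for name, v in histogram_features(image, mask, n_bins).items():
        out[f"{prefix}__Histogram__{name}"] = v
    droi = discretize(image, mask, n_bins)
    for fam, fn in (("GLCM", glcm_features), ("GLSZM", glszm_features),
                    ("GLRLM", glrlm_features), ("NGTDM", ngtdm_features)):
        for name, v in fn(droi).items():
            out[f"{prefix}__{fam}__{name}"] = v
    return out


def _crop_to_mask(image: np.ndarray, mask: np.ndarray, margin: int = 1
                  ) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image[sl], mask[sl]


def extract_all(volume: ImageVolume, mask: ROIMask, n_bins: int = 32) -> pd.Series:
    """Extract the full 620-feature panel for one tumor.

    The volume and mask must already live on the pipeline's common grid.
    The wavelet transform runs on the full volume (so filter support is not
    truncated at the ROI box); masked statistics are then taken per subband.
    Returns a :class:`pandas.Series` indexed by :data:`FEATURE_NAMES`.
    """
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share one grid")
    if not mask.voxels.any():
        raise ValueError("mask is empty")

    values: dict[str, float] = {}
    img0, msk0 = _crop_to_mask(volume.voxels, mask.voxels)
    values.update(_image_block(img0, msk0, "Original", n_bins))
    for name, v in shape_features(mask.voxels, volume.spacing).items():
        values[f"Original__Shape__{name}"] = v

    subbands = swt3(volume)
    for label in SUBBAND_LABELS:
        img, msk = _crop_to_mask(subbands[label], mask.voxels)
        values.update(_image_block(img, msk, f"Coiflet_{label}", n_bins))

    vec = pd.Series(values, dtype=np.float64).reindex(FEATURE_NAMES)
    bad = vec.index[~np.isfinite(vec.to_numpy())]
    if len(bad):
        logger.warning("non-finite features clamped to 0: %s", list(bad))
        vec[bad] = 0.0
    return vec
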