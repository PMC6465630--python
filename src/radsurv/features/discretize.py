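"""Gray-level discretization of a masked region.

Texture matrices operate on a small number of discrete gray levels.  We use
a fixed number of equal-width bins spanning the min-max of the masked
intensities of the image at hand (original image and each wavelet subband
are discretized separately).  A constant region degenerates to a single
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedROI", "discretize"]


@dataclass
class DiscretizedROI:
    """Integer gray levels (1..ng) over a mask, plus the binning used.

    ``level_map`` is a full-grid int array with 0 outside the mask; ``ng``
    is the nominal number of gray levels (1 for a constant region).
    """

    level_map: np.ndarray
    mask: np.ndarray
    ng: int
    bin_edges: np.ndarray

    @property
    def levels(self) -> np.ndarray:
        """Levels of the masked voxels only (1..ng)."""
        return self.level_map[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(image: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> DiscretizedROI:
    """Bin masked intensities into ``n_bins`` equal-width gray levels.

    Bin i (level i+1) covers [min + i*w, min + (i+1)*w) with
    w = (max - min)/n_bins; the maximum value falls in the last bin.  A
    constant region yields a single level (ng = 1).
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    image = np.asarray(image, dtype=np.float64)
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())

    level_map = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        level_map[mask] = 1
        return DiscretizedROI(level_map, mask, 1, np.array([lo, hi]))

    width = (hi - lo) / n_bins
    lev = np.floor((vals - lo) / width).astype(np.int32)
    np.clip(lev, 0, n_bins - 1, out=lev)
    level_map[mask] = lev + 1
    edges = lo + width * np.arange(n_bins + 1)
    return DiscretizedROI(level_map, mask, n_bins, edges)
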