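"""Single-level stationary (undecimated) 3-D Coiflet-1 wavelet filtering.

The eight subbands LLL ... HHH are obtained by convolving the volume along
each axis with either the low-pass (L, scaling) or high-pass (H, wavelet)
Coiflet-1 filter.  The transform is undecimated, so every subband has the
shape of the input and the tumor mask applies to each subband unchanged —
wavelet-domain histogram/texture features are computed over the same voxels
as the original-image features.

Conventions
-----------
* Letter order: the first letter selects the x-axis filter, the last the
  z-axis (slice) filter.  ``LHL`` therefore means low-pass along x,
  high-pass along y, low-pass along z.
* Boundary handling: symmetric (mirror) extension, which avoids the edge
  ramps a zero-padded transform would create inside small tumors.
* ``iswt3`` inverts the transform exactly (to floating-point precision) by
  solving the least-squares normal equations of the per-axis analysis
  operators; a plain adjoint average is not exact at the boundary for the
  asymmetric Coiflet filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

from .volume_io import ImageVolume

__all__ = ["SUBBAND_LABELS", "WaveletSubbands", "coiflet1_filters", "swt3", "iswt3"]

SUBBAND_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass
class WaveletSubbands:
    """The 8 same-shaped subband images of one volume."""

    subbands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.subbands) != set(SUBBAND_LABELS):
            raise ValueError(f"expected labels {SUBBAND_LABELS}")
        shapes = {s.shape for s in self.subbands.values()}
        if len(shapes) != 1:
            raise ValueError("all subbands must share one shape")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.subbands[label]

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.subbands.values())).shape


def coiflet1_filters() -> tuple[np.ndarray, np.ndarray]:
    """The 6-tap Coiflet-1 decomposition pair (low-pass, high-pass).

    The pair satisfies the quadrature-mirror relation
    ``g[k] = (-1)**k * h[N-1-k]``; the low-pass taps sum to sqrt(2) and have
    unit energy, the high-pass taps sum to 0.
    """
    w = pywt.Wavelet("coif1")
    h = np.asarray(w.dec_lo, dtype=np.float64)
    n = len(h)
    g = np.array([(-1) ** k * h[n - 1 - k] for k in range(n)])
    return h, g


def _convolve_matrix(n: int, taps: tuple[float, ...]) -> np.ndarray:
    """n x n matrix of 'symmetric-pad then centered linear convolution'."""
    f = np.asarray(taps)
    p = len(f)
    off = (len(f) - 1) // 2
    mat = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        ext = np.pad(e, p, mode="symmetric")
        full = np.convolve(ext, f)
        mat[:, j] = full[p + off : p + off + n]
    return mat


@lru_cache(maxsize=64)
def _axis_operators(n: int) -> dict[str, np.ndarray]:
    """Analysis matrices L, H and exact reconstruction matrices for length n."""
    h, g = coiflet1_filters()
    L = _convolve_matrix(n, tuple(h))
    H = _convolve_matrix(n, tuple(g))
    gram = L.T @ L + H.T @ H  # well-conditioned: ~2I away from boundary
    BL = np.linalg.solve(gram, L.T)
    BH = np.linalg.solve(gram, H.T)
    return {"L": L, "H": H, "BL": BL, "BH": BH}


def _apply_axis(arr: np.ndarray, mat: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(arr, axis, 0)
    out = np.tensordot(mat, moved, axes=(1, 0))
    return np.moveaxis(out, 0, axis)


def swt3(volume: ImageVolume | np.ndarray) -> WaveletSubbands:
    """Single-level stationary Coiflet-1 transform of a 3-D volume.

    Returns the 8 subbands, each with the input's shape.  Requires every
    axis to be at least as long as the 6-tap filter.
    """
    arr = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(
        volume, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("swt3 expects a 3-D array")
    h, _ = coiflet1_filters()
    if min(arr.shape) < len(h):
        raise ValueError(
            f"every axis must have >= {len(h)} voxels, got shape {arr.shape}")

    ops = [_axis_operators(n) for n in arr.shape]
    # separable filter tree: x, then y, then z
    level: dict[str, np.ndarray] = {"": arr}
    for axis in range(3):
        nxt: dict[str, np.ndarray] = {}
        for label, data in level.items():
            for letter in "LH":
                nxt[label + letter] = _apply_axis(
                    data, ops[axis][letter], axis)
        level = nxt
    return WaveletSubbands(level)


def iswt3(subbands: WaveletSubbands) -> np.ndarray:
    """Exact inverse of :func:`swt3` (max-abs error ~1e-12 on float data)."""
    shape = subbands.shape
    ops = [_axis_operators(n) for n in shape]
    level = dict(subbands.subbands)
    for axis in (2, 1, 0):
        nxt: dict[str, np.ndarray] = {}
        prefixes = sorted({lab[:axis] for lab in level})
        for pre in prefixes:
            lo = level[pre + "L"]
            hi = level[pre + "H"]
            nxt[pre] = _apply_axis(lo, ops[axis]["BL"], axis) + _apply_axis(
                hi, ops[axis]["BH"], axis)
        level = nxt
    return level[""]
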