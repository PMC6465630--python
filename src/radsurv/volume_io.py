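"""Volume and mask I/O, spacing normalisation, and the dual-rater mask protocol.

Conventions used throughout the package
---------------------------------------
* Voxel arrays are ordered ``(x, y, z)`` with ``z`` the slice axis.  File
  readers transpose from the scanner/file order so that ``voxels[i, j, k]``
  sits at physical position ``origin + (i*sx, j*sy, k*sz)``.
* Coordinates refer to voxel centers, 0-based.
* Spacing is in millimetres, one value per axis.

All cases of a study are resampled onto the per-axis minimum spacing of the
dataset before feature extraction, mirroring the common practice of
normalising heterogeneous CT acquisitions to one physical resolution.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "ROIMask",
    "RaterPair",
    "VolumeFormatError",
    "VolumeMetadataError",
    "AdjudicationRequiredError",
    "read_volume",
    "read_mask",
    "write_volume",
    "dataset_min_spacing",
    "resample_to_spacing",
    "mask_discrepancy",
    "merge_masks",
]

logger = logging.getLogger(__name__)

#: Resampling to a spacing coarser than this factor times the source spacing
#: is allowed but logged, since it discards most of the image information.
COARSENING_GUARD_FACTOR = 10.0


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a 3-D scalar volume."""


class VolumeMetadataError(ValueError):
    """Raised when required geometric metadata (spacing) is absent/invalid."""


class AdjudicationRequiredError(ValueError):
    """Raised when rater masks disagree beyond the merge threshold and no
    adjudicated mask was supplied."""


@dataclass
class ImageVolume:
    """A 3-D scalar image (CT, in Hounsfield units) with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities, axis order ``(x, y, z)``.
    spacing : tuple of float
        Per-axis voxel spacing in mm; all components > 0.
    origin : tuple of float
        Physical coordinate of voxel ``(0, 0, 0)``, mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D volume, got {self.voxels.ndim} dimensions"
            )
        if min(self.voxels.shape) < 2:
            raise VolumeFormatError("each axis needs at least 2 voxels")
        if not np.all(np.isfinite(self.voxels)):
            raise VolumeFormatError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeMetadataError(f"invalid spacing {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """A binary tumor mask on the same grid as its parent :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise VolumeFormatError("mask must be 3-D")
        if not self.voxels.any():
            raise ValueError("mask has no foreground voxels")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class RaterPair:
    """Two independent delineations of one tumor and their disagreement."""

    mask_a: ROIMask
    mask_b: ROIMask
    discrepancy: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mask_a.shape != self.mask_b.shape:
            raise ValueError("rater masks must share one grid")
        self.discrepancy = mask_discrepancy(self.mask_a, self.mask_b)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _from_sitk(img: sitk.Image) -> ImageVolume:
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"only 3-D volumes are supported, file has {img.GetDimension()} dimensions"
        )
    # NIfTI stores pixdim in float32; round away the cast so realistic mm
    # spacings (0.7, 2.0, ...) survive a write/read cycle exactly
    spacing = tuple(round(s, 6) for s in img.GetSpacing())  # sitk order (x, y, z)
    if any(s <= 0 for s in spacing):
        raise VolumeMetadataError(f"non-positive spacing in header: {spacing}")
    # GetArrayFromImage returns (z, y, x); transpose to the package (x, y, z).
    arr = sitk.GetArrayFromImage(img).astype(np.float64)
    if arr.ndim != 3:  # e.g. a multi-frame/vector NIfTI read as 3-D + components
        raise VolumeFormatError(
            f"only scalar 3-D volumes are supported, got array of ndim {arr.ndim}")
    arr = arr.transpose(2, 1, 0)
    return ImageVolume(arr, spacing, img.GetOrigin())


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI/NRRD file or a DICOM series directory as an :class:`ImageVolume`.

    Intensities are returned as stored (HU for CT); spacing and origin come
    from the header.  Axis order of the returned array is ``(x, y, z)``.
    """
    path = os.fspath(path)
    try:
        if os.path.isdir(path):
            reader = sitk.ImageSeriesReader()
            fnames = reader.GetGDCMSeriesFileNames(path)
            if not fnames:
                raise VolumeFormatError(f"no DICOM series found in {path!r}")
            reader.SetFileNames(fnames)
            img = reader.Execute()
        else:
            info = sitk.ImageFileReader()
            info.SetFileName(path)
            info.ReadImageInformation()
            if info.GetDimension() != 3:  # sitk would silently take one frame
                raise VolumeFormatError(
                    f"only 3-D volumes are supported, {path!r} has "
                    f"{info.GetDimension()} dimensions")
            img = sitk.ReadImage(path)
    except VolumeFormatError:
        raise
    except RuntimeError as exc:  # sitk wraps every ITK failure in RuntimeError
        raise VolumeFormatError(f"cannot read {path!r}: {exc}") from exc
    return _from_sitk(img)


def read_mask(path: str | os.PathLike, threshold: float = 0.5) -> ROIMask:
    """Read a binary mask; values > ``threshold`` are foreground."""
    vol = read_volume(path)
    return ROIMask(vol.voxels > threshold, vol.spacing, vol.origin)


def write_volume(volume: ImageVolume | ROIMask, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI/NRRD (format chosen by extension)."""
    arr = np.asarray(volume.voxels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, os.fspath(path))


# ---------------------------------------------------------------------------
# spacing normalisation
# ---------------------------------------------------------------------------

def dataset_min_spacing(volumes: Iterable[ImageVolume]) -> tuple[float, float, float]:
    """Per-axis minimum spacing over a dataset (the common target resolution)."""
    spacings = [v.spacing for v in volumes]
    if not spacings:
        raise ValueError("need at least one volume")
    return tuple(float(m) for m in np.min(np.asarray(spacings), axis=0))  # type: ignore[return-value]


def _target_grid(n: int, src: float, tgt: float) -> np.ndarray:
    """Sample positions (in source voxel index units) of the resampled axis.

    Voxel centers at 0, tgt, 2*tgt, ... covering the source extent
    (n-1)*src; the last center never falls outside the source grid.
    """
    n_new = int(np.floor((n - 1) * src / tgt + 1e-9)) + 1
    n_new = max(n_new, 2)
    return np.arange(n_new) * (tgt / src)


def resample_to_spacing(
    volume: ImageVolume,
    mask: ROIMask | None,
    target: Sequence[float],
) -> tuple[ImageVolume, ROIMask | None]:
    """Trilinearly resample a volume (and its mask) onto ``target`` spacing.

    The image is interpolated trilinearly; the mask is interpolated as a
    real-valued field and re-thresholded at 0.5, which approximately
    preserves physical volume without staircase artefacts.  The new grid
    spans the same physical extent and keeps the origin.
    """
    target = tuple(float(t) for t in target)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    for s, t in zip(volume.spacing, target):
        if t > COARSENING_GUARD_FACTOR * s:
            logger.warning(
                "target spacing %.3g mm is >%gx coarser than source %.3g mm",
                t, COARSENING_GUARD_FACTOR, s,
            )

    if tuple(target) == tuple(volume.spacing):
        out_mask = None if mask is None else ROIMask(
            mask.voxels.copy(), mask.spacing, mask.origin)
        return ImageVolume(volume.voxels.copy(), volume.spacing, volume.origin), out_mask

    axes = [
        _target_grid(n, s, t)
        for n, s, t in zip(volume.shape, volume.spacing, target)
    ]
    if any(len(a) < 2 for a in axes):
        raise ValueError("degenerate extent after resampling")
    coords = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([c.ravel() for c in coords])
    shape = tuple(len(a) for a in axes)

    vox = ndimage.map_coordinates(
        volume.voxels, coords, order=1, mode="nearest").reshape(shape)
    out_vol = ImageVolume(vox, target, volume.origin)

    out_mask = None
    if mask is not None:
        if mask.shape != volume.shape:
            raise ValueError("mask grid differs from volume grid")
        m = ndimage.map_coordinates(
            mask.voxels.astype(np.float64), coords, order=1, mode="nearest"
        ).reshape(shape)
        out = m > 0.5
        # grid points landing exactly on the half-level surface: break the
        # tie with the floor-voxel value (uniform strict/inclusive rules
        # erode/dilate the whole tie shell and bias the volume)
        ties = (m == 0.5).ravel()
        if ties.any():
            fl = np.minimum(np.floor(coords[:, ties]).astype(int),
                            np.asarray(volume.shape)[:, None] - 1)
            out.ravel()[ties] = mask.voxels[fl[0], fl[1], fl[2]]
        out_mask = ROIMask(out, target, mask.origin)
    return out_vol, out_mask


# ---------------------------------------------------------------------------
# dual-rater protocol
# ---------------------------------------------------------------------------

def mask_discrepancy(mask_a: ROIMask, mask_b: ROIMask) -> float:
    """Disagreement between two masks: |A xor B| / |A or B| (1 - Jaccard).

    Symmetric, 0 iff the masks are equal, at most 1 (disjoint masks).
    """
    a, b = mask_a.voxels, mask_b.voxels
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("discrepancy undefined for two empty masks")
    return float(np.logical_xor(a, b).sum() / union)


def merge_masks(
    pair: RaterPair,
    threshold: float = 0.05,
    adjudicated: ROIMask | None = None,
) -> ROIMask:
    """Combine two rater masks under the <5 % disagreement rule.

    If the discrepancy is below ``threshold`` the voxelwise union is
    returned (the ROI is meant to cover the whole tumor).  Otherwise the
    case needs a senior adjudicated mask, which is returned verbatim.
    """
    if pair.discrepancy < threshold:
        return ROIMask(
            np.logical_or(pair.mask_a.voxels, pair.mask_b.voxels),
            pair.mask_a.spacing,
            pair.mask_a.origin,
        )
    if adjudicated is None:
        raise AdjudicationRequiredError(
            f"rater discrepancy {pair.discrepancy:.3f} >= {threshold:.3f} "
            "and no adjudicated mask supplied"
        )
    if adjudicated.shape != pair.mask_a.shape:
        raise ValueError("adjudicated mask grid differs from rater grid")
    return adjudicated
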