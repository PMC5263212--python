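"""Volume container, NIfTI I/O, histogram matching and unit normalization.

All intensity preprocessing is restricted to the brain mask: skull
stripping is assumed to have happened upstream and a binary brain mask is
a required input next to every volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "load_volume",
    "save_volume",
    "save_mask",
    "match_histogram",
    "normalize_unit",
]


@dataclass
class Volume:
    """A 3D scalar volume with voxel spacing and a binary brain mask.

    Axes are (slice, row, col): the first axis walks axial slices, in-plane
    coordinates are 0-based (row, col). Intensities are arbitrary units.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    brain_mask: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (slice, row, col)")
        if self.brain_mask.shape != self.data.shape:
            raise ValueError("brain mask shape must equal data shape")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite everywhere")
        if not self.brain_mask.any():
            raise ValueError("brain mask must contain at least one voxel")

    @property
    def masked_values(self) -> np.ndarray:
        """1D array of intensities inside the brain mask."""
        return self.data[self.brain_mask]


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    """Diagonal affine mapping (slice,row,col) voxel indices to mm."""
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def load_volume(path: str | Path, mask_path: str | Path, case_id: str | None = None) -> Volume:
    """Load a NIfTI volume and its 0/1 brain-mask NIfTI as a :class:`Volume`."""
    img = nib.load(str(path))
    mask_img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    mask = np.asarray(mask_img.dataobj) > 0.5
    zooms = img.header.get_zooms()[:3]
    if case_id is None:
        case_id = Path(path).name.split(".")[0]
    return Volume(data=data, spacing=tuple(float(z) for z in zooms), brain_mask=mask, case_id=case_id)


def save_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume's data array as NIfTI-1 with its spacing in the affine."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine_from_spacing(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Write a boolean mask as a 0/1 uint8 NIfTI-1 volume."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine_from_spacing(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _quantile_map(values: np.ndarray, src: np.ndarray, ref: np.ndarray,
                  n_bins: int, n_quantiles: int) -> np.ndarray:
    """Map `values` so the empirical CDF of `src` matches that of `ref`.

    Piecewise-linear quantile mapping: each value is assigned its CDF level
    under `src` and replaced by the reference quantile at that level. The
    same knot grid is used on both sides, so matching a volume to itself is
    an exact identity wherever the quantile function is strictly increasing.
    The knot count is min(n_quantiles, n_bins).
    """
    n_knots = max(2, min(n_quantiles, n_bins))
    qs = np.linspace(0.0, 1.0, n_knots)
    ref_q = np.quantile(ref, qs)
    if src.max() == src.min():
        # degenerate histogram: every voxel sits at one reference quantile
        return np.full_like(values, np.median(ref), dtype=np.float64)
    src_q = np.quantile(src, qs)
    levels = np.interp(values, src_q, qs)
    return np.interp(levels, qs, ref_q)


def match_histogram(moving: Volume, reference: Volume,
                    n_bins: int = 256, n_quantiles: int = 100) -> Volume:
    """Transform `moving` so its within-mask histogram matches `reference`.

    Only voxels inside each brain mask participate; voxels outside the
    moving mask are left untouched. Shape and mask are unchanged.
    """
    if not moving.brain_mask.any() or not reference.brain_mask.any():
        raise ValueError("histogram matching requires nonempty brain masks")
    src = moving.masked_values
    ref = reference.masked_values
    out = moving.data.copy()
    out[moving.brain_mask] = _quantile_map(src, src, ref, n_bins, n_quantiles)
    return replace(moving, data=out)


def normalize_unit(vol: Volume) -> Volume:
    """Min–max normalize within-mask intensities to [0, 1].

    Outside-mask voxels are set to 0. A constant masked image maps to all
    zeros (documented convention, no error).
    """
    if not vol.brain_mask.any():
        raise ValueError("normalization requires a nonempty brain mask")
    vals = vol.masked_values
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(vol.data)
    if hi > lo:
        out[vol.brain_mask] = (vol.data[vol.brain_mask] - lo) / (hi - lo)
    return replace(vol, data=out)
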