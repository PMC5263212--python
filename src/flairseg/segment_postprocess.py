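"""From superpixel predictions to a filtered 3D tumour mask, and back-labels.

Training labels come from the ground truth via the >=50 % overlap rule; at
inference, tumour superpixels are unioned into a 3D mask and connected
components smaller than a voxel threshold (default 100) are discarded as
false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from flairseg.superpixel import SuperpixelMap

__all__ = ["SegmentationMask", "label_superpixels", "mask_from_predictions", "filter_components_3d"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentationMask:
    """Binary tumour mask after small-component removal."""

    mask: np.ndarray
    min_region_voxels: int
    connectivity: int = 26


def label_superpixels(gt_mask: np.ndarray, spx: SuperpixelMap, min_fraction: float = 0.5) -> np.ndarray:
    """Per-superpixel binary labels in spx.index order.

    A superpixel is tumour iff at least `min_fraction` of its pixels are
    tumour in the ground truth (>= at the boundary: exactly 50 % counts).
    """
    gt = np.asarray(gt_mask, dtype=bool)
    if gt.shape != spx.labels.shape:
        raise ValueError("ground-truth mask shape does not match superpixel map")
    out = np.zeros(len(spx.index), dtype=int)
    for i, (z, lab) in enumerate(spx.index):
        member = spx.labels[z] == lab
        out[i] = int(gt[z][member].mean() >= min_fraction)
    return out


def mask_from_predictions(spx: SuperpixelMap, predictions: np.ndarray) -> np.ndarray:
    """Union of tumour-labelled superpixels as a 3D boolean mask."""
    predictions = np.asarray(predictions)
    if predictions.shape[0] != len(spx.index):
        raise ValueError("one prediction per superpixel is required")
    mask = np.zeros(spx.labels.shape, dtype=bool)
    for (z, lab), pred in zip(spx.index, predictions):
        if pred:
            mask[z] |= spx.labels[z] == lab
    return mask


def filter_components_3d(mask: np.ndarray, min_voxels: int = 100,
                         connectivity: int = 26) -> SegmentationMask:
    """Remove 3D connected components with fewer than min_voxels voxels.

    Strict-less rule: a component of exactly min_voxels voxels is kept.
    Connectivity is 6, 18 or 26 (default 26).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return SegmentationMask(mask.copy(), min_voxels, connectivity)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return SegmentationMask(keep[lab], min_voxels, connectivity)
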