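"""Slice-wise SLIC superpixels with a joint intensity/spatial distance.

Each axial slice is gridded into S x S cells; cluster centres start at the
cell centres and pixels are iteratively assigned to the nearest centre
under the combined distance

    D = sqrt(d_c^2 + (d_s / S)^2 * m^2)

where d_c is the intensity difference of unit-normalized intensities, d_s
the Euclidean pixel distance, and m a compactness coefficient: larger m
weights the spatial term more and yields more compact, grid-like segments,
smaller m lets boundaries follow intensity edges. Pixels outside the brain
mask are excluded from clustering and carry label 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["SuperpixelMap", "slic_distance", "slic_segment", "enforce_connectivity", "segment_volume"]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class SuperpixelMap:
    """Per-slice superpixel label maps stacked into a 3D integer array.

    Label 0 marks voxels outside the brain mask; within each slice the
    nonzero labels are consecutive positive integers and each label's pixel
    set is 4-connected.
    """

    labels: np.ndarray  # (slice, row, col) int
    S: int
    m: float
    n_iter: int = 10
    case_id: str = ""
    _index: list[tuple[int, int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = [
                (z, int(lab))
                for z in range(self.labels.shape[0])
                for lab in np.unique(self.labels[z])
                if lab != 0
            ]

    @property
    def index(self) -> list[tuple[int, int]]:
        """Canonical (slice, label) ordering of all superpixels."""
        return self._index

    def n_superpixels(self) -> int:
        return len(self._index)


def slic_distance(pixel_i, pixel_j, S: float, m: float) -> float:
    """Combined intensity/spatial distance between two (coords, intensity) pixels.

    D = sqrt(d_c^2 + (d_s/S)^2 m^2) with d_c the absolute intensity
    difference and d_s the Euclidean coordinate distance. Symmetric.
    """
    if S <= 0:
        raise ValueError("grid side S must be positive")
    (yi, xi), ii = pixel_i
    (yj, xj), ij = pixel_j
    d_s = np.hypot(yj - yi, xj - xi)
    d_c = abs(ij - ii)
    return float(np.sqrt(d_c**2 + (d_s / S) ** 2 * m**2))


def _grid_centres(mask: np.ndarray, S: int) -> np.ndarray:
    """Initial centres (y, x, intensity placeholder) at grid-cell centres.

    Cells whose footprint contains no masked pixel contribute no centre.
    """
    H, W = mask.shape
    centres = []
    for gy in range(0, H, S):
        for gx in range(0, W, S):
            cell = mask[gy : gy + S, gx : gx + S]
            if cell.any():
                cy = gy + (min(gy + S, H) - gy - 1) / 2.0
                cx = gx + (min(gx + S, W) - gx - 1) / 2.0
                centres.append((cy, cx))
    return np.asarray(centres, dtype=np.float64)


def slic_segment(slice_image: np.ndarray, slice_mask: np.ndarray, S: int = 6,
                 m: float = 0.2, n_iter: int = 10) -> np.ndarray:
    """SLIC-partition one masked slice; returns a 2D label map (0 outside mask).

    Assignment uses a 2S x 2S search window around each centre; ties go to
    the lowest centre index, so the result is deterministic. Fragments are
    merged by :func:`enforce_connectivity` before returning.
    """
    image = np.asarray(slice_image, dtype=np.float64)
    mask = np.asarray(slice_mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("slice image and mask shapes differ")
    if not mask.any():
        raise ValueError("slice mask is empty")
    if S < 2:
        raise ValueError("grid side S must be at least 2")

    H, W = image.shape
    pos = _grid_centres(mask, S)
    n_c = len(pos)
    # centre intensity = mean masked intensity near the centre (its grid cell)
    inten = np.empty(n_c)
    for c, (cy, cx) in enumerate(pos):
        gy, gx = int(cy) // S * S, int(cx) // S * S
        cell_img = image[gy : gy + S, gx : gx + S]
        cell_msk = mask[gy : gy + S, gx : gx + S]
        inten[c] = cell_img[cell_msk].mean() if cell_msk.any() else image[int(cy), int(cx)]

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    labels = np.full((H, W), -1, dtype=np.int64)
    for _ in range(n_iter):
        best = np.full((H, W), np.inf)
        labels.fill(-1)
        for c in range(n_c):
            cy, cx, ci = pos[c, 0], pos[c, 1], inten[c]
            y0, y1 = max(0, int(cy) - S), min(H, int(cy) + S + 1)
            x0, x1 = max(0, int(cx) - S), min(W, int(cx) + S + 1)
            sub = np.s_[y0:y1, x0:x1]
            d_s2 = (yy[sub] - cy) ** 2 + (xx[sub] - cx) ** 2
            d_c2 = (image[sub] - ci) ** 2
            D = np.sqrt(d_c2 + d_s2 / S**2 * m**2)
            win = mask[sub] & (D < best[sub])
            best[sub] = np.where(win, D, best[sub])
            lab_sub = labels[sub]
            lab_sub[win] = c
            labels[sub] = lab_sub
        # pixels outside every window (possible for sprawling masks): nearest centre
        orphan = mask & (labels < 0)
        if orphan.any():
            oy, ox = np.nonzero(orphan)
            d = (oy[:, None] - pos[None, :, 0]) ** 2 + (ox[:, None] - pos[None, :, 1]) ** 2
            labels[oy, ox] = np.argmin(d, axis=1)
        # recompute centres as member means
        for c in range(n_c):
            member = labels == c
            if member.any():
                pos[c, 0] = yy[member].mean()
                pos[c, 1] = xx[member].mean()
                inten[c] = image[member].mean()

    out = np.where(mask, labels + 1, 0)
    return enforce_connectivity(out, min_size=max(1, S * S // 4))


def enforce_connectivity(labels: np.ndarray, min_size: int = 1) -> np.ndarray:
    """Make every superpixel 4-connected and absorb small fragments.

    Each label's 4-connected components are found; all but the largest
    component of a label, plus any component smaller than min_size, are
    merged into the adjacent label sharing the longest border. Labels are
    then renumbered consecutively from 1 (0 stays background).
    """
    labels = np.asarray(labels, dtype=np.int64).copy()
    # split every (label, component) into its own provisional id
    comp = np.zeros_like(labels)
    nxt = 1
    sizes: dict[int, int] = {}
    parents: dict[int, int] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        cc, n = ndimage.label(labels == lab, structure=_FOUR_CONN)
        counts = np.bincount(cc.ravel())[1:]
        main = int(np.argmax(counts)) + 1
        for i in range(1, n + 1):
            comp[cc == i] = nxt
            sizes[nxt] = int(counts[i - 1])
            parents[nxt] = int(lab) if (i == main and counts[i - 1] >= min_size) else 0
            nxt += 1
    keep = {cid for cid, par in parents.items() if par != 0}
    frags = sorted((cid for cid in parents if parents[cid] == 0), key=lambda c: sizes[c])
    for cid in frags:
        region = comp == cid
        # 4-neighbour ids and shared border length
        neigh = np.zeros_like(region)
        neigh[:-1] |= region[1:]
        neigh[1:] |= region[:-1]
        neigh[:, :-1] |= region[:, 1:]
        neigh[:, 1:] |= region[:, :-1]
        cand = comp[neigh & ~region & (comp > 0) & (comp != cid)]
        if cand.size:
            vals, cnts = np.unique(cand, return_counts=True)
            target = int(vals[np.argmax(cnts)])
            comp[region] = target
            sizes[target] = sizes.get(target, 0) + sizes[cid]
        else:
            keep.add(cid)  # isolated island in the mask: becomes its own label
            parents[cid] = -1
    # consecutive relabelling in raster order of first appearance
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    flat = comp.ravel()
    order = np.nonzero(flat)[0]
    for idx in order:
        cid = int(flat[idx])
        if cid not in mapping:
            mapping[cid] = len(mapping) + 1
    for cid, new in mapping.items():
        out[comp == cid] = new
    return out


def segment_volume(image: np.ndarray, mask: np.ndarray, S: int = 6, m: float = 0.2,
                   n_iter: int = 10, case_id: str = "") -> SuperpixelMap:
    """Run slice-wise SLIC over a 3D volume; empty slices stay all-zero."""
    labels = np.zeros(image.shape, dtype=np.int64)
    for z in range(image.shape[0]):
        if mask[z].any():
            labels[z] = slic_segment(image[z], mask[z], S=S, m=m, n_iter=n_iter)
    return SuperpixelMap(labels=labels, S=S, m=m, n_iter=n_iter, case_id=case_id)
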