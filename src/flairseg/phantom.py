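"""Synthetic FLAIR-like phantoms with textured hyperintense lesions.

Each phantom is a seeded, fully reproducible recipe: an ellipsoidal
brain-shaped foreground filled with several smoothly varying tissue
intensities, one hyperintense lesion with an irregular (blob-perturbed
sphere) boundary and speckle texture, additive Gaussian noise, and the
paired ground-truth lesion mask. Voxels are anisotropic — thick slices,
fine in-plane resolution — mimicking clinical axial FLAIR acquisition.

These phantoms exercise every pipeline stage without clinical data. They
emulate contrast, texture and noise, not MR physics: no bias field, no
partial-volume mixing, no anatomy beyond a smooth tissue patchwork.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from flairseg.io_preprocess import Volume, save_mask, save_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "write_cohort"]

# contrast multipliers cycled across a cohort to mimic grade variability
CONTRAST_LEVELS = (0.75, 1.0, 1.25)


@dataclass(frozen=True)
class PhantomSpec:
    """Seeded recipe for one synthetic FLAIR volume plus ground truth.

    Intensities are arbitrary units. tumour_contrast is the mean lesion
    intensity minus the mean within-brain background intensity;
    tumour_radius is the radius (mm) of the sphere whose blob-perturbed
    boundary delimits the lesion.
    """

    shape: tuple[int, int, int] = (10, 96, 96)
    spacing: tuple[float, float, float] = (5.0, 0.94, 0.94)
    tissue_means: tuple[float, ...] = (95.0, 105.0, 115.0)
    tumour_contrast: float = 80.0
    tumour_radius: float = 12.0
    texture_amplitude: float = 5.0
    noise_sigma: float = 8.0
    tissue_scale_mm: float = 12.0
    boundary_irregularity_mm: float = 1.5
    include_lesion: bool = True
    seed: int = 0


def _mm_grid(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _smooth_field(rng: np.random.Generator, shape, spacing, scale_mm: float) -> np.ndarray:
    """Zero-mean unit-std Gaussian random field with correlation scale in mm."""
    sigma_vox = [max(scale_mm / s, 0.5) for s in spacing]
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    return (f - f.mean()) / f.std()


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, np.ndarray]:
    """Build one phantom; identical specs give bitwise-identical output."""
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = _mm_grid(spec.shape, spec.spacing)
    centre = [0.5 * (n - 1) * s for n, s in zip(spec.shape, spec.spacing)]
    semi = [0.45 * n * s for n, s in zip(spec.shape, spec.spacing)]
    brain = (
        ((zz - centre[0]) / semi[0]) ** 2
        + ((yy - centre[1]) / semi[1]) ** 2
        + ((xx - centre[2]) / semi[2]) ** 2
    ) <= 1.0
    if min(semi) <= spec.tumour_radius:
        raise ValueError("tumour radius does not fit inside the brain ellipsoid")

    # smooth multi-tissue background: quantile-sliced random field -> means
    field = _smooth_field(rng, spec.shape, spec.spacing, spec.tissue_scale_mm)
    inside = field[brain]
    n_tis = len(spec.tissue_means)
    edges = np.quantile(inside, np.linspace(0, 1, n_tis + 1)[1:-1])
    classes = np.searchsorted(edges, field)
    background = np.asarray(spec.tissue_means)[classes]
    background = ndimage.gaussian_filter(background, [0.5, 1.0, 1.0])

    # lesion: blob-perturbed sphere centred where it surely fits
    margin = spec.tumour_radius + 2.0
    frac = np.array([min(0.5, max(0.0, 1.0 - margin / s)) for s in semi])
    offset = rng.uniform(-1, 1, size=3) * frac * np.asarray(semi) * 0.5
    lcentre = [c + o for c, o in zip(centre, offset)]
    dist = np.sqrt((zz - lcentre[0]) ** 2 + (yy - lcentre[1]) ** 2 + (xx - lcentre[2]) ** 2)
    blob = _smooth_field(rng, spec.shape, spec.spacing, 4.0)
    sphere = dist <= spec.tumour_radius
    blob = blob - blob[sphere].mean()  # zero-mean locally so the blob preserves volume
    lesion = (dist + spec.boundary_irregularity_mm * blob) <= spec.tumour_radius
    lesion &= brain
    if not spec.include_lesion:
        lesion[:] = False
    elif not lesion.any():
        raise ValueError("lesion ended up empty; increase tumour_radius")

    data = background.copy()
    bg_mean = background[brain & ~lesion].mean()
    speckle = ndimage.gaussian_filter(rng.standard_normal(spec.shape), [0.3, 0.7, 0.7])
    speckle = (speckle - speckle.mean()) / speckle.std()
    if lesion.any():
        data[lesion] = bg_mean + spec.tumour_contrast + spec.texture_amplitude * speckle[lesion]
    noise = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    data = np.where(brain, data + noise, 0.0)

    vol = Volume(data=data, spacing=spec.spacing, brain_mask=brain,
                 case_id=f"phantom_{spec.seed}")
    return vol, lesion


def generate_cohort(n: int, base: PhantomSpec | None = None, seed: int = 0
                    ) -> list[tuple[Volume, np.ndarray]]:
    """n phantoms with derived seeds, contrast cycled over low/mid/high."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    if base is None:
        base = PhantomSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    out = []
    for i in range(n):
        level = CONTRAST_LEVELS[i % len(CONTRAST_LEVELS)]
        spec = replace(base, seed=int(child_seeds[i]),
                       tumour_contrast=base.tumour_contrast * level)
        vol, gt = generate_phantom(spec)
        vol.case_id = f"phantom_{i:02d}"
        out.append((vol, gt))
    return out


def write_cohort(cohort: list[tuple[Volume, np.ndarray]], out_dir: str | Path,
                 with_lesion: list[bool] | None = None) -> Path:
    """Write NIfTI pairs plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for vol, gt in cohort:
        vpath = out_dir / f"{vol.case_id}_flair.nii.gz"
        mpath = out_dir / f"{vol.case_id}_brainmask.nii.gz"
        gpath = out_dir / f"{vol.case_id}_gt.nii.gz"
        save_volume(vol, vpath)
        save_mask(vol.brain_mask, vol.spacing, mpath)
        save_mask(gt, vol.spacing, gpath)
        entries.append({
            "case_id": vol.case_id,
            "volume": vpath.name,
            "brain_mask": mpath.name,
            "ground_truth": gpath.name,
        })
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"cases": entries}, indent=2))
    return manifest
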