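"""The 28-feature superpixel descriptor.

Per superpixel: 16 first-order intensity statistics, a 5-bin Gabor-texton
histogram, 6 fractal features from a multi-Otsu binary decomposition
(border area, mean border intensity and box-counting dimension for each of
two threshold bands), and the mean isocontour curvature. Non-texton
features are min-max scaled to [0, 30] with parameters learned on the
training set; the raw texton counts already live on that scale for the
default superpixel size and are passed through unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_multiotsu
from sklearn.cluster import KMeans

__all__ = [
    "STAT_COLUMNS",
    "TEXTON_COLUMNS",
    "FRACTAL_COLUMNS",
    "CURVATURE_COLUMNS",
    "FEATURE_COLUMNS",
    "GaborBank",
    "TextonModel",
    "BoxCountResult",
    "FeatureMatrix",
    "intensity_stats",
    "gabor_kernel",
    "filter_responses",
    "texton_fit",
    "texton_fit_vectors",
    "texton_map",
    "assign_textons",
    "texton_histogram",
    "multi_otsu",
    "border_map",
    "sfta_features",
    "box_count_dimension",
    "curvature_map",
    "curvature_features",
    "extract_case_features",
    "assemble_and_scale",
]

STAT_COLUMNS = [
    "int_mean", "int_std", "int_var", "int_mad", "int_medad", "int_cov",
    "int_skew", "int_kurt", "int_max", "int_min", "int_median", "int_mode",
    "int_cm3", "int_range", "int_iqr", "int_entropy",
]
TEXTON_COLUMNS = ["texton_1", "texton_2", "texton_3", "texton_4", "texton_5"]
FRACTAL_COLUMNS = [
    "frac_area_1", "frac_int_1", "frac_dim_1",
    "frac_area_2", "frac_int_2", "frac_dim_2",
]
CURVATURE_COLUMNS = ["curv_mean"]
FEATURE_COLUMNS = STAT_COLUMNS + TEXTON_COLUMNS + FRACTAL_COLUMNS + CURVATURE_COLUMNS
KEY_COLUMNS = ["case", "slice", "label"]

# default Gabor bank: 6 orientations x 5 envelope sizes x 4 wavelengths
DEFAULT_THETAS = (0.0, 30.0, 45.0, 60.0, 90.0, 120.0)
DEFAULT_SIGMAS = (0.3, 0.6, 0.9, 1.2, 1.5)
DEFAULT_LAMBDAS = (0.8, 1.0, 1.2, 1.5)


def intensity_stats(values: np.ndarray) -> np.ndarray:
    """16 first-order statistics of a superpixel's intensities.

    Order matches STAT_COLUMNS. Sample (n-1) variance; skewness/kurtosis 0
    by convention for constant regions; mode from a 64-bin quantization;
    entropy (base 2) from a 32-bin within-superpixel histogram.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("intensity_stats requires at least one pixel")
    mean = v.mean()
    vmin, vmax = v.min(), v.max()
    if v.size > 1:
        var = v.var(ddof=1)
    else:
        var = 0.0
    std = np.sqrt(var)
    median = np.median(v)
    mad = np.mean(np.abs(v - mean))
    medad = np.median(np.abs(v - median))
    cov = std / mean if mean != 0 else 0.0
    if std > 0:
        skew = float(stats.skew(v))
        kurt = float(stats.kurtosis(v))
    else:
        skew = kurt = 0.0
    if vmax > vmin:
        hist64, edges64 = np.histogram(v, bins=64, range=(vmin, vmax))
        mode = 0.5 * (edges64[:-1] + edges64[1:])[np.argmax(hist64)]
        hist32, _ = np.histogram(v, bins=32, range=(vmin, vmax))
        p = hist32[hist32 > 0] / v.size
        entropy = float(-(p * np.log2(p)).sum())
    else:
        mode = vmin
        entropy = 0.0
    cm3 = np.mean((v - mean) ** 3)
    iqr = np.percentile(v, 75) - np.percentile(v, 25)
    return np.array([
        mean, std, var, mad, medad, cov, skew, kurt, vmax, vmin, median,
        mode, cm3, vmax - vmin, iqr, entropy,
    ])


def gabor_kernel(theta: float, sigma: float, lam: float, psi: float = 0.0,
                 gamma: float = 1.0, truncate: float = 3.0) -> np.ndarray:
    """Complex Gabor kernel.

    G(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2))
              * exp(i (2 pi x' / lam + psi))

    with x' = x cos(theta) + y sin(theta), y' = -x sin(theta) + y cos(theta),
    theta in degrees, sigma the Gaussian envelope size in pixels and lam the
    sinusoid wavelength coefficient. Support is truncated at
    max(truncate * sigma, 3) pixels radius.
    """
    if sigma <= 0 or lam <= 0:
        raise ValueError("sigma and lambda must be positive")
    t = np.deg2rad(theta)
    r = int(np.ceil(max(truncate * sigma, 3.0)))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    xp = x * np.cos(t) + y * np.sin(t)
    yp = -x * np.sin(t) + y * np.cos(t)
    envelope = np.exp(-(xp**2 + gamma**2 * yp**2) / (2.0 * sigma**2))
    carrier = np.exp(1j * (2.0 * np.pi * xp / lam + psi))
    return envelope * carrier


@dataclass
class GaborBank:
    """A bank of Gabor kernels over all (theta, sigma, lambda) combinations."""

    thetas: tuple[float, ...] = DEFAULT_THETAS
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS
    psi: float = 0.0
    gamma: float = 1.0
    kernels: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.kernels:
            self.kernels = [
                gabor_kernel(th, sg, lm, self.psi, self.gamma)
                for th, sg, lm in itertools.product(self.thetas, self.sigmas, self.lambdas)
            ]

    @property
    def n_filters(self) -> int:
        return len(self.kernels)


def filter_responses(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """(H, W, N_FB) magnitudes of the complex filter outputs.

    Boundaries are reflect-padded so a flat image yields a flat response
    (zero-padding would imprint a dark frame on every response map).
    """
    image = np.asarray(image, dtype=np.float64)
    out = np.empty(image.shape + (bank.n_filters,))
    for i, k in enumerate(bank.kernels):
        re = ndimage.convolve(image, k.real, mode="reflect")
        im = ndimage.convolve(image, k.imag, mode="reflect")
        out[..., i] = np.hypot(re, im)
    return out


@dataclass
class TextonModel:
    """k-means texton prototypes over Gabor response vectors.

    Centres are reordered by ascending norm so texton identities do not
    depend on k-means initialization order.
    """

    centers: np.ndarray  # (k, N_FB)
    k: int
    center_order: str = "ascending_norm"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.k < 2:
            raise ValueError("texton count k must be at least 2")
        if len(np.unique(self.centers, axis=0)) != self.k:
            raise ValueError("texton centres must be pairwise distinct")


def texton_fit_vectors(X: np.ndarray, k: int = 5, seed: int = 0,
                       max_pixels: int = 200_000) -> TextonModel:
    """k-means texton prototypes from an (n, N_FB) response-vector matrix.

    At most `max_pixels` vectors are used, subsampled reproducibly from
    `seed`; centres are reordered by ascending norm.
    """
    X = np.asarray(X, dtype=np.float64)
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer distinct response vectors than texton count k")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_pixels:
        X = X[rng.choice(X.shape[0], max_pixels, replace=False)]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    centers = km.cluster_centers_[np.argsort(np.linalg.norm(km.cluster_centers_, axis=1))]
    return TextonModel(centers=centers, k=k)


def texton_fit(responses_list: list[np.ndarray], masks: list[np.ndarray],
               k: int = 5, seed: int = 0, max_pixels: int = 200_000) -> TextonModel:
    """Fit the texton model by k-means over pooled within-mask response vectors.

    `responses_list` holds (H, W, N_FB) (or (Z, H, W, N_FB)) response arrays,
    `masks` the matching boolean masks.
    """
    vecs = [resp[np.asarray(msk, dtype=bool)] for resp, msk in zip(responses_list, masks)]
    return texton_fit_vectors(np.concatenate(vecs, axis=0), k=k, seed=seed, max_pixels=max_pixels)


def texton_map(slice_image: np.ndarray, bank: GaborBank, model: TextonModel) -> np.ndarray:
    """Assign each pixel its nearest texton prototype; values in 1..k."""
    if model.centers.shape[1] != bank.n_filters:
        raise ValueError("texton model dimension does not match filter bank")
    resp = filter_responses(slice_image, bank)
    return assign_textons(resp, model)


def assign_textons(responses: np.ndarray, model: TextonModel) -> np.ndarray:
    """Nearest-centroid texton labels (1..k) for precomputed responses."""
    flat = responses.reshape(-1, responses.shape[-1])
    # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; ||x||^2 constant per pixel
    d = flat @ model.centers.T * (-2.0) + (model.centers**2).sum(axis=1)
    return (np.argmin(d, axis=1) + 1).reshape(responses.shape[:-1])


def texton_histogram(pixel_index: tuple[np.ndarray, np.ndarray], tmap: np.ndarray,
                     k: int = 5) -> np.ndarray:
    """Raw counts of each texton label among the superpixel's pixels."""
    labels = tmap[pixel_index]
    return np.bincount(labels, minlength=k + 1)[1 : k + 1].astype(np.float64)


def multi_otsu(image: np.ndarray, n_t: int = 3) -> np.ndarray:
    """Otsu thresholds splitting the intensity histogram into n_t + 1 classes."""
    vals = np.asarray(image, dtype=np.float64).ravel()
    if np.unique(vals).size < n_t + 1:
        raise ValueError("too few distinct values for multi-level Otsu")
    thr = threshold_multiotsu(vals, classes=n_t + 1)
    return np.sort(thr)


def border_map(binary: np.ndarray) -> np.ndarray:
    """Border pixels of a binary image: value 1 with >=1 zero 4-neighbour.

    The image boundary counts as zero (region touching the array edge has a
    border there).
    """
    b = np.asarray(binary, dtype=bool)
    eroded = ndimage.binary_erosion(b, structure=ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
    return b & ~eroded


@dataclass
class BoxCountResult:
    """Box counts N(eps) over dyadic box sizes and the fitted dimension D0."""

    box_sizes: np.ndarray
    counts: np.ndarray
    dimension: float


def box_count_dimension(border_pixels: np.ndarray) -> BoxCountResult:
    """Box-counting fractal dimension of a binary pixel set.

    D0 is the least-squares slope of log N(eps) against log(1/eps) over
    dyadic box sizes eps in {1, 2, 4, ...} up to min(H, W)/2. Degenerate
    inputs (empty set, or an array too small for two box sizes) return
    dimension 0.
    """
    b = np.asarray(border_pixels, dtype=bool)
    if b.ndim != 2 or not b.any():
        return BoxCountResult(np.array([]), np.array([]), 0.0)
    H, W = b.shape
    sizes = []
    eps = 1
    while eps <= min(H, W) / 2:
        sizes.append(eps)
        eps *= 2
    if len(sizes) < 2:
        return BoxCountResult(np.asarray(sizes), np.array([b.sum()] * len(sizes)), 0.0)
    counts = []
    for eps in sizes:
        ph, pw = (-H) % eps, (-W) % eps
        pad = np.pad(b, ((0, ph), (0, pw)))
        blocks = pad.reshape((H + ph) // eps, eps, (W + pw) // eps, eps)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    sizes_a = np.asarray(sizes, dtype=np.float64)
    counts_a = np.asarray(counts, dtype=np.float64)
    slope = np.polyfit(np.log(1.0 / sizes_a), np.log(counts_a), 1)[0]
    return BoxCountResult(sizes_a, counts_a, float(np.clip(slope, 0.0, 2.0)))


def band_images(image: np.ndarray, thresholds: np.ndarray) -> list[np.ndarray]:
    """Binary band channels from consecutive threshold pairs.

    n_t thresholds t1 < ... < t_nt give n_t - 1 bands {t_i <= I < t_{i+1}};
    the default n_t = 3 yields the two bands behind the six fractal features.
    """
    thr = np.sort(np.asarray(thresholds, dtype=np.float64))
    return [(image >= thr[i]) & (image < thr[i + 1]) for i in range(len(thr) - 1)]


def sfta_features(image: np.ndarray, pixel_index: tuple[np.ndarray, np.ndarray],
                  thresholds: np.ndarray) -> np.ndarray:
    """Six fractal features of one superpixel.

    Per band channel: border-pixel count inside the superpixel, mean source
    intensity over those border pixels, and box-counting dimension of the
    border pixels within the superpixel's bounding box. Empty borders give
    (0, 0, 0).
    """
    image = np.asarray(image, dtype=np.float64)
    rows, cols = pixel_index
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    inside = np.zeros(image.shape, dtype=bool)
    inside[rows, cols] = True
    feats = []
    for band in band_images(image, thresholds):
        borders = border_map(band)
        sel = borders & inside
        area = int(sel.sum())
        if area == 0:
            feats.extend([0.0, 0.0, 0.0])
            continue
        intensity = float(image[sel].mean())
        dim = box_count_dimension(sel[r0:r1, c0:c1]).dimension
        feats.extend([float(area), intensity, dim])
    return np.asarray(feats)


def curvature_map(slice_image: np.ndarray, smooth_sigma: float = 1.0,
                  grad_floor: float = 1e-6) -> np.ndarray:
    """Isocontour curvature at every pixel: divergence of the image normal.

    Curv = (f_xx f_y^2 - 2 f_xy f_x f_y + f_yy f_x^2) / (f_x^2 + f_y^2)^(3/2)

    with central-difference derivatives after Gaussian smoothing of scale
    `smooth_sigma` (0 disables smoothing). Pixels whose gradient magnitude
    falls below `grad_floor` get curvature 0.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    f_y, f_x = np.gradient(img)
    f_yy, f_yx = np.gradient(f_y)
    f_xy, f_xx = np.gradient(f_x)
    g2 = f_x**2 + f_y**2
    num = f_xx * f_y**2 - 2.0 * f_xy * f_x * f_y + f_yy * f_x**2
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = num / g2**1.5
    curv[np.sqrt(g2) < grad_floor] = 0.0
    return np.nan_to_num(curv, nan=0.0, posinf=0.0, neginf=0.0)


def curvature_features(slice_image: np.ndarray, pixel_index: tuple[np.ndarray, np.ndarray],
                       smooth_sigma: float = 1.0) -> float:
    """Mean curvature over the superpixel's pixels."""
    return float(curvature_map(slice_image, smooth_sigma)[pixel_index].mean())


@dataclass
class FeatureMatrix:
    """Superpixel-by-feature table plus the [0, 30] scaling metadata."""

    frame: pd.DataFrame  # KEY_COLUMNS + FEATURE_COLUMNS
    scale_lo: pd.Series | None = None
    scale_hi: pd.Series | None = None
    scale_max: float = 30.0
    texton_columns: tuple[str, ...] = tuple(TEXTON_COLUMNS)

    @property
    def X(self) -> np.ndarray:
        return self.frame[FEATURE_COLUMNS].to_numpy(dtype=np.float64)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def assemble_and_scale(rows: pd.DataFrame, fit: bool = True,
                       scale_params: tuple[pd.Series, pd.Series] | None = None,
                       scale_max: float = 30.0) -> FeatureMatrix:
    """Assemble raw feature rows into a FeatureMatrix scaled to [0, scale_max].

    With fit=True the per-column training min/max are learned from `rows`;
    otherwise `scale_params` (lo, hi) must be provided and test values may
    leave [0, scale_max]. Texton count columns pass through unchanged; a
    constant column maps to all zeros.
    """
    frame = rows.copy()
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature rows missing columns: {missing}")
    scaled_cols = [c for c in FEATURE_COLUMNS if c not in TEXTON_COLUMNS]
    if fit:
        lo = frame[scaled_cols].min()
        hi = frame[scaled_cols].max()
    else:
        if scale_params is None:
            raise ValueError("applying scaling requires stored parameters")
        lo, hi = scale_params
    span = (hi - lo).replace(0.0, np.nan)
    frame[scaled_cols] = (scale_max * (frame[scaled_cols] - lo) / span).fillna(0.0)
    return FeatureMatrix(frame=frame, scale_lo=lo, scale_hi=hi, scale_max=scale_max)


def extract_case_features(image: np.ndarray, spx, bank: GaborBank, texton_model: TextonModel,
                          case_id: str = "", n_t: int = 3,
                          curvature_sigma: float = 1.0) -> pd.DataFrame:
    """Raw (unscaled) 28-feature rows for every superpixel of one volume.

    `image` is the preprocessed [0, 1] volume, `spx` its SuperpixelMap.
    Otsu thresholds are computed per slice from within-mask intensities.
    """
    records = []
    for z in range(image.shape[0]):
        lab2d = spx.labels[z]
        labs = np.unique(lab2d)
        labs = labs[labs != 0]
        if labs.size == 0:
            continue
        sl = image[z]
        tmap = texton_map(sl, bank, texton_model)
        cmap = curvature_map(sl, smooth_sigma=curvature_sigma)
        masked = sl[lab2d > 0]
        try:
            thr = multi_otsu(masked, n_t=n_t)
        except ValueError:  # near-constant slice: no band structure
            thr = None
        for lab in labs:
            idx = np.nonzero(lab2d == lab)
            vals = sl[idx]
            stats16 = intensity_stats(vals)
            tex5 = texton_histogram(idx, tmap, k=texton_model.k)
            frac6 = sfta_features(sl, idx, thr) if thr is not None else np.zeros(6)
            curv = float(cmap[idx].mean())
            rec = dict(zip(KEY_COLUMNS, (case_id, z, int(lab))))
            rec.update(zip(STAT_COLUMNS, stats16))
            rec.update(zip(TEXTON_COLUMNS, tex5))
            rec.update(zip(FRACTAL_COLUMNS, frac6))
            rec[CURVATURE_COLUMNS[0]] = curv
            records.append(rec)
    return pd.DataFrame.from_records(records, columns=KEY_COLUMNS + FEATURE_COLUMNS)
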