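# Methods

## Problem and pipeline

`flairseg` segments the hyperintense abnormality (tumour core plus
oedema) in single-protocol FLAIR MRI. Skull stripping is upstream: every
volume arrives with a binary brain mask, and all computation is restricted
to it. The pipeline is: intensity standardization → slice-wise superpixel
partition → per-superpixel feature description → feature selection →
superpixel classification → 3D region filtering. Classification at
superpixel rather than voxel level buys boundary-adherent units, more
stable texture estimates, and orders-of-magnitude fewer samples.

## Preprocessing

Scanner intensities are arbitrary, so every case's within-mask histogram
is matched to a reference case (user-selectable by `case_id`; default the
first case in order) by piecewise-linear quantile mapping on a 100-knot
grid. Matching a volume to itself is an exact identity wherever the
quantile function is strictly increasing, and the map is monotone, so
repeated matching is stable. A constant (degenerate) volume maps to the
reference median. Intensities are then min–max normalized to [0,1] within
the mask; a constant masked image maps to all zeros by convention. Whether
matching should use all voxels or only brain voxels is an open choice; we
match within the brain mask only, since skull-stripped background is zero
and would otherwise dominate the histogram.

## Superpixels

SLIC with the combined distance `D = sqrt(d_c² + (d_s/S)² m²)` on
[0,1]-normalized intensities. Defaults `S = 6`, `m = 0.2`; small
superpixels (~36 px) keep lesion boundaries tight while still holding
enough pixels for texture statistics. Centres start at the geometric
centres of the S×S grid cells (no gradient perturbation); each of the 10
iterations assigns pixels within a 2S×2S window of each centre to the
minimum-D centre (ties to the lowest centre index, so the algorithm is
deterministic) and recomputes centres as member means. Pixels outside the
brain mask are excluded and labelled 0. A connectivity pass then splits
stray 4-connected fragments, merges any fragment smaller than S²/4 into
the neighbour sharing the longest border, and renumbers labels
consecutively. Iteration count and window size are conventional SLIC
choices; the distance itself fixes only their meaning, not their values.

## Features (28 per superpixel)

**Intensity statistics (16).** Sample conventions: variance with n−1;
skewness and excess kurtosis set to 0 for constant regions; coefficient of
variation 0 when the mean is 0; mode as the centre of the fullest of 64
equal-width bins over the superpixel's range; entropy base-2 over a 32-bin
within-superpixel histogram.

**Gabor textons (5).** The bank crosses 6 orientations
{0°, 30°, 45°, 60°, 90°, 120°}, 5 envelope sizes σ ∈ {0.3 … 1.5} px
(step 0.3), and 4 wavelength coefficients λ ∈ {0.8, 1.0, 1.2, 1.5}
(ψ = 0, γ = 1; 120 kernels, truncated at max(3σ, 3) px radius). The
response of a pixel is the magnitude of the complex filter output;
convolution is reflect-padded so a flat image yields a flat response. A
k-means model (k = 5, matching the tissue classes expected in FLAIR:
grey matter, white matter, tumour, oedema, other) is fitted once on up to
200 000 response vectors pooled over the training cases — per-image
clustering would make texton identities incomparable across cases — and
centres are reordered by ascending norm so texton IDs are independent of
initialization order. The feature is the raw 5-bin count histogram of the
texton map inside the superpixel; for ~36-px superpixels these counts
already live on the [0,30] scale, so they are exempt from rescaling.

**Fractal (6).** Multi-Otsu with `n_t = 3` thresholds defines two binary
band channels from consecutive threshold pairs `[t_i, t_{i+1})`,
computed per slice from within-mask intensities. (Band construction from
consecutive pairs is a design decision: with three thresholds it is the
channel count consistent with a 6-feature fractal block; one-sided
`I > t_i` channels would give 9.) A border pixel of a band is a 1-pixel
with at least one zero 4-neighbour, the array edge counting as zero. Per
band and superpixel: border-pixel count, mean source intensity over the
border pixels, and box-counting dimension of the border set inside the
superpixel's bounding box. D₀ is the least-squares slope of log N(ε)
against log(1/ε) over dyadic ε up to min(H, W)/2, clipped to [0, 2];
empty sets, and bounding boxes too small to supply two box sizes, return
0.

**Curvature (1).** Isocontour curvature
`(f_xx f_y² − 2 f_xy f_x f_y + f_yy f_x²)/(f_x² + f_y²)^{3/2}` from
central differences after Gaussian smoothing (σ = 1 px, configurable;
raw-vs-smoothed derivatives is an open choice and smoothing makes the
estimate usable at realistic noise). Pixels with gradient magnitude below
10⁻⁶ get curvature 0. On a radial ramp the estimator recovers 1/r within
5 % for r ∈ [5, 30] px; values within ~2 px of the array edge inherit the
smoothing boundary condition.

**Scaling.** Per-column min–max to [0, 30] learned on training rows;
texton counts pass through; constant columns map to 0; test values may
leave the range.

## Feature selection

Features are discretized by equal-frequency binning (10 bins — selection
operates on ranks, so the [0,30] scaling does not affect it). Greedy
forward mRMR with the MID (difference) criterion: the first pick maximizes
I(f; c); each later pick maximizes relevance minus mean redundancy to the
already-selected set (MIQ available via config). Mutual information is the
plug-in contingency-table estimate in bits. Selection is wrapped in
leave-one-case-out voting: each fold ranks its top 5, a feature earns one
vote per fold that kept it, and the 5 highest-voted features win (ties by
better mean rank, then lower index). The classical final set — normalized
mean intensity, a fractal-dimension band, two texton channels, mean
curvature — ships as a named preset (`select.use_preset`) so inference
pipelines can skip selection.

## Classifier

Extremely randomized trees: T = 20 trees, K = 5 attributes per split
(capped at the feature count), one uniform random cut-point per candidate
attribute, best split kept, `n_min` = 2, depth ≤ 15, no bootstrap. Tumour
probability is the arithmetic mean of per-tree leaf class frequencies;
the decision threshold is 0.5 with ≥ at the boundary. The implementation
wraps scikit-learn's `ExtraTreesClassifier`, which realizes exactly this
scheme; the split score is Shannon information gain (`criterion=
"entropy"`, Gini via config) rather than the normalized-gain variant of
the original extra-trees formulation — the normalization rarely changes
binary splits and scikit-learn does not expose it. No resampling or class
weighting is applied for the (heavily imbalanced) tumour class; the
ensemble's probability averaging handles it, and a class-weight flag
exists but is off by default.

## Postprocessing and evaluation

Training labels: a superpixel is tumour when ≥ 50 % of its pixels are
tumour in the ground truth (exactly 50 % counts as tumour). Predicted
tumour superpixels are unioned into a 3D mask; 26-connected components
(configurable) with fewer than 100 voxels are removed — strictly fewer,
so a 100-voxel component survives. Component size is counted in voxels
across slices, not per-slice pixels.

Superpixel-level precision, sensitivity and balanced error rate
BER = ½(FNR + FPR) are computed before region filtering; voxel-level Dice
after it. Empty denominators yield metric 0 (BER term 0); Dice of two
empty masks is 1.

## Phantom generator

The phantoms emulate the geometry of a clinical axial FLAIR acquisition:
10 slices of 96×96 at 5 × 0.94 × 0.94 mm (thick slices, fine in-plane).
The brain is an ellipsoid at 45 % of each extent. Background tissue is a
Gaussian random field (12 mm correlation length) quantile-sliced into
three classes of means 95/105/115 a.u. and lightly re-smoothed — a smooth
multi-tissue patchwork, not anatomy. The lesion is a sphere (default
radius 12 mm, ≈ 1 600 voxels) whose boundary is perturbed by a locally
zero-mean 4 mm blob field scaled to 1.5 mm, preserving volume to within
a few percent while making the outline irregular; lesion intensity is the
within-brain background mean plus the contrast (default 80 a.u.) plus
5 a.u. speckle. Gaussian noise (σ = 8 a.u.) is added inside the brain.
Cohorts cycle contrast through 0.75/1.0/1.25 × base to mimic grade
variability; the weakest setting (60 a.u.) stays above 4× the noise SD,
the regime in which a simple midpoint threshold already recovers the
lesion at Dice ≥ 0.9 — verifying the phantoms are learnable before any
pipeline quality is asserted. All randomness derives from the spec seed;
identical specs give bitwise-identical volumes.

What the phantoms do **not** model: bias fields, partial-volume mixing,
multi-focal or non-convex lesions, calcification/haemorrhage hypointensity,
anatomical structure, scanner-specific noise correlations. Passing the
end-to-end tests therefore demonstrates that the implementation recovers
a well-posed hyperintense lesion under realistic contrast and noise — not
clinical-grade performance.

## Problem sizes and numerical choices

The end-to-end protocol used by the tests and the acceptance script is a
12-phantom cohort at the default geometry, trained on 8 cases and
evaluated on 4 held-out cases plus one lesion-free phantom; this exercises
roughly 13 000 training superpixels and runs in a couple of minutes on a
single CPU. Tie-breaks are deterministic throughout (lowest index);
k-means uses 10 seeded restarts; the texton response subsample, mRMR
discretization and extra-trees are all driven by the pipeline seed, so a
fixed seed and config reproduce every output bitwise.

## Known limitations

Single-protocol FLAIR only; hypointense-within-hyperintense structures
(necrosis, haemorrhage) are absorbed into the tumour class; slice-wise
superpixels mean 3D coherence enters only through the component filter;
the [0,30] scaling assumes test intensities near the training range —
histogram matching is what makes that assumption tenable across scanners.
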