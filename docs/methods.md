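# Methods

## Problem and model

A skin OCT B-scan is a 2-D intensity raster whose rows are depth (row 0
shallowest) and whose columns are lateral position.  `octseg` labels each
pixel as upper bound (air/gel above the skin), epidermis together with
follicular invaginations, or dermis, and then refines the epidermis class so
that follicle borders are smooth and countable.  The design separates a
learned stage — which is good at coarse pixel classification but renders
follicle borders raggedly, because the intensity gradient at a follicle wall
is weak — from a deterministic signal-processing stage that encodes the
prior knowledge "follicles are smooth, compact invaginations below an
otherwise straight dermo-epidermal junction (DEJ)".

## Network

Encoder blocks: convolution (64 kernels of 7×3, zero padding, so feature
maps keep their spatial size) → batch normalization → ReLU → 2×2 stride-2
max-pooling whose argmax indices are stored.  Decoder blocks: index-based
unpooling (each value returns to its argmax position, doubling resolution) →
channel concatenation with the matched encoder's pre-pool feature map →
convolution → batch-norm → ReLU.  Head: 1×1 convolution to 3 channels and a
per-pixel softmax.  The default depth is 4 encoder/decoder blocks; because
526 and 75 are not divisible by 2⁴, the forward pass reflect-pads to the
next multiple of 2^n_blocks and crops the output, so a 526×75 patch yields a
526×75×3 probability map.  The rectangular 7×3 kernel matches the anisotropy
of the problem: layer boundaries are near-horizontal, so a taller receptive
field in depth is worth more than lateral width.

The whole network, including backprop, is written in numpy (im2col
convolutions, batch-norm with running statistics, pooling-index bookkeeping)
and is verified against central finite differences in the test suite.
Weights use fan-in-scaled (He) initialization from a seeded generator; all
training randomness (shuffling, augmentation) flows from the same config
seed, so runs are bit-reproducible in single-threaded use.

**Loss.**  The Soft-Dice loss is computed as one global ratio with sums over
all pixels and classes, `1 − 2Σpg/(Σp² + Σg²)`; it is 0 exactly at a perfect
hard prediction and 1 for disjoint supports, and training *minimizes* it.  A
per-class-averaged variant is available behind `dice_mode="per_class"`.  If
both maps are identically zero the loss is defined as 0 (vacuous perfect
match).  The analytic gradient −2g/B + 4Ap/B² is chained through the softmax
Jacobian.

**Optimization.**  SGD with classical momentum 0.97; learning rate 0.001
multiplied by 0.1 every 20 epochs; 60 epochs; batch size 4;
⌈n_train/batch⌉ iterations per epoch (2730 patches → 683).  The checkpoint
returned is the epoch with minimum validation loss.  Augmentation applies
the identical geometric transform to patch and mask: horizontal flips,
rotations up to ±5°, integer translations up to ±5 px; masks are resampled
with order-0 interpolation so labels stay categorical.

**Cross-validation.**  Folds are by patient.  For each external test patient
i, each remaining patient j serves once as the internal validation fold
while the others train — K−1 models per test fold, K(K−1) overall, and no
model ever sees its test patient.  Test scans are predicted in two 526×512
slices (offsets 0 and width−512); each model's two slice maps are averaged
over their 49-column overlap (the merge rule is this package's choice; any
convex combination preserves valid probabilities), and the K−1 model maps
are averaged before the final argmax.  Argmax ties break to the lowest class
index.  With K = 2 the single internal split degenerately uses the one other
patient as both training and validation fold.

## Savitzky–Golay baseline

The DEJ signal s_dej(x) is, per column, the deepest epidermis-class row; the
surface is the shallowest.  Columns without epidermis pixels are filled by
linear interpolation between valid neighbours (edges extend the nearest
value).  The filter is built from the least-squares projection
B = S(SᵀS)⁻¹Sᵀ, where S's columns are the monomials m^i, i ≤ d, on the
window m = −M…M (N = 2M+1).  Interior samples use the center column b₀ (an
even-symmetric FIR response); the first and last M samples take the fitted
polynomial of the first/last complete window evaluated at their off-center
positions — i.e. the off-center columns of B.  This makes polynomial
reproduction exact up to degree d everywhere, transients included, which the
tests assert against an independent per-window `lstsq` oracle.

Defaults d = 1, N = 449: with a window much wider than any follicle the fit
is insensitive to the invaginations and returns the straight trend of the
junction.  The corrected baseline subtracts the scalar
dif = min(bl) − min(s_dej), i.e. the line is shifted until its shallowest
point touches the shallowest DEJ point.  (Expressed in height-up
coordinates — image height minus row, the orientation in which these
signals are usually plotted — this is exactly an alignment of maxima,
`blc = bl − (max(s_dej) − max(bl))`.  Applying that formula literally on raw
row indices instead shifts the baseline *into* the follicles; that reading
is still available via `baseline_correction: literal_rows`.)

Follicle candidates are epidermis pixels strictly deeper than blc at their
column, grouped by 8-connectivity.  The area opening removes components
smaller than α = 0.3·max(A_c); with no components α is 0 and the result is
empty.  The 0.3 fraction, d = 1 and N = 449 are exposed in the run config.

## Fourier-descriptor smoothing

Each surviving component's boundary is taken as the exterior of the union of
its unit pixel squares (an exact polygon, computed with shapely), resampled
at N points equispaced in arc length with N the smallest power of two ≥ the
perimeter in pixels, and encoded as s[n] = x[n] + j·y[n].  Descriptors are
the DFT S[k]; S[0]/N is the centroid.  Reconstruction keeps the P
lowest-|frequency| bins — k = 0 first, then the ± pairs (k, N−k) by
increasing k, truncating the last pair to its positive-frequency member when
P is even — zeroes the rest, and inverts with the standard N-point inverse
DFT.  With P = N this is the identity; truncation is a projection
(idempotent).  The default is the fixed count P = 4; alternatively
P = round(f_c·N) with cutoff f_c = 0.007 (these two rules coincide at
N ≈ 571; at small N the cutoff rule keeps almost nothing, so fixed P is the
default).  One printed form of the reconstruction runs the inverse exponent
over P rather than N; that reading does not reduce to the identity at P = N,
so the standard truncated inverse DFT is implemented.

Smoothed contours are rasterized by point-in-polygon filling of pixel
centers; the final mask is upper epidermis (class-1 pixels at or above blc)
∪ filled follicles, with class 0 above the surface curve and class 2
elsewhere.  Components too small to carry a 2-D contour (< 3 px, or
line-like) are passed through unsmoothed.

## Metrics

Dice 2|A∩B|/(|A|+|B|) and Jaccard |A∩B|/|A∪B| per layer (both-empty
convention: 1).  Follicle counting runs the full refinement on a mask and
counts surviving components; the relative success rate is
RSR = 1 − |F_GT − F_P|/F_GT (undefined at F_GT = 0 and rejected there).
Epidermal thickness is the mean of (s_dej − surface) over valid columns not
intersecting any surviving follicle, times the axial pixel pitch; thickness
is a boundary-to-boundary difference (a band occupying rows 50–80 has
thickness 30 px, not 31).  Per-patient RMSE/MAE compare per-image thickness
series; cohort values are unweighted means over patients.  The axial pitch
is a required input for μm reporting (default 1.0 = "pixel units"); the
phantom declares 2.2 μm/px, the axial resolution class of ultrahigh-
resolution OCT.  Per-patient follicle counts in the pipeline report are the
rounded mean of per-image counts.  Table rendering rounds to 2 decimals;
computation never rounds.

## Phantom generator

What it emulates: a dark region above a bright entrance line at the surface;
an epidermis band brighter than the dermis; exponential depth attenuation
below the surface; multiplicative gamma speckle (mean 1, variance =
speckle_level²); a gently undulating entrance surface (sinusoid, random
phase); follicles as Gaussian-shaped DEJ invaginations truncated to compact
support at 2·halfwidth and placed in disjoint lateral sub-intervals, so
centers are ≥ 4·halfwidth apart and components on the true mask are
separated by construction.  The non-follicular DEJ is flat (the surface
waviness modulates band thickness, not the junction): a straight-line
baseline is the correct model for this geometry, which is precisely the
assumption the d = 1 Savitzky–Golay stage encodes.  Defaults (surface at
40 px, band 30 px ≈ 66 μm at 2.2 μm/px, follicle depth 40 px, halfwidth
15 px, speckle 0.3, attenuation 0.004/px) give images whose band thickness
and follicle scale sit in the range reported for healthy cheek skin.

What it does not emulate: coherent speckle statistics with spatial
correlation, shadowing under hairs, curved or tilted DEJ trends, sebaceous
gland substructure, multiple scattering.  Passing tests on phantoms
therefore demonstrate the correctness of the pipeline's mechanics (geometry,
filtering, counting, thickness) — not clinical-grade segmentation accuracy
on real scans, which depends on training the full-size network on real
annotated data.

## Problem sizes and numerical choices

The test suite and examples run reduced configurations — 96×96 phantoms,
2 encoder blocks, 8 filters, a few epochs — chosen so the full pipeline
remains exercised end to end while the suite stays fast on one CPU; the
full-size architecture (4 blocks, 64 filters, 526×975 scans) is exercised
for shape/contract correctness in single forward passes.  Dice/metric
computations are exact; SG filtering agrees with the brute-force oracle to
1e-8 relative; Fourier round trips to 1e-9.  Degenerate inputs are defined
explicitly: zero-denominator Dice and Soft-Dice return 1 and 0 respectively
(vacuous agreement), empty follicle sets propagate as empty, argmax ties
take the lowest class, width = slice_width yields a single inference slice.

## Known limitations

- The numpy network trains ~10²–10³× slower than a GPU framework; the
  full-size 60-epoch, 72-model protocol is impractical here and headline
  segmentation scores on real data (epidermis Dice ≈ 0.8, thickness error
  ≈ 10 μm) are not reproduced at desk scale.
- A straight-line baseline cannot follow a genuinely curved DEJ; on such
  anatomy the below-baseline decomposition over- or under-segments and the
  area opening must compensate.
- RSR is unbounded below (heavy over-detection gives negative values); it is
  reported as defined.
- Contour smoothing with fixed P = 4 assumes roughly elliptical follicles;
  elongated oblique follicles lose shape detail.
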