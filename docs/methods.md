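# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Phantom generator

The generator emulates single-frame X-ray angiograms: dark tubular
vessels (contrast agent attenuates X-rays) on a bright background with
low-frequency "soft-tissue" blobs, faint rib-like sinusoidal bands, and
additive Gaussian noise. Branches are random-walk centerlines with a
seeded, smoothly drifting heading (tortuosity 0.04 rad/step by default),
resampled at 0.5 px and rendered as a union of disks with a local radius
profile. A stenosis is a focal Gaussian constriction of the radius (axial
sigma 0.75 diameters) whose rendered throat width equals
`diameter × (1 − fraction)` within a pixel; branches must be at least
three diameters long so a focal narrowing is expressible. The map
`(config, seed) → sample` is a pure function; identical seeds give
bit-identical samples.

Default conditions: 300 × 300 px images (clinical-scale), vessel diameters
3–12 px, vessel level 80 / background 180 on a 0–255 scale, background
blob amplitude 15, rib amplitude 6, noise σ = 10, stenosis probability
0.5 with severity drawn from [0.5, 0.8], abnormality threshold 0.5
(clinically significant narrowing is conventionally ≥ 50%; configurable).
The desk-scale experiments in the tests and the acceptance script use
64 × 64 px images with diameters 3–9 px so training fits in CPU minutes;
these sizes are the package's documented verification conditions.

Vessels may cross and overlap by default — the hard case for
segmentation. The *classification* experiments use a dedicated preset
(`pipeline.classification_phantom_config`): 1–2 non-overlapping vessels of
5–10 px calibre. Two physical facts motivate this: stenosis grading from a
single 2-D projection is ambiguous where vessels superimpose (a real
limitation of single-view angiography), and a ≥ 50% narrowing of a 3-px
vessel leaves a sub-2-px throat that the raster cannot resolve.

What the phantoms do **not** model: projective/cone-beam geometry,
temporal sequences, breathing or cardiac motion, contrast-bolus dynamics,
Poisson (quantum) noise, and real anatomical tree topology. Passing tests
demonstrate correctness of the algorithms under the additive-Gaussian,
static, single-frame model — not clinical performance.

## Preprocessing

**Wiener filter.** The image is mirrored into a 2H × 2W even-symmetric
tile before the FFT to suppress boundary ringing (the periodicity
assumption otherwise creates edge artifacts). With white noise of
variance σ², the expected squared spectrum magnitude under an
unnormalized FFT is σ²·N_pixels; the gain
`max(1 − σ²N/|I(f)|², 0)` is used when no signal-power estimate is
supplied, with gain 1 at zero-power frequencies (nothing to filter
there). σ is estimated from first differences along the horizontal,
vertical and diagonal directions — each is Gaussian with deviation σ√2
for white noise — summarized by the median absolute deviation (robust to
image structure) and the median across directions. Zero noise power makes
the filter the identity to FFT round-off (verified < 1e−6 relative).

**Curvature enhancement.** Gaussian-derivative scale σ = 2 px, matched to
phantom vessel radii (roughly half-radius to radius for 3–12 px vessels);
a max-over-scales option exists but is off by default. scipy's sampled
derivative kernels do not sum exactly to zero, so a constant image would
leak a small multiple of its DC level into the Hessian; the implementation
subtracts that multiple of the smoothed image, making a flat surface have
exactly zero curvature. Responses below a floor of 1.0 intensity/px²
(residual-noise curvature, far below any vessel response of tens) are
zeroed, which also makes vessel-free images come back flat instead of
amplifying noise. The response is clipped at the 99.5th percentile — the
globally optimal response group that normalizes contrast — and min-max
rescaled so vessels are bright.

**Otsu.** Computed per image (globally) over the integer gray-value range
actually occupied; a tiled variant is available behind a flag. Ties in
the between-class variance resolve to the lowest threshold. Foreground
(1) is the bright class — vessels, after the enhancement stage's sign
orientation. A constant image is a degenerate histogram: warning plus
all-background mask. The decomposition satisfies `w₁ + w₂ = 1`,
`w₁μ₁ + w₂μ₂ = μ_total` and within + between = total variance at every
candidate threshold (asserted in tests); the selected threshold matches
an exhaustive scan exactly on every test image.

## Segmentation network

The nested U-Net follows the UNet++ pattern: node (i, j) convolves the
concatenation of all previous same-level nodes with the ×2-upsampled node
from the level below; a plain-U-Net fallback flag exists for ablation.
Attention gates (1×1 convolutions) act on the concatenated skip stack with
the upsampled decoder feature as gating signal; the ReLU is applied to the
encoder term before the gating term is added, and the coefficient map is
the sigmoid of a 1×1 projection of that sum — strictly inside (0, 1).
The network consumes a 2-channel stack (binarized image + original/255)
so the learned stage can correct binarization errors, and emits a logit
map; mask = sigmoid ≥ 0.5 (configurable).

Training: BCE-with-logits plus soft Dice, Adam at lr 1e−3, 30 epochs,
batch 8, all randomness seeded (two runs with the same seed give
identical loss curves). A NaN loss aborts with the epoch/batch attached.
The tiny preset is depth 3 with 8 base channels (~33k parameters).

**Artery-angle estimation.** Per connected component: orientation is the
principal axis of the pixel coordinates (eigenvector of the second-moment
matrix, folded to [0°, 180°) against the x-axis); length is the longest
geodesic path on the morphological skeleton (double Dijkstra sweep with
√2 diagonal weights); mean width is area/length. Components are split at
crossings: skeleton branch points are removed, the remaining segments
clustered greedily by orientation (threshold 30°, configurable), and
pixels assigned to the nearest cluster skeleton. Angle recovery on
straight branches is within 2° (50 seeded branches in the acceptance
suite; typical error < 0.2°).

All networks run on `angioseg._nn`, a compact float64 numpy reverse-mode
autodiff engine (conv2d via strided im2col einsum, 2×2 max-pool, nearest
upsample, channel concat, fused stable losses) with numerical gradient
checks in the test suite.

## Features

Diameter: at each interior skeleton point (points within 4 px of skeleton
endpoints are skipped — rounded caps distort normals), a ray is cast along
the local normal (tangent from PCA of nearby skeleton pixels) to the 0.5
level of the bilinearly-interpolated mask indicator on both sides;
`d = √((x₁−x₂)² + (y₁−y₂)²)` between the two crossings. The median over
skeleton points is the robust summary; the minimum is also exported
because stenosis lives at the narrowest point. Mean absolute recovery
error on seeded branches is ≈ 0.15 px (max ≈ 0.5 px at generic placement;
a branch centered exactly on a pixel row remains quantized to ±1 px — an
unavoidable rasterization effect).

The `constriction_ratio` orders widths along the skeleton's longest
geodesic path, median-smooths them (window 5), and compares each interior
width with the smaller of the running maxima up- and downstream: a step
between two merged vessels of different calibre is not a constriction
(one side never recovers), while a genuine focal stenosis is flanked by
wide segments on both sides. The score approximates `1 − fraction` for a
stenosed vessel and stays near 1 for a healthy one.

GLCM texture uses only pixel pairs with both ends inside the region
(offset 1 px, orientations 0/45/90/135° averaged, symmetric, normalized),
after quantizing to 32 levels anchored to the region's own min/max —
hence invariance to adding a constant. A single occupied level yields
ASM = homogeneity = 1, entropy = 0, and correlation defined as 1.

Shape: roundness = 4π·area/perimeter² (perimeter from regionprops);
solidity and convexity use the convex hull of *pixel centers* (counting
centers inside the hull polygon), which makes the hull operation
idempotent so a region's own hull has solidity exactly 1; dispersion is
the max/mean radial distance of region pixels from the centroid; kurtosis
is non-excess (Gaussian = 3); `local_intensity` is the region mean minus
the mean of a 5-px dilated background ring. Constant regions return
skewness 0 / kurtosis 3, flagged.

## Classifier

Dual path, each disableable for ablation: a VGG-16-pattern CNN on the
masked original image with the spatial-attention block (channel-avg and
channel-max maps, concatenated, 7×7 convolution, sigmoid, applied
multiplicatively) inserted after the fourth convolution block pre-pool;
and a handcrafted-feature path in which a softmax-normalized learnable
weight vector (the attention estimator, uniform 1/k at initialization,
always summing to 1, exported for inspection) scales the z-scored feature
matrix — scaled by k so the uniform initialization is the identity —
feeding a linear head. Final logits are the sum of both heads; class
probabilities by stable softmax with ties broken toward the lower index.
Zero-variance feature columns are dropped with a warning; standardization
statistics come from the training set only.

The full preset reproduces the canonical 16-layer progression
(224→112→56→28→14→7 spatial, 64→128→256→512 channels, dense
25088→4096→4096→classes), asserted analytically layer by layer. The tiny
preset (4 single-conv blocks 8/16/32/32, 64×64 single-channel input,
dense 512→64→2, dropout 0.5) is the trainable workhorse.

Training: cross-entropy, Adam, 30 epochs, batch 16, seeded. Four choices
were load-bearing at this scale and are deliberate: **lr 1e−3 for the
convolutional stack** (at 1e−4 the loss barely moves in 30 epochs on the
tiny preset); **lr 1e−2 for the feature path** (the attention estimator
plus linear head form a shallow model on standardized inputs and tolerate
a much larger step — with a shared rate their margins grow too slowly to
outweigh the CNN head's test-time noise on borderline samples);
**zero-initialized logit heads** (He-initialized heads start with random
class preferences that can trap the feature-attention softmax at
sign-flip saddles — one seed in three collapsed before this change); and
**random dihedral augmentation** of the image path (masked vessel images
have no canonical orientation; without augmentation the CNN memorizes a
100-image training set and its overfit test-time logits corrupt the
feature path). Under these defaults the 100/30 phantom experiment reaches
held-out accuracy 1.0 across independent phantom seed sets while the
label-permutation control stays at chance.

## Evaluation

Standard definitions throughout; the ones with no universal formula are
fixed normatively here: PSNR = 10·log₁₀(peak²/MSE) with identical images
flagged +∞; segmentation accuracy = fraction of agreeing pixels;
both-empty masks give Dice = Jaccard = 1 (perfect agreement on absence);
Hausdorff runs on 8-connected boundary pixels of the masks; rCNR divides
the absolute vessel/background mean difference by the noise σ (estimated
by the directional estimator when not supplied). Dice = 2J/(1+J) is
asserted as an algebraic identity; Hausdorff, ROC-AUC (trapezoid =
Mann–Whitney pair counting), MSE and the confusion metrics are verified
against brute-force oracles at 1e−12.

## Pipeline and problem sizes

`pipeline.run_pipeline` executes phantom generation → preprocessing →
segmenter training → test segmentation → features → classifier training →
metrics, writing a config snapshot, per-stage outputs, a log and a metrics
JSON; identical config+seed reproduces identical JSON. The default smoke
configuration is 32 training / 8 test phantoms at 64 × 64 with the tiny
presets (≈ 1 CPU-minute). The acceptance script uses: 50 images for the
Otsu oracle, 5 × 50 pixels for the eigen oracle, 40 seeded Wiener trials
at σ ∈ {5, 10, 20}, 50 metric-oracle instances, 50 branches for parameter
recovery, 32 phantoms for segmenter training, 130 (100/30) for
classification, and 5 seeds × (16 train / 6 test, 15 epochs, σ = 20) for
the preprocessing ablation.

## Known limitations

- The additive-Gaussian noise model ignores the Poisson character of
  X-ray quanta; the Wiener stage assumes uncorrelated noise.
- Curvature enhancement is single-scale by default; vessels far wider
  than 2·σ_scale respond mostly at their walls.
- The crossing-split heuristic assumes crossings of straight-ish vessel
  runs; three-way bifurcations at shallow angles may stay merged, and
  stenoses located exactly at a crossing are attributed ambiguously.
- The classifier's stenosis evidence degrades when vessels overlap in
  projection (hence the non-overlapping classification preset) and when
  the throat width falls below ~2 px.
- Angle estimation reports chord/principal-axis orientation; highly
  tortuous vessels are summarized, not traced.
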