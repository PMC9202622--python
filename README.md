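# angioseg

Automated segmentation and diagnosis support for coronary artery disease
(CAD) in X-ray angiograms: multi-constraint preprocessing, attention-gated
nested U-Net segmentation with artery-angle estimation, threefold
(color/texture/shape) feature extraction, and binary normal/abnormal
classification — together with a synthetic angiogram phantom generator so
that every stage is buildable, trainable and testable against exact ground
truth without any clinical data.

**Who it is for.** Researchers and students working on vessel segmentation
in projection X-ray imaging who need a complete, reproducible, CPU-only
reference pipeline with verifiable primitives; every numerical building
block is checkable against a brute-force oracle.

## The method

An angiogram shows contrast-filled vessels as dark tubular structures on a
brighter, structured background, corrupted by acquisition noise.  The
pipeline processes an image `N = O + A` (signal plus additive noise) in
four stages:

1. **Wiener noise removal.** In the frequency domain the minimum-MSE
   linear filter has gain `W(f) = |O(f)|² / (|O(f)|² + |A(f)|²)`,
   estimated from the observed spectrum as `W(f) = (|I|² − |A|²)/|I|²` and
   clamped to [0, 1].  The noise power is set adaptively from directional
   (diagonal/horizontal/vertical) high-pass residuals summarized by a
   robust MAD estimator.
2. **Principal-curvature contrast enhancement.** Gaussian-smoothed second
   derivatives form the local Hessian `[[k11, k12], [k12, k22]]`; with
   Gaussian curvature `G = k11·k22 − k12²` and mean curvature
   `M = (k11 + k22)/2`, the principal curvatures are
   `γ∓ = M ∓ √(M² − G)`.  `γ⁺` is large and positive exactly on dark
   tubular ridges; it is clipped at a high percentile and rescaled so
   vessels become bright.
3. **Otsu binarization.** The gray-level histogram is split at the
   threshold maximizing the between-class variance
   `w₁w₂(μ₁ − μ₂)²` (equivalently minimizing the weighted within-class
   variance), with `w₁ + w₂ = 1` and `w₁μ₁ + w₂μ₂ = μ_total`.
4. **Segmentation and classification.** An attention-gated nested U-Net
   (UNet++-style dense skips) refines the binarized image; on each skip,
   `f = ReLU(W_F F + b_F) + (W_G G + b_G)`,
   `α = σ(W_θ f + b_θ) ∈ (0, 1)`, output `F ⊙ α`.  Connected components
   of the mask are described per artery (principal-axis angle, skeleton
   geodesic length, mean width; crossings split where skeleton
   orientations disagree), the mask is AND-ed with the original image,
   and a VGG-16-style classifier with avg/max-pool spatial attention
   `C(F) = σ(conv7×7[F_avg; F_max])` plus an attention-weighted
   handcrafted-feature path assigns normal/abnormal through a softmax
   `p_j = e^{b_j} / Σ_k e^{b_k}`.

Evaluation uses accuracy/sensitivity/specificity, revised contrast-to-noise
ratio `rCNR = |In_A − In_B|/σ_n`, MSE, Dice `2|R∩R̂|/(|R|+|R̂|)`, Jaccard,
boundary Hausdorff distance, PSNR, pixelwise segmentation accuracy and ROC
curves with trapezoid AUC.

Neural networks run on a small numpy reverse-mode autodiff engine shipped
with the package (`angioseg._nn`); the tiny presets train in seconds to a
couple of minutes on one CPU.

## Worked example

```bash
python examples/02_preprocess.py
```

prints, for a seeded noisy phantom (true noise σ = 15):

```
estimated noise sigma: 16.94 (true 15.0)
PSNR vs clean image:   24.57 dB noisy -> 28.35 dB denoised
rCNR vessel/background: 6.05 raw -> 6.05 enhanced
Otsu threshold 66; binarization Dice 0.782, Jaccard 0.642
```

The Wiener stage recovers the noise level within ~13% and buys ~3.8 dB of
PSNR; after curvature enhancement and Otsu thresholding, the binary mask
already overlaps the true vessel mask at Dice 0.78 before the learned
segmenter ever runs.  `examples/03_train_and_segment.py` trains the tiny
attention nested U-Net (held-out Dice ≈ 0.95 on these conditions) and
`examples/05_classify.py` trains the classifier, printing its learned
feature-attention weights — `width_ratio`, the local-narrowing score, is
the stenosis signature and receives the largest weight.

The same flows are scriptable from a shell (`angioseg phantom`,
`angioseg preprocess`, `angioseg train-seg`, `angioseg segment`,
`angioseg features`, `angioseg train-clf`, `angioseg classify`,
`angioseg evaluate`, `angioseg run`).

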