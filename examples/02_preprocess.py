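"""Multi-constraint preprocessing: denoise, enhance, binarize.

Runs the three-stage pipeline on a noisy phantom and reports how each
stage moves the image toward a clean vessel mask: PSNR of the Wiener
output against the noise-free image, the contrast-to-noise ratio of the
curvature-enhanced image, and the Dice overlap of the Otsu binarization
with the true mask.
"""

import numpy as np

from angioseg import evaluate, phantom, preprocess

sample = phantom.generate_tree(phantom.PhantomConfig(size=128, noise_sigma=15.0), seed=3)
result = preprocess.preprocess_pipeline(sample.image)

psnr_noisy = evaluate.psnr(sample.clean_image, sample.image)
psnr_denoised = evaluate.psnr(sample.clean_image, result.denoised)
print(f"estimated noise sigma: {result.noise_sigma:.2f} (true 15.0)")
print(f"PSNR vs clean image:   {psnr_noisy:.2f} dB noisy -> {psnr_denoised:.2f} dB denoised")

vessel = sample.mask.astype(bool)
rcnr_raw = evaluate.rcnr(sample.image, vessel, ~vessel, sigma_n=15.0)
rcnr_enh = evaluate.rcnr(result.enhanced, vessel, ~vessel, sigma_n=15.0)
print(f"rCNR vessel/background: {rcnr_raw:.2f} raw -> {rcnr_enh:.2f} enhanced")

dice, jaccard = evaluate.dice_jaccard(sample.mask, result.binary)
print(f"Otsu threshold {result.threshold}; binarization Dice {dice:.3f}, Jaccard {jaccard:.3f}")
# A higher PSNR after Wiener filtering and a higher rCNR after curvature
# enhancement are exactly the improvements the binarization relies on.
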