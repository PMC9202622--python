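"""Train the attention-gated nested U-Net and segment a held-out phantom.

A tiny preset (depth 3, 8 base channels) trained on 16 noisy phantoms for
a few minutes of CPU time reaches Dice well above 0.9; the per-artery
table reports the orientation, length and mean width of every segmented
vessel, with crossings split where skeleton orientations disagree.
"""

import numpy as np

from angioseg import evaluate, phantom, segnet

config = phantom.PhantomConfig(size=64, n_branches=(1, 3), noise_sigma=10.0,
                               diameter_range=(3.0, 9.0))
train = [phantom.generate_tree(config, seed=i) for i in range(16)]
test = phantom.generate_tree(config, seed=99)

inputs = np.stack([segnet.sample_to_input(s) for s in train])
net = segnet.build_network(segnet.NestedUNetConfig(depth=3, base_channels=8, seed=0))
net, losses = segnet.train_segmenter(
    net, train, segnet.TrainConfig(epochs=20, seed=0), inputs=inputs
)
print(f"training loss: {losses[0]:.3f} -> {losses[-1]:.3f} over {len(losses)} epochs")

binary = segnet.sample_to_input(test)[0]
result = segnet.segment(test.image, binary, net)
dice, jaccard = evaluate.dice_jaccard(test.mask, result.mask)
print(f"held-out Dice {dice:.3f}, Jaccard {jaccard:.3f}")
for region in result.per_artery_regions:
    print(
        f"  artery {region.region_id}: angle {region.angle_deg:6.1f} deg, "
        f"length {region.length_px:5.1f} px, mean width {region.mean_width_px:4.1f} px"
    )
# masked_original is the original image under the predicted mask (bitwise
# AND) -- the input the classifier stage consumes.
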