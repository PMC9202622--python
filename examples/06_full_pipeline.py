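"""End-to-end run: phantoms -> preprocessing -> segmentation -> metrics.

Runs the default smoke configuration (32 training / 8 test phantoms, tiny
network presets) and prints the metrics report.  The same config and seed
always reproduce identical numbers.
"""

from angioseg import pipeline

config = pipeline.RunConfig(seed=1, out_dir="scratch/example_run")
run_dir, report = pipeline.run_pipeline(config)

print(f"\nrun directory: {run_dir}")
for key, value in report.to_dict().items():
    if key == "roc" or value is None:
        continue
    print(f"  {key:25s} {value:.4f}")
# dice/jaccard/hausdorff/segmentation_accuracy measure the predicted test
# masks against ground truth; psnr and mse compare the denoised images
# with the noise-free originals; accuracy/sensitivity/specificity/auc come
# from the normal-vs-abnormal classifier on the test split.
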