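"""Relate severity scores to ordinal disease stages with the full battery.

Computes Pearson/Spearman correlation with the stage code (NC=0, MCI=1,
AD=2), pairwise Welch t-tests, accuracy-maximizing 2-/3-class threshold
metrics, dispersion of the normalized scores and Pareto bins.
"""

from neuroscore.pipeline import run_pipeline

result = run_pipeline(
    {
        "phantom": {"n_subjects_per_stage": 12, "images_per_subject": 2,
                    "image_size": 32},
        "training": {"batch_size": 16, "epochs": 4},
    },
    seed=0,
)
report = result.report

print(f"held-out images: {report.n}")
print(f"Pearson r  = {report.correlation.pearson:+.4f} "
      f"(|r| = {report.correlation.pearson_abs_pct:.2f}%)")
print(f"Spearman rho = {report.correlation.spearman:+.4f} "
      f"(|rho| = {report.correlation.spearman_abs_pct:.2f}%)")
for pair, res in report.ttests.items():
    print(f"t-test {pair}: p = {res['p']:.3g}")
print(f"3-class accuracy = {report.threeclass.overall_accuracy:.3f} "
      f"(cutpoints {report.threeclass.cutpoints[0]:.2f}, "
      f"{report.threeclass.cutpoints[1]:.2f})")
print(f"dispersion: variance {report.dispersion.variance:.4f}, "
      f"variation ratio {report.dispersion.variation_ratio:.3f}")
# Negative correlations mean higher disease stage -> lower similarity to
# the healthy baseline, the expected direction for a severity score.
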