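# neuroscore

Objective severity scoring of dementia from structural brain-MRI slices,
using contrastive representation learning. Instead of a psychiatric
rating scale filled in by a clinician, the score is computed purely from
imaging: an encoder places each brain slice on the unit hypersphere so
that same-stage brains cluster, and a subject's neurological function is
read off as the similarity of their slice to a panel of healthy brains.

The package is aimed at researchers studying image-based severity scales
for progressive disease (normal control → mild cognitive impairment →
Alzheimer's disease) who need a fully reproducible, CPU-only reference
pipeline. Because clinical MRI cohorts are access-controlled, a synthetic
atrophy-phantom generator is a first-class component: it produces
datasets whose ventricular enlargement and cortical thinning grow
monotonically with stage, so every stage of the pipeline is testable
offline.

## The method

1. **Encoder.** A weight-sharing residual CNN maps a 2D slice to a pooled
   1024-d feature, a projection head maps it to 128-d, and the embedding
   is L2-normalized onto the unit hypersphere.
2. **Supervised contrastive training.** Each batch of N slices is
   duplicated into the twin channels (2N samples through one parameter
   set). For anchor *i* with positives P(i) = {j ≠ i : y_j = y_i}:

   L_i = −(1/|P(i)|) Σ_{j∈P(i)} log [ exp(z_i·z_j/τ) / Σ_{k≠i} exp(z_i·z_k/τ) ]

   summed over all 2N anchors, temperature τ = 0.07.
3. **Scoring.** score(x) = 100 × cos(z_x, z_base), averaged over five
   healthy baseline individuals drawn from the training split. Healthy
   test subjects score near 100; scores fall with atrophy.
4. **Evaluation.** Pearson/Spearman correlation with the ordinal stage,
   pairwise Welch t-tests, accuracy-maximizing two- and three-class
   threshold metrics, dispersion statistics of the normalized score, and
   Pareto bins.

The neural-network layers (convolution, residual blocks, projection,
normalization, Adam) are a compact numpy implementation with explicit,
finite-difference-validated backpropagation; the whole pipeline runs on
one CPU in minutes.

## Worked example

```sh
python examples/04_evaluate_stages.py
```

runs a small end-to-end pipeline (12 subjects per stage × 2 images,
32×32 px phantoms, 4 training epochs) and prints:

```
held-out images: 14
Pearson r  = -0.9852 (|r| = 98.52%)
Spearman rho = -0.9187 (|rho| = 91.87%)
t-test NC/MCI: p = 7.47e-06
t-test MCI/AD: p = 3.54e-07
t-test NC/AD: p = 6.63e-12
3-class accuracy = 1.000 (cutpoints 10.17, 81.08)
dispersion: variance 0.1382, variation ratio 0.786
```

The correlations are negative because the score measures similarity to
healthy baselines: higher disease stage → lower score. The tiny p-values
say the three stage groups are well separated on the held-out split, and
the three-class accuracy is the fraction of held-out images assigned to
the right stage by two score cut-points. `examples/01`–`03` demonstrate
the individual stages (phantom generation, contrastive training,
baseline-panel scoring).

The same pipeline is available from the shell:

```sh
neuroscore run-all --seed 1 --out runs/demo
```

(or `generate` / `train` / `score` / `evaluate` separately; every stage
derives its randomness from the single `--seed`, so reruns are
byte-identical).

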