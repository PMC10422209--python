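# Methods

## The model

The package scores the neurological function of a subject from a single
structural brain-MRI slice. A residual convolutional encoder maps a 2D
grayscale slice to a pooled feature vector f ∈ R^1024 (global average
pooling over the last convolutional stage, whose channel count equals the
feature width), a projection head maps f to R^128, and the result is
L2-normalized onto the unit hypersphere. The "twin" channels of the
architecture are realized as one parameter set applied to both inputs, so
weight sharing is structural: an embedding cannot depend on which channel
an image entered, and there are no batch-coupled statistics (no batch
normalization), so inference embeddings are independent of batch
composition by construction.

Training uses the supervised contrastive (SupCon) objective. For a batch
of N images duplicated into the two channels (2N samples z_1..z_2N with
stage labels y), each anchor i has positives P(i) = {j ≠ i : y_j = y_i}
and loss

    L_i = −(1/|P(i)|) Σ_{j∈P(i)} log [ exp(z_i·z_j/τ) / Σ_{k≠i} exp(z_i·z_k/τ) ]

with temperature τ. The total loss sums L_i over all 2N anchors; the mean
over anchors is logged alongside and used for parameter updates so the
effective step size does not scale with batch size. The normalizer is one
over the number of positives of the anchor (the "L_out" SupCon variant).
Positives are same-label samples; duplicating the batch guarantees every
anchor at least one positive (its own copy).

After training, the severity score of a test image is

    score = 100 × cos(z_test, z_base),

averaged over a panel of five healthy (NC) baseline individuals selected
at random from the training split (one image per distinct subject).
Averaging over five healthy subjects cancels inter-individual differences
between healthy brains. On the unit sphere the cosine is the dot product;
per-baseline scores lie in [−100, 100] and are not clamped — a negative
score signals a pathological embedding geometry and should be visible,
not hidden. Higher scores mean more similar to healthy; group means
decrease NC → MCI → AD, so the score's correlation with the ordinal stage
code is negative by design.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `feature_dim` | 1024 | pooled feature width |
| `projection_dim` | 128 | embedding width on the hypersphere |
| `projection_layers` | 1 | single linear map (no bias, no trailing ReLU — a trailing ReLU would confine embeddings to the nonnegative orthant); a 2-layer linear–ReLU–linear head is available |
| `backbone_depth` | `small` | 4 residual blocks over 3 stages (16/32/64 channels) for desk-scale CPU training; `standard` is an 18-layer-class net (2 blocks per stage, 64–512 channels) |
| τ (`temperature_tau`) | 0.07 | common SupCon default; sharper contrasts for smaller τ |
| `batch_size` | 32 | 64 samples per step after duplication |
| `learning_rate` | 3e-4 | Adam. Larger rates (1e-3) can overshoot into the collapse saddle where all embeddings coincide: there every anchor's loss is exactly log(2N−1) and the gradient, being radial, is annihilated by the sphere projection, so training stalls. 3e-4 descends monotonically in our settings. |
| `epochs` | 10 | sufficient for severity recovery at the default dataset size |
| `augmentation` | `none` | exact-copy duplication (the duplicate is then a trivial positive); `light` (random flip + ≤2px shift) makes the duplicate non-trivial |

## The phantom generator

The generator emulates the statistical structure the scoring framework
assumes, not MRI physics. Each subject in stage g receives a latent
severity s ~ U(interval_g) plus a N(0, subject_effect_sd) offset clipped
to [0, 1] (clipping rather than resampling keeps the draw count, and thus
the random stream, fixed). Stage intervals default to NC [0, 0.15],
MCI [0.35, 0.55], AD [0.75, 1.00]; the gaps make stages separable by
construction of the ground truth, mirroring the ordinal, separable stage
labels of clinical cohorts. The rendered slice is an ellipse ("brain",
intensity 0.55) with a bright cortical band (0.85) whose thickness
shrinks linearly in s and a central dark ventricle (0.05) whose two
semi-axes grow linearly in s — so ventricle area is strictly increasing
in s, the single monotone atrophy signal. Each of a subject's images is
the same rendered phantom plus i.i.d. N(0, noise_sd) pixel noise
truncated to [0, 1].

Defaults: 40 subjects per stage × 3 images at 64×64 px, noise_sd 0.03,
subject_effect_sd 0.02. Subjects are split 80/20 into train/test by
subject id — never by image — with `round(0.8 × n_subjects)` train
subjects (banker's rounding; 633 subjects → 506 train).

What the phantom does **not** model: registration error, bias fields,
partial-volume effects, anatomical variability beyond a scalar severity,
or any overlap between stage severity distributions. Passing the
end-to-end tests therefore shows that the pipeline recovers a monotone
atrophy signal under clean conditions; it does not certify performance on
clinical data, where stage distributions overlap heavily.

## Imaging conventions

Volumes are consumed already preprocessed; the expected conformant shape
is 113×137×113 with axis order (sagittal, coronal, axial). The extracted
plane is coronal plane 69 in 1-based indexing (array index 68), the
printed middle of a 137-plane axis; the coronal axis position is
configurable because NIfTI orientation varies. Intensities are min-max
normalized per image (constant image → all zeros); per-image
normalization removes scanner-scale effects and is idempotent.

## Evaluation conventions

- Stage coding NC=0, MCI=1, AD=2. Signed correlations are stored;
  |r|×100 is rendered for tabular display.
- Pairwise two-sample t-tests default to the unequal-variance (Welch)
  form; pooled variance is a flag.
- Two-class metrics: the more severe stage is the positive class; whether
  a low score votes positive is inferred from the group means. The single
  cut-point maximizes accuracy over midpoints of sorted unique scores
  (plus all/none sentinels), ties broken toward higher sensitivity, then
  the smaller threshold. Three-class metrics use two ordered cut-points
  found by exhaustive scan over midpoint pairs, with the score axis
  intervals assigned to stages by group-mean order, and report per-stage
  one-vs-rest rates plus the full confusion matrix. By default cut-points
  are selected on the same set being evaluated; a separate selection set
  can be supplied.
- Dispersion is computed on min-max-normalized scores: population
  variance/std, quartile deviation (Q3−Q1)/2 with linear-interpolation
  quantiles, and variation ratio 1 − mode frequency/n after rounding to 2
  decimals (a continuous score needs a discretization to have a mode).
- Pareto bins are equal-width over [min, max]; the cumulative curve is
  forced to end at exactly 100%.

## Reproducibility and numerics

One global seed fans out into named substreams (phantom, encoder, train,
panel) via hashed seed sequences, so stages can be re-run independently
and a full pipeline run is reproducible to the byte, including the report
JSON. The loss uses a numerically stable log-sum-exp; the analytic
gradient of the loss and of every layer has been validated against
central finite differences. Zero-norm vectors are an error at
normalization and scoring time, never silently fixed. Baseline panels
record the encoder weight fingerprint (SHA-256) and scoring refuses a
mismatched checkpoint.

## Test problem sizes

End-to-end severity recovery runs at the default conditions (3 stages ×
40 subjects × 3 images, 64×64 px, 10 epochs, one CPU, ≈2 minutes). The
byte-identical-reproducibility check runs all pipeline stages at a
reduced size (12 subjects per stage × 2 images, 32×32 px, 2 epochs) —
reproducibility is size-independent, so the smaller run checks the same
property. Loss-oracle equivalence uses 200 random batches with 2N ≤ 16
against an explicit double-loop implementation at 1e-6.

## Known limitations

- The encoder and training loop are a compact numpy implementation with
  explicit backpropagation: single-CPU, float64, no GPU or mixed
  precision; it is sized for the phantom study, not for large cohorts.
- The `standard` backbone is provided for architectural parity but is
  slow in this implementation; the `small` backbone is the working
  default.
- Threshold-based class metrics depend on the cut-point selection set;
  selecting on the evaluation set (the default, used when no separate
  selection set exists) is optimistic relative to a held-out selection.
- The phantom's severity gaps make three-class separation easier than in
  clinical data; accuracy near 1.0 on phantoms is expected and is not a
  clinical claim.
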