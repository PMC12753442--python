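# Methods

## Scientific setting

Lymph-node metastasis (LNM) status in cervical cancer decides between
radical surgery and chemoradiotherapy, but preoperative assessment from
any single source — CT, ultrasound, or laboratory indicators — is
unreliable, and LNM prevalence in surgical cohorts is low (on the order
of 12–13%).  The model implemented here aligns three per-patient
modalities in a shared contrastive space and fuses them for binary
classification, the working hypothesis being that cross-modal
agreement regularizes the small-sample, imbalanced learning problem.

## Model and objective

Three encoders produce D = 512 features: two image backbones (residual
CNNs truncated before any classification layer; CT and US use
independent weights by default, a `share_image_backbone` flag ties
them) and a two-layer perceptron F → 256 → 512 for the clinical vector.
The clinical MLP uses a rectifier between its two layers and no
nonlinearity after the second, because the features feed both the
projection heads and the fusion classifier.

Projection heads (512 → 256 → 128, rectifier between) map features into
the contrastive space.  For anchors in modality a against modality b
the per-anchor InfoNCE loss on cosine similarity at temperature τ
(default 1) is

    L_i = -log [ exp(s_ii/τ) / Σ_{j≠i} exp(s_ij/τ) ],

a *literal* form whose denominator contains only cross-patient
negatives, so the loss can be negative (its two-sample fully-separated
value is −2).  The conventional form including the positive pair in the
denominator is available via `include_positive_in_denominator`, and a
symmetrized (a→b plus b→a)/2 variant via `symmetrize`; both default to
off.  Within-modality pairs are never used as negatives.  The combined
contrastive term is the unweighted mean of the three ordered pair
losses ct→clin, us→clin, ct→us.  The training objective is exactly
`total = cross_entropy + contrastive`; the decomposition is logged per
epoch and asserted in tests.

Fusion is plain concatenation in the fixed order ct ‖ us ‖ clin
(width 3D = 1536 with all three modalities) into a single affine
classifier to two class scores — the simplest reading of "a binary
classifier"; hard predictions take the argmax with exact ties resolved
to the negative class.

## Training protocol

Stratified 80/10/10 split (train size = round(0.8 n); the remainder is
halved with the extra patient going to test, so n = 127 gives
102/12/13).  Stratification keeps at least one positive in validation
and test — with 16 positives an unstratified 10% draw is often
positive-free, leaving sensitivity undefined — and requires ≥ 3
positives; a flag disables it.  Mini-batches of 8 are drawn with
replacement with probability proportional to inverse class frequency,
so each class appears with expected frequency 1/2.  Optimization is
Adam (conventional moments, no weight decay) at initial rate 1e-3 with
a half-cosine decay to 0 over the configured epochs (default 30, no
restarts).  Images are augmented by a random square crop with area
fraction uniform on (0.7, 1.0) — a chosen constant, exposed in
configuration — resized bilinearly to the configured input side;
evaluation uses the deterministic full-image path.  The checkpoint with
the highest validation accuracy is returned, earliest epoch on ties.
Clinical features are min-max scaled to [0, 1] with bounds fitted on
the training split only; held-out values are clipped and a constant
feature maps to 0.

The default clinical feature vector has 12 entries: age, SCC-Ag, CA125,
CA19-9, neutrophils, lymphocytes, platelets, albumin, plus the derived
NLR, PLR, SII and PNI.  FIGO stage is excluded by default because its
association with the label is near-deterministic in this disease
setting, which would trivialize the prediction task; it is available
via configuration.  PNI uses the conventional multiplier 5
(albumin + 5 × lymphocytes), which is the only form consistent with
typical published PNI magnitudes (~50 at albumin ~42); the literal
albumin-plus-lymphocytes form is multiplier 1.

## Numerical core

No deep-learning framework is used: `lnmfusion.nn` is a compact
reverse-mode autodiff engine over float32 NumPy arrays (broadcasted
arithmetic, matmul, im2col convolution, max-pooling, reductions,
indexing), with layers (convolution, batch normalization, residual
blocks, affine) and Adam built on top.  Gradients are verified against
central differences in the test suite.  InfoNCE is computed with
max-subtraction stabilization; embedding rows with zero norm raise a
domain error rather than being epsilon-masked.  Two backbones are
provided: the standard 18-layer residual topology (3-channel input,
7×7/2 stem, stages 64–512, natively 512-wide) intended for 224-px
inputs, and a reduced-depth variant (1-channel 3×3/2 stem, two residual
stages to 32 channels, affine widening to 512) that is the default so
training runs on one CPU in seconds per epoch.  Grayscale inputs are
replicated across channels where the backbone expects three.  The
`pretrained_init` flag loads backbone weights from a user-supplied
`.npz` file; no checkpoint is bundled and random initialization is the
default.

## Synthetic cohorts

The generator defines the study conditions for all experiments.
Labels: exactly `n_positive` of `n_patients` (default 16/127).  Images:
a smooth low-frequency background (bilinear upsampling of a 4×4
Gaussian grid, sd 0.10) around intensity 0.45, pixel noise of sd
`noise_sd` (default 0.10), and — for positive patients only — an
additive Gaussian blob (σ = side/6, random center) of amplitude
0.12 × effect, clipped to [0, 1].  Clinical values: truncated normals
centred inside the assay reference ranges; positive patients are
shifted by `effect_clin` standardized units in the clinically expected
direction (higher SCC-Ag, CA125, CA19-9, neutrophils, platelets; lower
lymphocytes, albumin).  FIGO stage is ordinal with label-dependent
probabilities whose association strength scales with `effect_clin` (so
a zero-effect cohort is fully null).  Default effect amplitudes are 1.0
per modality — individually informative but not trivially separable.

What the generator does *not* emulate: scanner physics, 3-D volumes or
contrast phases, anatomically structured backgrounds, correlated
measurement error between laboratory assays, or micro-metastasis size.
Passing tests therefore demonstrate that the pipeline recovers planted
cross-modal signal under realistic imbalance — not clinical performance
on real imaging.

## Experiment sizes and measurement choices

The packaged experiments are scaled for a single CPU: cohorts of
n = 200 at 12.5% prevalence, 64-px images, the reduced backbone, and 10
training epochs (three seeds each) for the signal-recovery, null, and
ablation studies.  The null-calibration and ablation AUCs are measured
on an independently generated 400-patient cohort in addition to the
20-patient test split: with only 2–3 positives in a 10% split the
Monte-Carlo standard deviation of a null AUC is ≈ 0.18, larger than the
±0.15 acceptance band itself, whereas at n = 400 (50 positives) it is
≈ 0.05.  The training conditions are unchanged; only the measurement
set for those two AUC properties is enlarged.

## Statistics module

Pearson chi-square on 2×2 tables is computed *without* continuity
correction — the convention that exactly reproduces the published
baseline-table statistics this module is validated against (5.853,
92.045, 0.013, 3.520, 0.341), including tables with small expected
cells; Fisher's exact test is offered separately.  Two of the published
marker rows (CA125, CA19-9) have counts that do not sum to their group
sizes and are excluded from validation.  The Mann-Whitney z uses the
first sample's U, tie-corrected variance, and a 0.5 continuity
correction toward the null mean; these are documented constants, not
values validated against published z statistics (the raw data needed to
check sign and correction conventions is unavailable).  Normality
screening uses the one-sample Kolmogorov-Smirnov statistic against a
normal with the sample's own mean and SD — the common screening
dialect; it is deliberately conservative and is used only to route
continuous summaries between mean ± SD / pooled-t and
median (P25, P75) / Mann-Whitney.  Constant samples raise rather than
being given a convention.  The baseline-table generator uses chi-square
for categorical rows by default (matching the published table's
practice even at small expected counts), with Fisher selectable.

## Known limitations

- The reduced backbone at 64 px is far smaller than an 18-layer network
  at 224 px; the fidelity path exists but is slow in pure NumPy.
- Float32 autodiff limits gradient agreement with finite differences to
  ~1e-3 relative; tolerances in the gradient tests reflect that.
- The two-sided Fisher p uses hypergeometric enumeration (summing
  tables no more probable than observed), which can differ from other
  two-sided definitions near ties.
- The synthetic ablation can only demonstrate the *direction* of the
  fusion benefit (fused ≥ best single modality within noise); absolute
  metric values on real cohorts are out of reach by construction.
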