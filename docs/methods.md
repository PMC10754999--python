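# Methods

## Data model

A spectrum is a length-826 absorbance vector on the uniform ascending
wavenumber grid 700–4000 cm⁻¹ in 4 cm⁻¹ steps. Spectra carry a sample id,
a replicate id and a class label; a dataset additionally fixes the ordered
class list (default AS, RA, OA, HC — the order used in every report).
Files with descending axes are reversed on read; spectra on any other grid
are rejected rather than resampled, because resampling semantics (aliasing,
end effects) are not part of this package's contract. Units are treated as
arbitrary absorbance-like intensities.

Preprocessing is deliberately minimal. The only default step is replicate
averaging: each sample's spectrum is the unweighted pointwise mean of its
repeat acquisitions (three in the emulated protocol). Min–max and
unit-vector normalization exist behind an explicit flag for synthetic
experiments, but no normalization or baseline correction is applied unless
asked for, and none is needed by the classifiers.

## Synthetic generator

The generator produces

```
A(w) = Σ_b  A_b · s_cb · p_sb · exp(−(w − c_b)² / 2σ_b²)
       + β₁ t + β₂ t²  +  j_r  +  ε(w)
```

with bands *b* at centers c_b ∈ {3280, 2940, 1641, 1542, 1420, 1245, 1078}
cm⁻¹, widths σ_b = 60 cm⁻¹ for the two broad high-wavenumber bands and
20 cm⁻¹ in the fingerprint region, and base amplitudes
A_b = (0.90, 0.45, 1.00, 0.80, 0.30, 0.25, 0.20) arbitrary units (amide I
strongest). t ∈ [0, 1] is the normalized wavenumber; the default baseline
is β₁ = 0.02, β₂ = 0.01. Class structure enters only through the
multiplier vector s_c (band positions never move, matching the observation
that disease groups differ mainly in band magnitude); biological
variability is a per-sample, per-band multiplicative perturbation
p_sb ~ 1 + N(0, 0.03); each replicate adds an offset j_r ~ N(0, 0.005) and
i.i.d. point noise ε ~ N(0, 0.01). Replicates of a sample share p_sb, so
averaging them demonstrably improves SNR.

Randomness is hierarchical: every (class, sample) and every replicate draws
from a stream spawned from the single config seed keyed by its indices, so
generation is a pure function of the config and enlarging a dataset never
reshuffles existing samples.

Presets fix the class multipliers:

- **easy** — multi-band patterns differing by 10–30% per band; the
  noiseless class templates are mutually distinguishable with margin well
  above both the point noise and the sample variability, so a
  nearest-class-mean rule on the templates is exact and the Bayes accuracy
  is ≈ 1. (The OA vector was set so the smallest pairwise template
  distance clears the within-class spread; this calibration is part of the
  preset's definition, checked by a test.)
- **hard** — a single-band difference of 8–16% of amide I/II, leaving
  pairwise template RMS distances between 0.5 and 2 point-noise SDs:
  genuinely overlapping classes.
- **null** — identical multipliers everywhere; any classifier's expected
  accuracy is 1/4.

What the generator does *not* emulate: water-vapor and CO₂ artifacts,
scattering (EMSC-type) distortions, Mie effects, detector nonlinearity,
wavenumber calibration drift, and any covariance between bands beyond the
shared per-sample amplitude perturbation. Passing tests on synthetic data
therefore demonstrate that the pipeline recovers amplitude-pattern class
structure at realistic SNR — not that any particular clinical accuracy
would be achieved on real serum spectra.

## Architectures

All four networks consume the raw 826-point spectrum as a single channel.
Convolutions are stride-1 with odd kernels and 'same' zero padding, so
sequence length changes only at pooling layers; the order inside a block is
conv → batch-norm → ReLU throughout. The output head is a dense layer with
softmax trained by categorical cross-entropy (label-based metrics make this
the natural choice). Hyperparameters stated by the reference design are
used verbatim: alexnet1d's filters 32/64/128 with kernel 3, pool 2 and
dropout 0.4; resnet1d's stem kernel 9 with 24 filters and pool 3, residual
block filters 32/64/128 with kernel 3 and a single-conv shortcut; mscnn's
branch kernels 3/7/9. Where the design is genuinely open the defaults are:

- hidden dense width 128 (alexnet1d, mscnn);
- mscnn branch filters 32 per branch, pool 2, dropout 0.4 (consistency
  with the one stated dropout rate);
- msresnet branch filters 16/32/64 with branch pool 3 — the multi-scale
  front end replaces the resnet stem, so it adopts the stem's pool size;
- residual shortcut is a kernel-1 conv projecting to the block's channel
  count, one per block ("same parameters" is read as the same
  hyperparameter pattern, since shared weights would be shape-inconsistent
  across 32/64/128 blocks);
- no stride inside residual blocks; lengths are reduced only by the stem
  pool and the final global average pooling.

All of these are constructor keyword arguments, not hard-coded constants.

Graphs are declarative (`LayerGraph`): nodes with kind + hyperparameters,
explicit edges including branch/merge and shortcut links, JSON-serializable,
with shape propagation and exact trainable-parameter counting independent
of the execution engine.

## Execution engine

No deep-learning framework is used: `ftirnet.nn` materializes a layer graph
into numpy layers with hand-derived reverse-mode gradients (convolution via
sliding-window views contracted by BLAS, batch normalization with running
statistics and momentum 0.1, inverted dropout, fused softmax/cross-entropy)
and an Adam optimizer (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, bias-corrected).
Activations are float32; losses accumulate in float64. Every gradient path
is validated against central finite differences in float64 (absolute
tolerance 10⁻⁷ at the whole-network level). All randomness — weight
initialization (He), batch shuffling, dropout masks — flows from one
generator seeded by the training config, so runs are bit-reproducible.

Numerical edge cases: constant spectra under min–max normalization map to
zero with a warning instead of dividing by zero; non-finite losses or
gradients abort training with a numeric error naming the epoch; max-pool
drops a trailing remainder shorter than the window (826 → 275 under
pool 3); probabilities are clipped at 10⁻¹² inside the log-loss.

## Protocol

`split_train_test` draws a single 7:3 sample-level split (224/96 for 320
samples). The default split is simple random — per-class test counts
fluctuate, as they do in the published per-class denominators — with a
stratified variant available. `make_folds` partitions the 224 training
ids into five folds (sizes 45/45/45/45/44), each serving once for
validation. Cross-validation is used only to report mean±SD validation
accuracy; the reported model is retrained on the full training set with
final-epoch weights (no early stopping, schedule or weight decay) and
evaluated once on the untouched test set. Disjointness of fit/validation/
test ids is asserted at run time in every experiment.

## Metrics

All scalar metrics derive from one integer confusion matrix (rows = true):
accuracy = trace/total; per-class accuracy = recall; sensitivity = macro
recall (pinned by the identity between the published per-class cells and
the published overall sensitivity); precision = macro precision with
never-predicted classes contributing 0 under a logged warning;
specificity = macro one-vs-rest TN/(TN+FP), which for k equal classes
equals 1 − (1 − accuracy)/(k − 1) exactly. ROC curves and AUCs are
one-vs-rest per class (scikit-learn trapezoidal integration, equal to
brute-force pairwise concordance with ties at 0.5 — tested), macro-averaged
over classes, with a separately labelled micro (pooled) AUC. Tables print
4 decimal places; cohort statistics 3.

Cohort statistics: Pearson χ² without continuity correction on the
group × sex table, and a one-way ANOVA reconstructed from per-group
(mean, SD, n) summaries — between-group mean square from the means and
sizes, within-group from the pooled variances. Reconstructing an F
statistic from *rounded* published summaries does not generally reproduce
the originally computed value, so the ANOVA is reported as computed and
checked only against algebraic identities (F = t² for two groups, F = 0
for equal means).

## Problem sizes in the checked experiments

The synthetic recovery test trains the multi-scale residual network for 30
epochs on the default-size easy dataset (320 averaged samples) and requires
held-out accuracy ≥ 0.9; with defaults it reaches 1.0. The chance-level
control trains all four architectures for 6 epochs on 20-sample-per-class
null datasets over five seeds — the null property is size-invariant by
construction, and the smaller size keeps the suite fast — and requires the
mean accuracy to sit within three standard errors of 1/4. Epoch counts for
these checks are choices of this package (the emulated protocol's 200
epochs are the `TrainConfig` default).

## Known limitations

- The engine is CPU/numpy; training at the full 200-epoch protocol is
  minutes, not seconds, and there is no GPU path.
- No resampling between wavenumber grids; mixed-grid inputs are an error.
- The JCAMP-DX reader covers only uncompressed (X++(Y..Y)) tables with
  XFACTOR/YFACTOR/NPOINTS records.
- Synthetic spectra are amplitude-pattern caricatures of serum FTIR (see
  above); conclusions about clinical performance require real spectra.
- Batch-norm statistics make training results depend on batch composition;
  determinism holds for a fixed seed and batch size but not across them.
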