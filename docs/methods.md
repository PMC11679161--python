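# Methods

This note documents the models, algorithms and design choices behind
`mbtcn`: a five-class (AAMI N/S/V/F/Q) single-lead ECG beat classifier built
from a multi-branch convolutional front end, multi-head self-attention, and
a lightweight temporal convolutional network (TCN), together with the
class-balancing workflow and the synthetic beat generator used to exercise
the whole pipeline without any data download.

## Preprocessing

Input records are annotated single-lead traces at 360 Hz.  Denoising uses a
Butterworth band-pass of order 4 with a 1–40 Hz passband — low enough to
remove baseline wander, high enough to cut electromyographic noise — applied
forward-backward (`scipy.signal.sosfiltfilt`), so the filter is zero-phase
and annotated R-peak positions are not shifted.  The order is configurable;
the band is the classifier's working definition of "ECG band".

Beats are fixed 250-sample windows: 100 samples before and 150 after the
annotated R-peak (≈ 0.694 s at 360 Hz), reflecting the empirical observation
that the R-peak sits in the latter half of the beat cycle.  Windows that
would cross a record boundary are dropped, not padded.  Each record's first
9 and last 5 annotated beats are discarded (keep ordinals 10 … n−5,
1-based) to avoid unstable record edges; the trim is applied to the full
annotation list *before* non-beat symbols are excluded, and both skips are
configurable.  Annotation symbols map onto the five AAMI classes
(N ← {N, L, R, e, j}; S ← {A, a, J, S}; V ← {V, E}; F ← {F};
Q ← {/, f, Q}); any other symbol excludes the beat.

Features are z-scored, `X' = (X − μ)/σ`, with per-feature statistics and the
*population* standard deviation (ddof = 0).  Zero-variance features map to
0 rather than dividing by zero.  By default the standardizer is fitted on
the training split only and applied to validation/test — fitting on the
pooled data before splitting leaks test statistics into training, so the
pooled order is available only behind an explicit switch
(`PipelineConfig.standardize_first`).

WFDB I/O is a minimal clean-room implementation of the documented format
subset (format-16 signals, `.hea` headers, MIT `.atr` annotations with SKIP
escapes); it is validated by write/read round-trips against the generator.

## Class balancing

The majority class N is undersampled *cluster-proportionally*: K-means
(Lloyd's algorithm with k-means++ seeding, convergence when the largest
centroid displacement falls below `tol`, empty clusters re-seeded from the
farthest point) partitions the N beats into K = 10 clusters; each cluster
contributes `S_k` samples with `S_k` the largest-remainder rounding of
`P_k · N_target`, `P_k` the cluster's share.  Largest-remainder rounding
makes the quotas sum exactly to `N_target`.  `N_target` defaults to 2.3 ×
the largest minority-class count, which reproduces the published ratio of
kept-N to the largest minority class.  K = 10 keeps enough clusters to
preserve the morphological diversity of class N without starving quotas.

After undersampling, the data are split 80:20 into train-pool/test and the
pool again 80:20 into train/validation (stratified by class by default).
Only the training split is then modified: minority classes S and F are
raised to the median training-class size by SMOTE — synthetic rows
`x_new = x_i + λ(x_j − x_i)` with `x_j` one of `x_i`'s k = 5 nearest
same-class neighbours and `λ ~ U[0, 1]` — and the result is cleaned by one
round of Tomek-link removal (mutual nearest neighbours of different classes;
the globally-more-frequent class member of each link is deleted, both on a
tie).  Nearest neighbours use exact Euclidean distance with
lowest-index tie-breaking, computed by the dot-product expansion in chunks
so memory stays linear in n.

`BeatMatrix.synthetic_flags` marks rows *created by augmentation*: SMOTE
rows carry the flag, and the balancing workflow guarantees that validation
and test splits contain none.  The pipeline clears the generator's
provenance flags when generated beats become a study's source data, so the
guarantee is meaningful end-to-end.  Undersampling runs before the
test split (so test composition depends on the clustering seed — recorded
in the balance report); oversampling runs strictly after it.

## Network

Input is one beat, 250 × 1.  Three parallel branches each apply
conv(kernel₁, dilation 1) → ReLU → batch-norm → max-pool(2,2) →
conv(⌊kernel₁/2⌋, dilation₂) → ReLU → batch-norm → max-pool(2,2) with
length-preserving padding, so each branch emits ⌊⌊250/2⌋/2⌋ = 62 steps.
Tuned kernels are 4/14/62 with second-layer dilations 1/2/4 and 16 filters
per convolution; a wider published layer template (kernels 12/22/48, 48→64
filters, 6-filter TCN) ships as `ModelConfig.wide_template()`.  Branch maps
are concatenated channel-wise (d = 48) and batch-normalized.

Multi-head self-attention (h = 4 heads, d_k = d/h) computes per head
`softmax(Q_i K_iᵀ/√d_k) V_i` with `Q_i = X W_i^Q` etc., concatenates the
heads and projects with `W^O`.  No positional encoding is injected, so this
stage is permutation-equivariant over time steps (a documented property:
order information reaches the head only through the TCN).

The TCN is 4 residual blocks of two dilated *causal* convolutions each
(kernel 8, 10 filters, ReLU → batch-norm → dropout 0.4 after each), with
dilations doubling 1, 2, 4, 8 — receptive field 1 + Σ 2(k−1)d = 211 steps —
and an additive skip (identity, or width-1 convolution on channel change):
`y = ReLU(F(x) + skip(x))`.  A flatten and a 5-way dense softmax head with
an L2 penalty (λ = 10⁻⁴, dense weights only, as the architecture table
marks) complete the model.  The tuned configuration totals 34,843 persisted
parameters ≈ 0.133 MB in float-32, within the published 0.15 MB envelope.

The network and its gradients are implemented on a small reverse-mode
autodiff core over numpy (`mbtcn.nn`): convolutions gather dilated taps as
contiguous slices and reduce to BLAS matmuls; every layer's gradient is
verified against central differences in the test suite.  Convolution taps
follow the causal orientation `y_t = Σᵢ fᵢ·x_{t−d·i}`.

## Training

Loss is multi-class focal loss `−α_t (1−p_t)^γ log p_t` averaged over the
batch, with the tuned scalar α = 0.76943 applied to every true class
(a per-class α vector is supported) and γ = 2.  At γ = 0, α = 1 the loss
is exactly categorical cross-entropy.  The probability-surface form clips
probabilities to [10⁻⁷, 1−10⁻⁷] before the log; the training loop instead
computes the identical value from logits via log-softmax
(`focal_loss_from_logits`), because a hard clip before the log zeroes the
gradient of any sample whose true-class probability underflows the clip —
enough to leave a whole class permanently dead once the network becomes
confidently wrong on it.

The learning rate ramps linearly from 10⁻⁴ to 7·10⁻⁴ over
`warmup_steps = ⌊epochs · n_train / batch⌋` steps (floored so the boundary
identity with the decay phase holds exactly), then decays as
`7·10⁻⁴ · 0.97^((step − warmup)/1500)` with a real-valued exponent
(a staircase switch exists), floored at 10⁻⁵.  Note the warmup-step formula
spans the whole nominal run; the decay phase is reached only when early
stopping extends past it or `warmup_steps` is set explicitly.
The optimizer is Adam (β₁ = 0.9, β₂ = 0.999) — unstated upstream, standard
for this model family.  Early stopping halts after `patience` (default 10;
pipeline default 5) consecutive epochs without a validation-loss improvement
greater than `min_delta` = 10⁻⁴ and restores the best-validation-loss
weights.  Default geometry: 80 epochs, batch 64.

Batch-norm uses ε = 10⁻⁵ and EMA momentum 0.99.  Because that EMA needs
thousands of steps to forget its (0, 1) initialization, inference statistics
are *re-estimated per epoch*: the mean of the epoch's batch moments replaces
the running statistics at each epoch end ("precise BN").  This is free — the
moments are already computed — and makes eval-mode behaviour match the
trained network at any training scale.

All randomness (initialization, shuffling, dropout, SMOTE, splits,
clustering, generation) flows from explicit seeds; two runs with the same
seed reproduce histories, balance reports and manifests exactly.

## Evaluation

Confusion matrices use the fixed class order N, S, V, F, Q.  Per-class
precision TP/(TP+FP), sensitivity TP/(TP+FN), F1 and specificity come from
the one-vs-rest reduction; overall accuracy is trace/total (the multi-class
reading consistent with the published per-fold tables); macro metrics are
unweighted five-class means; zero denominators yield 0 with a warning.
Display rounding is half-up to two decimals.  AUC is one-vs-rest per class
via the rank statistic (ties counted half, `sklearn.metrics.roc_auc_score`),
macro-averaged over the classes present; the macro (not micro) average is
assumed for the published AUC column.  Cross-validation is k = 5 fold,
stratified by default (plain random folds behind a switch — stratification
keeps minority-class metrics defined at desk scale); standardization and
balancing are re-fit inside each training fold, and fold sizes differ by at
most one.

## Synthetic data

Each beat is a sum of Gaussian waves (the P-QRS-T decomposition) from
frozen per-class templates: N has the full P-QRS-T; S has a diminished,
early ectopic P; V is wide, P-free, with discordant T; F is the exact
midpoint blend of N and V; Q is a flattened low-amplitude complex.  The R
apex of every template sits at sample 100 so generator geometry matches the
segmentation window.  Realism controls: white noise (σ 0.03 mV), baseline
wander (0.10 mV at 0.3 Hz), 50 Hz powerline interference (0.05 mV), and
small jitter of wave amplitudes (10%), widths (10%) and off-QRS centers
(3 samples).  Default class proportions are 68.5/2.5/6.5/0.7/21.8% for
N/S/V/F/Q, mirroring the benchmark database's printed composition so the
balancing code paths face a realistic imbalance.  Records concatenate beats
at 0.8 s RR spacing with true R indices written as annotations (symbols
drawn from each class's annotation-symbol pool) and can be written as WFDB
triples.

What the generator does *not* emulate: inter-patient variability, rhythm
dynamics (RR-interval structure across beats), pathological noise bursts, or
the within-class morphological diversity of real archives.  Templates are
linearly separable by construction (a nearest-centroid classifier exceeds
99% on noise-free draws), so pipeline results on synthetic data demonstrate
that the machinery works — segmentation, balancing, optimization, metric
flow — not that the model would reach the published accuracy on real
records.

## Desk-scale study conditions

The end-to-end synthetic study uses 5,000 beats in 5 records, the default
imbalance, the tuned architecture, batch 64 and 15 epochs with patience 5 —
sizes chosen so the whole study (balanced plus unbalanced comparison) runs
in minutes on one CPU while still exercising every stage at realistic
class ratios.  The pipeline sets an explicit 2-epoch learning-rate warmup
(`PipelineConfig.warmup_epochs`): under the default warmup-equals-total-
steps geometry the learning rate stays near its 10⁻⁴ floor for the whole
desk-scale run, which is too little drive to escape early class-collapse
basins in a dozen epochs.  The out-of-scope Bayesian hyperparameter search is replaced
by shipping the published optima as defaults; every hyperparameter remains
exposed in configuration.

## Known limitations

* The numpy training loop is single-threaded and desk-scale; it is not a
  GPU framework replacement.
* The focal-loss α is a scalar by default; the per-class vector is untuned.
* Tomek-link removal recomputes exact nearest neighbours each round
  (O(n²) per round in time, O(n·chunk) in memory).
* Attention weights are exposed for inspection but no attribution analysis
  is provided.
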