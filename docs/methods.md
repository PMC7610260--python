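# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests demonstrate.

## Fingerprint representation

A spectrum is a centroided peak list (strictly increasing m/z, nonnegative
intensities). Fingerprints live on a uniform grid of `n_bins` half-open
intervals over `[mz_min, mz_max]` (default 881 bins over 100–1000 Da, bin
width ≈ 1.0215 Da; the last bin is closed so a peak exactly at the upper
edge is kept). Peaks are accumulated by **sum** within a bin — summing
conserves total ion current, unlike max-pooling — and peaks outside the
range are dropped and tallied, so `binned + dropped = total` intensity is an
exact invariant. Per-sample total-ion-current (TIC) normalization to unit
sum removes acquisition-scale differences; it is idempotent and leaves
cosine similarity unchanged. mzML input is read directly (base64
float32/float64 arrays, plain or zlib-compressed); only centroided data are
supported — peak picking, baseline correction and recalibration are out of
scope.

## The locally connected classifier (SN) and its multi-modal variant (CSN)

Spectra are structured 1-D signals in which *position is identity*: bin 49
is always the same metabolite mass window. A convolution's shared weights
would force every region to use the same filter; the SN instead uses
**locally connected** layers — sliding windows (kernel ~9–11, stride 3)
where every output position owns its weights. Four such layers (channels
8, 8, 16, 16) reduce 881 bins to a 7-position, 16-channel representation
that a fully connected "feature-interaction" stack (64 → 16 units, ReLU,
dropout 0.5) maps to a 2-class softmax. The CSN concatenates the clinical
vector with the flattened spectral features at the entry of the interaction
stack, so both modalities shape all downstream weights.

Kernel widths are chosen per layer as `9 + (w − 9) mod 3` so the strided
windows tile each layer's input **exactly**. This matters: with a fixed
kernel the leftover tail of a layer falls outside every receptive field,
and any planted marker in those bins would have an identically zero
gradient — invisible to both the classifier and the saliency map. (This
failure mode was observed directly during development and is guarded by
tests.)

Training: softmax cross-entropy, mini-batch Adam (batch 32, learning rate
3e-3), decoupled weight decay 1.0 on weight matrices (biases exempt),
dropout 0.5 in the interaction stack and 0.25 on the input bins, for up to
80 epochs. A stratified 10% holdout of the training rows monitors
cross-entropy; the default schedule runs the full 80-epoch cap and restores
the best-holdout-epoch weights, and a smaller `early_stop_patience` stops as
soon as the monitor stalls. Input-bin dropout deserves a note: with 20
informative bins and ~250 training samples, an unregularized network
happily rides a small subset of markers (or memorizes noise); randomly
silencing a quarter of the input bins each step forces redundant use of
*all* informative bins, which is what makes gradient saliency recover the
full planted panel rather than a fragment of it. These defaults were set
jointly with the weight decay by their effect on held-out AUC and planted-
panel recovery on synthetic cohorts; all are configurable.

Inputs are standardized per bin (mean/sd of the training rows); clinical
columns are median-imputed (training medians) then z-scored. All
randomness — initialization, shuffling, dropout, holdout selection — flows
from one integer seed; inference disables dropout, so prediction is a pure
function and refitting with the same seed and data is bitwise reproducible.

For narrow inputs (a clinical table of ~3 columns, or a small feature
panel) a sliding window wider than the input is meaningless;
`arch_for_width` then shortens the stack and ultimately degrades to a plain
MLP (`lc_layers=()`). The clinical-indexes-only model in the pipeline report
is exactly that degenerate case of the same family.

## Baselines

OPLS-DA is implemented from scratch. With X column-standardized and
y ∈ {−1, +1} centered: the predictive weight is `w ∝ Xᵀy`; each orthogonal
component takes the loading `p` of the current predictive score, removes its
projection on `w`, normalizes (`w_o`), and deflates `X ← X − t_o p_oᵀ` with
`t_o = X w_o`. Because `Xᵀy ∝ w` is invariant under these deflations, every
orthogonal score satisfies `t_oᵀy = 0` exactly (tested to 1e-8), and with
zero orthogonal components the model *is* single-component PLS1 (verified
numerically against an independent PLS implementation). Out-of-sample
prediction applies the stored centering, strips each stored orthogonal
component, projects on `w`, and scales by the y-loading; the continuous
score feeds the same ROC machinery as every other model. Constant feature
columns are dropped with a warning. The default is one orthogonal
component; `select_n_orthogonal` picks it by internal CV when desired.

LASSO-penalized logistic regression, random forest and RBF-SVM are
adapters over scikit-learn, each wrapped in standardization where
appropriate and tuned by internal stratified 5-fold CV (penalty path,
`max_features`, `C`); they are comparison methods, not contributions, and
their continuous scores (probability or decision function) enter the ROC
harness unchanged.

## Evaluation statistics

* **AUC** is computed from placement values (fraction of opposite-class
  samples outscored, ties half-weighted); it equals the Mann–Whitney
  concordance probability and is tested exhaustively against pair counting.
* **DeLong** variance and CI use the placement-value (structural
  components) estimator; the CI is on the identity scale clipped to [0, 1]
  (logit scale available). Values match R's `pROC` on a frozen instance.
  The paired test uses the 2×2 covariance of the two models' placement
  vectors; identical score vectors define `p = 1`.
* **Youden threshold**: candidate cuts are midpoints between adjacent
  sorted unique scores plus ±∞ sentinels; the cut maximizing
  `sensitivity + specificity − 1` wins, ties broken toward higher
  specificity (a screening context favors fewer false alarms among
  controls) and then the higher cut. "Case" means score strictly greater
  than the threshold. Thresholds are always fixed on discovery and applied
  unchanged to validation.
* **Cross-validation**: stratified k-fold (k = 10 by default); metrics are
  computed per fold and averaged, not pooled.
* **Permutation test**: statistic = mean CV AUC of the supplied fitting
  procedure; `p = (1 + #{permuted ≥ observed})/(B + 1)` with B = 999 by
  default, so the smallest attainable p is 0.001 and p is never zero.
* **Power analysis**: two-sided two-sample normal approximation,
  `n/group = 2((z_{1−α/2} + z_{power})/d)²` rounded up. At α = 0.15,
  power 0.9 and a standardized effect of 0.70 the minimum total is 62.

## Saliency feature selection

Per-sample saliency is the absolute gradient of the case-class *logit*
(pre-softmax, dropout off) with respect to each input bin, chained through
the stored standardization so it refers to the inputs as supplied. The
vanilla gradient is the default and only operator here; smoothed or
occlusion variants are out of scope. Aggregation is the arithmetic mean
over all discovery samples (configurable to per-class); the top-k bins
(k = 20) form the panel, ties broken toward the lower bin index. Regulation
direction is called from case/control mean intensities on discovery
(fold change recorded; no multiple-testing correction, since the panel is
selected by the model, not by per-bin tests). The 2-D square layout
(ceil(√n) × ceil(√n), row-major, zero-padded) exists for visualization
only — the network consumes 1-D inputs, so the layout provably cannot
change any saliency value, and padded cells are flagged and excluded.

`refit_on_panel` trains a fresh network restricted to the panel's bins and
evaluates it under the standard harness, quantifying how much of the
discriminative signal the panel retains.

## Synthetic cohorts

The generator emulates the *shape* of a fingerprint-based case-control
study, not mass-spectrometric physics. Per bin, log-intensity is
`N(baseline_log_mean = 2.0, baseline_log_sd = 0.5)`, independent across
bins; planted bins shift the case mean by ±log(effect size) — effects are
multiplicative on intensity, matching how up/down regulation is described.
An optional shared per-sample factor (`tic_log_sd`, 0.25 in the
study-scale configurations) emulates total-ion-current drift and makes TIC
normalization consequential. Clinical columns are normal with
class-specific means; missing values are injected completely at random.
The default study configuration uses 172 controls / 172 cases, 881 bins,
20 planted bins at 2-fold effect and 5% clinical missingness; the 4:1
stratified split apportions validation samples by largest remainder (ties
toward controls), yielding discovery 275 = 137/138 and validation
69 = 35/34. A second generator plants signal in pairwise *products* of
adjacent bins (class-dependent correlation sign, identical marginals) — a
signal invisible to linear models, used to probe the network's nonlinear
advantage; adjacency puts each pair inside shared locally connected
windows, mirroring co-varying neighboring peaks.

What this does **not** emulate: peak-shape and centroiding artifacts,
mass-calibration drift, heteroscedastic detector noise, correlated
metabolite modules, batch effects, or realistic effect-size spectra.
Passing tests therefore demonstrate the *machinery* (recovery of known
truth under the stated noise model, calibration of the statistics), not
clinical performance on real serum.

## Problem sizes and numerical choices

Study-scale checks run at the clinical cohort shape (344 samples, 881
bins); calibration checks use 500 simulations at n = 40/40; the
permutation-test null uses a cheap class-centroid scorer so hundreds of
refits stay inexpensive; recovery medians use 10 replications (5 per point
across the effect-size sweep). Degenerate cases are defined explicitly:
all-zero fingerprints refuse TIC normalization; zero-norm vectors refuse
cosine similarity; single-class label vectors refuse AUC, training and
fits; AUC exactly 0 or 1 yields a point CI with the clip noted; identical
paired scores give p = 1. Null-calibration bands inherit the irreducible
placement noise of a 69-sample validation set (AUC sd ≈ 0.07 at chance
level), which is why null-AUC checks are stated over repeated independent
replications rather than single runs.

## Known limitations

* The NumPy training loop is single-threaded and CPU-bound; it is sized
  for hundreds of samples and ~10³ bins, not for larger studies.
* Locally connected layers are parameter-hungry (no weight sharing); with
  very small cohorts the heavy regularization defaults matter, and
  hyperparameters were chosen on the synthetic conditions documented above.
* OPLS-DA is binary-response only; VIP-score selection is intentionally
  absent (selection here is saliency-based).
* mzML support reads the first spectrum of a file (one file per sample);
  vendor formats and profile-mode data are unsupported.
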