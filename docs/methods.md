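# Methods

## Time-independent profile representation

A cumulative release profile is a sequence of (time, % released) pairs,
strictly increasing in time, with at least two points. Two normalizations
make profiles of different durations and plateaus comparable:

* **Time** is min-max scaled, t̃ = (t − t_min)/(t_max − t_min), so every
  profile runs over [0, 1]. The scaling is invariant to affine changes of
  the time axis (unit conversions, shifted starting points).
* **Magnitude** is divided either by 100 (`percent` mode, fraction of the
  loaded drug) or by the profile's own maximum (`max` mode). `max` is the
  default for shape analysis because it makes the AUC a pure shape
  descriptor, independent of the plateau a profile happens to reach;
  `percent` is the default for the early-release targets, which are
  physically fractions of the loaded dose. Which convention published
  compilations use for the AUC is not always stated, so both are exposed;
  the class counts of a given compilation can arbitrate.

Profiles whose first sample falls after t = 0 are anchored with an implicit
(0, 0) point before interpolation — cumulative release is physically zero at
injection. Linear interpolation between knots resamples each profile onto a
uniform grid of T points including both endpoints. T = 101 (step 0.01) by
default: fine enough that the trapezoid error of the AUC (O(T⁻²)) is far
below measurement noise, small enough that sequence models stay cheap.
Values are *not* forced monotone by default (`enforce_monotone=False`):
small assay-noise dips are genuine data features.

The **AUC** of the normalized curve is computed by the trapezoidal rule.
0.5 corresponds to a perfectly linear release; the binary release type is
0 (monophasic / delayed biphasic / triphasic) for AUC ≤ 0.5 — the boundary
is deliberately inclusive, so a perfectly linear curve is class 0 — and
1 (burst biphasic) otherwise. Early-release targets are the interpolated
fractions at 24, 48 and 72 h; profiles shorter than the requested hour are
rejected rather than extrapolated.

## Synthetic study generator

The generator emulates the structure of compiled PLGA microparticle
studies so every downstream stage has a ground truth. Each of n
formulations draws 11 descriptors from fixed ranges (drug MW log-uniform
150–5000 Da; polymer MW log-uniform 5–150 kDa; LogP uniform −3–8; TPSA
uniform 20–300 Å²; particle size log-uniform 1–200 µm; encapsulation
efficiency uniform 20–99 %; loading capacity uniform 1–30 %; drug:polymer
ratio uniform 0.05–0.5; LA/GA from the common molar ratios 50:50–85:15;
solubility enhancer 0 in half the media, else up to 5 %; one of four
emulsion methods). Durations are log-uniform over 3–120 days; sampling
times are irregular and denser early; plateaus span 65–100 % released;
Gaussian measurement noise (sd 0.02 release fraction, small relative to
inter-template differences) is added and clipped at zero.

Release shapes come from four kinetic templates:

* monophasic: y = t/t_end (AUC exactly 0.5);
* burst biphasic: y = b(1 − e^(−k₁t)) + (1 − b)(1 − e^(−k₂t)) with k₁ ≫ k₂ —
  a sum of concave curves, so AUC > 0.5 for *any* positive rates;
* delayed biphasic: a logistic erosion onset rescaled to [0, 1] with its
  midpoint past half the duration (AUC < 0.5);
* triphasic: a small fast burst (≤ 15 % of mass) plus a late logistic
  erosion phase (AUC < 0.5 across the default parameter ranges).

Two kinds of feature→kinetics links provide recoverable ground truth, both
deliberately monotone and (log-)linear so attribution recovery is
unambiguous:

* an **early-release propensity** e = −1.0·z(EE) − 0.8·z(log polymer MW)
  − 0.6·z(log particle size), standardized against the sampling
  distributions (not the realized sample); e modulates every template's
  burst fraction, burst rate and erosion lag monotonically, so higher
  encapsulation efficiency, polymer MW and particle size always lower
  early release;
* a **class probability**: the delayed-class probability is the configured
  mixture weight (default 0.26, mirroring the 84:237 imbalance of the
  compiled data the generator emulates) shifted linearly by drug LogP
  (+0.30 across its range) and drug MW (+0.15), centred so the marginal
  class balance stays at the mixture. Degenerate mixtures (0 or 1) are
  honoured exactly.

Everything is driven by one integer seed; identical seed and configuration
reproduce the dataset bit for bit.

**What passing tests do not show.** Durations, templates and plateaus are
drawn independently of the descriptors, so a large share of the variance in
early release is irreducible from the features — held-out correlations on
synthetic data are structurally lower than the 0.6-ish values reported on
real compilations, where duration itself correlates with formulation
chemistry. The generator validates protocol correctness (leak-free CV,
attribution recovery, shape taxonomy), not real-data effect sizes. It is
also not a mechanistic PLGA degradation model: templates are phenomenological
curve families, and covariances between descriptors (e.g. loading capacity
vs. encapsulation efficiency) are absent.

## Tabular models

The formulation method is one-hot encoded (categories fixed on the training
fold; unseen categories at transform time map to the all-zero vector with a
warning instead of crashing on external data). Continuous descriptors are
z-scored with training-fold statistics only; zero-variance columns
standardize to zeros; missing continuous values are imputed with the
training-fold median. Model families: ordinary least squares / logistic
regression (liblinear), random forests (scikit-learn) and gradient-boosted
trees (xgboost, labelled "XGB" in reports). Hyperparameter names and ranges
are encoded per family — logistic C 1e-4–1e4 (log), penalty l1/l2, max_iter
200–1000, class weight none/balanced, tol 1e-6–1e-3 (log); random forest
50–300 estimators, depth 3–20, min split 2–20, min leaf 1–10, max features
sqrt/log2, bootstrap on/off; XGB depth 3–20, learning rate 0.01–0.3, 50–300
estimators, colsample 0.5–1.0, gamma 0–5, alpha and lambda 0–1 — and every
spec validates against its space at construction.

The **time-as-input baseline** expands each training formulation into T
rows (features ⊕ t̃ → release value) and fits one boosted-tree regressor;
prediction evaluates all grid points per formulation. Its no-time ablation
drops the t̃ column, making all grid points of a formulation identical
inputs — the model can then only emit flat profiles, which is the point of
the comparison.

## Sequence model

The static-to-sequence network (embedding FC + ReLU → repeat T× → LSTM/GRU
stack → linear head) is implemented directly in NumPy with manual
backpropagation through time and an Adam optimizer; the analytic gradients
are checked against central finite differences in the test suite. Design
choices the architecture sketch leaves open are fixed as: one hidden
embedding layer of width f = 64 (f is not tuned), a linear output head (no
squashing; evaluation clips to [0, 1.1] only for reporting), Adam as the
first-order adaptive optimizer, dropout applied between recurrent layers
only when there is more than one layer (independent masks per time step),
and batch-mean loss per update. Weights use PyTorch-style uniform
±1/√h initialization (He-scaled normal for the embedding); training is
fully seeded and deterministic. Tunable choices match the encoded search
space: hidden size {32, 64, 128, 256}, layers {1, 2, 3}, cell {LSTM, GRU},
dropout {0.2, 0.3, 0.4}, learning rate {1e-3, 1e-4}, batch size
{16, 32, 64, 128}. A non-finite loss aborts training with the offending
configuration named.

Time-independence is structural: the forward pass consumes only the feature
matrix; the time grid exists solely as the repeat count T.

## Evaluation protocol

10×2 nested cross-validation: ten outer folds (sizes ⌊n/10⌋ or ⌈n/10⌉);
per outer fold a 2-fold split of the training rows; a seeded random search
(default 50 trials) picks the candidate with the best mean inner-validation
score (−RMSE for regression and profiles, F1 for classification); the
winner is refit on the full nine folds and scored on the held-out fold.
Standardization statistics are fit once per outer fold on the nine training
folds, per the protocol, and reused for inner tuning — the held-out fold
never contributes. The per-(fold, family) search stream is seeded
independently of the data, so corrupting held-out rows provably cannot
change the tuned hyperparameters (asserted in the acceptance suite).
Sequence models train 250 epochs during tuning and 500 for the outer refit
by default.

Folds are stratified by class for classification and by the true profile's
AUC class for profile prediction; the 0.26/0.74 imbalance otherwise yields
occasional single-class folds. Regression folds are unstratified. Pearson
correlation is reported on the pooled out-of-fold predictions (a single
pooling rule, stated here because fold-averaged correlations are not
comparable across fold sizes). Per-profile RMSE is additionally broken down
by the true AUC class (≤ 0.5 vs > 0.5) and by finer AUC bins; empty groups
are omitted with a warning rather than reported as NaN.

Degenerate-input conventions: AUROC with a single-class truth is NaN with a
warning (other metrics still returned); correlation with zero variance
raises; tied scores give AUROC 0.5; predicted labels are score > 0.5, so
labels and scores are consistent at that threshold.

## Shapley attribution

Attributions are exact for every supported family: closed-form
w_j(x_j − mean(background_j)) for linear and logistic models (on the
log-odds margin for the latter, with the training fold as background); the
boosted trees' built-in tree-path contributions; and an own implementation
of the path-dependent TreeSHAP recursion for random forests (classifier
trees are explained on the class-1 probability). The recursion is verified
in the tests against brute-force subset-enumeration Shapley values on small
trees — an independent oracle — and local accuracy (base + Σφ = model
output) is asserted for every explainer. In nested CV, each outer fold's
model explains its own test rows and the per-fold attributions are
concatenated; this convention is declared, not inferred.

Summaries: features ranked by mean |φ| (ties alphabetical), top-k share of
the total mean |φ| (flagged degenerate when all attributions are zero), and
a per-feature direction — the sign of the Spearman correlation between
feature value and attribution, with |ρ| < 0.1 or numerically-zero
attribution mass reported as neutral. Attributions for the sequence model
are out of scope; only the tabular tasks are explained.

## Numerical and interface choices

Times are handled in hours internally; day-denominated inputs are converted
(×24) at read time via a flag. Canonical files are comma-delimited text
with headers; floats are written at %.17g and parsed with round-trip
precision so write→read is exact. Duplicate (id, time) rows collapse to
their mean with a warning; profiles with fewer than two distinct times, or
zero time range, are rejected as degenerate. Extrapolation beyond a knot
bracket is refused everywhere except the documented (0, 0) anchor. The run
configuration is YAML validated against a closed key set before any
computation; the pipeline writes a manifest (config hash, seed, package
versions, stage timings) sufficient to reproduce any output byte for byte.

Problem sizes in the bundled tests are chosen to keep the full suite fast
on a single CPU: nested-CV checks run at n = 321 with 10 trials and tree
families; sequence-model checks use 200 formulations, T = 101 and 50
epochs (or smaller grids for unit tests). The protocol constants used for
real analyses — 50 trials, 250/500 epochs — remain the defaults.

## Known limitations

* The generator's feature→kinetics links are deliberately simple; models
  that exploit interactions or non-monotone effects are not stressed.
* Random-forest TreeSHAP is pure Python and O(trees × leaves × depth²) per
  sample; explaining large forests on large test sets is slow (the boosted
  explainer is the fast path).
* No mechanistic kinetics fitting (Higuchi, Korsmeyer–Peppas), no burst
  criterion (none is standard across drugs), no uncertainty quantification,
  no probability calibration, and no attribution for the recurrent model.
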