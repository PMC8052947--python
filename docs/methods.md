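# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `hrnv` package.

## Derived RR sequences

A recording is an ordered series of RR intervals (ms), assumed clean sinus
rhythm — no ectopic-beat or artifact correction is applied, and that is a
documented precondition, not a limitation of the arithmetic. Order-n
aggregation sums n consecutive intervals; non-overlapping windows advance n
beats (RRnI), overlapping windows advance m beats (RRnI_m, 1 ≤ m ≤ n−1).
Trailing beats that cannot fill a window are dropped, so every emitted value
is a true n-beat sum. Stream order is fixed (HRV, HR2V, HR2V1, HR3V, HR3V1,
HR3V2) to keep feature-vector layout deterministic.

## Parameter suite

Per stream, 24 parameters (22 for HRV, which has no scaled NN50n/pNN50n)
giving 142 named signal features. Choices where a convention had to be
fixed:

* **SDNN** is the sample standard deviation (ddof = 1). **Poincaré SD1/SD2**
  are population dispersions (ddof = 0) of the rotated lag-1 coordinates
  (x_{k+1} ∓ x_k)/√2: with that estimator SD1 = RMSSD/√2 holds to well
  within 1% at realistic lengths, which we use as a numerical cross-check.
* **Skewness/kurtosis** are the biased standardized third/fourth moments
  (kurtosis not excess-corrected); both are undefined (NaN) for
  zero-variance series.
* **Triangular index** uses the conventional 1/128 s (7.8125 ms) histogram
  bin width, with bin edges aligned to the absolute grid.
* **Spectral analysis** uses the Lomb–Scargle periodogram of the unevenly
  sampled tachogram (beat times = cumulative interval sums), with no
  resampling. The periodogram is evaluated from 1/(4·span) to the mean
  Nyquist frequency in steps of 1/(4·span) and scaled so that its integral
  over that grid equals the series variance; band powers are then absolute
  (ms²). A pure sinusoid of amplitude a recovers its theoretical power
  a²/2 to a few percent. Bands: VLF 0.003–0.04, LF 0.04–0.15,
  HF 0.15–0.4 Hz (standard short-term bands). Normalized powers use
  LF+HF as the denominator. The same construction is applied to aggregated
  streams, whose beat times are cumulative sums of the aggregated values.
* **SampEn/ApEn** use embedding dimension m = 2 and tolerance
  r = 0.2 · SD of the analysed sequence (field convention). SampEn counts
  template pairs once (i < j) over the first N−m templates for both lengths,
  self-matches excluded, and is NaN when no pair matches; ApEn includes
  self-matches. Both are validated against a brute-force O(N²) oracle with
  exact count equality.
* **DFA** integrates the mean-centred series and removes a least-squares
  line per box; α1 is the log–log slope over box sizes 4–16 (requires ≥ 30
  values), α2 over 16–64 capped at N/2 so every size has at least two
  complete boxes (requires ≥ 100 values; at least three sizes must remain).
  The plain estimator carries the well-known small-scale finite-size bias:
  on uncorrelated noise α1 averages ≈ 0.58 rather than the asymptotic 0.5
  (a random walk is recovered at ≈ 1.50 with negligible bias). We keep the
  conventional estimator rather than a bias-corrected variant, and tests of
  the theoretical limits average several independent series so that they
  probe the scaling exponent rather than single-draw noise.

Parameters whose preconditions fail (short streams, zero variance,
unmatched templates) are NaN — explicitly missing, never silently zero.

## Synthetic cohort

The generator is outcome-conditional: the binary outcome is drawn first at
the configured prevalence (default 0.31, n = 800), then covariates are drawn
given the group. This gives direct control of prevalence and per-variable
effect sizes for recovery testing, at the cost of not modelling a true
logistic link.

* **Clinical variables** (32): ten continuous (troponin and CK-MB simulated
  log-normally; effect sizes applied on the latent normal scale as
  standardized mean differences) and twenty-two binary (log-odds shifts;
  race simulated as one mutually exclusive category, outcome-independent).
  Twelve variables are informative by default, with directions matching the
  clinical picture (older, male, diabetic smokers with ischaemic ECG
  changes and raised troponin at higher risk). ECG-flag effects correspond
  to the large odds ratios such flags show in real cohorts
  (e.g. ST-elevation log-OR 2.0 from a 3% base rate).
* **Tachograms**: RR(t) = patient mean + LF and HF sinusoids + white noise,
  with the MACE group given a 20 ms lower mean RR, HF amplitude 15.5 vs
  18 ms and noise SD 21.5 vs 24 ms (reduced vagally mediated variability).
  Patients are heterogeneous — between-patient mean-RR SD 100 ms and a
  log-normal amplitude/noise dispersion with CV 0.4 — so no single feature
  separates the groups deterministically. The three dials were set by
  liability arithmetic so that each vagal feature carries a per-variable
  standardized difference of ≈ 0.2–0.35 (univariable significance on the
  scale clinical cohorts report for HRV measures), the aggregate HRV factor
  contributes d ≈ 0.45, the troponin surrogate remains the strongest single
  biomarker (d = 1.1), and the pooled discrimination of the full model
  lands near 0.9 with a visible drop when troponin is excluded — the
  structure reported for cohorts of this kind, rather than an HRV signal
  that would dwarf every clinical variable or flood the preselection with
  hundreds of near-duplicate significant features.
* **Scores**: HEART/TIMI/GRACE are bounded integer rounds of an
  outcome-linked latent mean plus Gaussian noise, giving the characteristic
  group medians (≈ 7 vs 4 for HEART) and AUCs in the realistic ordering
  (HEART > TIMI ≈ GRACE).
* **Determinism**: one spec seed is expanded through SeedSequence spawning
  into per-stage and per-patient streams; identical seeds reproduce cohorts
  exactly, distinct seeds differ.

What the generator does **not** emulate: genuine physiological coupling
(no IPFM or autonomic closed loop), intra-patient non-stationarity, ectopy
or measurement artifacts, missing data, or realistic correlation between
clinical variables beyond their common outcome link. Passing tests
therefore demonstrate that the pipeline recovers planted structure under
idealised sampling, not that it would perform identically on real ECGs.

## Preselection and stepwise comparator

Continuous candidates are screened with Welch's t-test, binary candidates
(≤ 2 distinct values) with the Yates-corrected chi-square test; p-values are
unadjusted (screening, not inference). The threshold sweep standardizes
inside each training fold, applies full-rank PCA (rotation only, so the
sweep isolates the effect of preselection), fits unpenalized logistic
regression and pools out-of-fold predictions; ties in AUC go to the larger
threshold. Retention is monotone by construction.

Backward stepwise starts from candidates with univariable p < 0.2 and
removes the largest Wald p until all are ≤ 0.05. Exactly collinear
candidates (the normalized-power pair sums to 100 in every stream; SD1 is a
deterministic function of RMSSD up to end effects) would make the
information matrix singular, so a pivoted-QR pass first reduces the
candidate set to a maximal linearly independent subset, and the Wald fits
use IRLS (GLM), which tolerates near-singular information — inflated
standard errors simply push redundant variables out early. Missing
predictor values are imputed with the column median.

## Dimensionality reduction

All eight methods sit behind one fit/transform contract and never see
outcome labels. Standardization (z-score, learned on the training fold
only) precedes every method except LSA, which receives the scale-only
matrix (divided by training SD, not centred) since its defining property is
operating on uncentred data; LSA is implemented as a truncated SVD and
checked to coincide with PCA up to sign on centred input. Kernel PCA uses a
degree-3 polynomial kernel with scale 1/(3·D̃): at sklearn's default scale
the cubic term dominates for z-scored features and visibly distorts the
embedding, whereas this choice keeps the polynomial expansion in its
near-linear regime with the higher-order terms as a perturbation. Random
projections draw their matrices from seeded Gaussian/sparse ensembles.
Isomap and LLE use a neighborhood that grows with the training set
(k = n/10, floor 10) — the standard consistency requirement for geodesic
and reconstruction estimates — and LLE switches to its modified variant
when k exceeds the target dimension.

Transductive methods are fitted strictly inside CV training folds to avoid
leakage, with explicit out-of-sample extensions: Isomap and LLE use the
standard kernel-regression/reconstruction-weight extensions; metric MDS is
fitted by SMACOF majorization initialised from the classical (Torgerson)
solution — making the fit deterministic — and embeds new points by
per-point stress majorization against the frozen training embedding (150
iterations, initialised at the mean embedding of the ten nearest training
points). A consequence worth noting: a study that fitted manifold methods
transductively on all data before cross-validation would report slightly
higher AUCs than this leakage-free protocol (we measured the difference at
about 0.03 AUC for MDS on the default synthetic cohort). Isomap in
particular remains several points below the linear methods on this
synthetic geometry at any neighborhood size, transductively or not:
neighborhood graphs built in a space whose ambient dimensions are largely
independent noise carry little class structure, a known failure mode that
the heavier-tailed, mutually correlated variables of real cohorts appear
to avoid.

The dimension sweep evaluates pooled out-of-fold logistic AUC per target
dimension (default grid 2–30, capped at D̃); the best dimension is the
smallest attaining the maximum. Downstream logistic regression is
unpenalized maximum likelihood with tight tolerances, which makes the AUC
invariant (to ~1e-6) under full-rank linear reparameterisations — used as
an internal correctness oracle for the PCA path.

## Evaluation

AUC uses the rank (Mann–Whitney) estimator with ties at one half, equal by
construction to trapezoidal ROC integration; its 95% CI comes from DeLong's
structural-components variance. Operating points minimise the Euclidean
distance to the ROC upper-left corner (ties broken toward higher
sensitivity); sensitivity/specificity/PPV/NPV carry Wald 95% CIs and the
underlying confusion counts are always reported. Calibration uses ten
equal-width probability bins with empty bins omitted. Clinical scores are
evaluated directly as ranking scores over their integer thresholds — no
refitting — which makes their rows identical between the with- and
without-troponin analyses; for calibration plots a score is min–max scaled
to [0, 1] as a probability proxy. Cross-validation is stratified 5-fold
with a recorded seed throughout.

## Problem sizes

The default synthetic analysis uses n = 800 patients with 5–6 minute
tachograms (~400 beats), a nine-point threshold grid, an eight-point
dimension grid and 5-fold CV; the oracle checks run at series lengths up to
300 beats and n = 200 for pairwise concordance. These sizes were chosen so
the full analysis, including both troponin variants, completes in minutes
on a single core while keeping every estimate comfortably away from
small-sample degeneracy.

## Known limitations

* The frequency-domain normalisation ties total power to the variance over
  the evaluated grid; power above the mean Nyquist frequency is folded into
  the rescaling rather than resolved.
* SampEn is undefined (NaN) for series with no matching templates; cohorts
  of very short or very irregular streams will carry missing entropy
  columns into median imputation.
* The stepwise comparator's aliasing pass uses a fixed QR tolerance (1e-8
  relative); pathological near-collinearity between that tolerance and
  working precision can still inflate Wald standard errors (by design it
  then removes those variables rather than crashing).
* MDS out-of-sample placement is a local stress minimiser; for points far
  from the training cloud the embedding depends on the nearest-neighbour
  initialisation.
* The α1 white-noise bias described above is inherent to plain first-order
  DFA at boxes 4–16 and should be kept in mind when comparing absolute α1
  values across packages.
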