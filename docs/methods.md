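# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Signal model of the simulator

Each subject's 4D scan is built voxel-wise as

    y_v(t) = Σ_trials a_v(trial, phase) · (boxcar ∗ HRF)(t) + drift_v(t) + ε_v(t)

with one boxcar per trial phase (anticipation of the trial-specific 4–8 s
duration; stimulation of 1 s), convolved with the canonical double-gamma
HRF.  All in-brain voxels respond with a common base amplitude (task
activity unrelated to the percept).  In *informative* voxels — voxels inside
a designated subset of non-control atlas regions — the amplitude differs by
perceived label: +e/2 on painful, −e/2 on non-painful trials, in the
phase(s) named by the signal specification.  The subject-level effect e is
drawn once per subject from Normal(μ_e, σ_e) truncated at zero, which
induces the random-effects structure the group permutation test assumes.
Amplitude units are arbitrary; every downstream step is invariant to a
global positive rescaling after standardization and l2 scaling (this is
property-tested).

Noise is stationary AR(1) per voxel (marginal sd `noise_sd`, lag-1
correlation `ar1_rho`, default 0.3), restarted at session boundaries, plus
session-wise drift: a random linear trend and a slow cosine (300 s period,
random phase/amplitude per voxel) scaled by `drift_amplitude` — slow enough
that the 128 s high-pass filter has work to do.  Labels are
Bernoulli(`label_balance`) per trial; by default a session × threat cell's
labels are redrawn until both classes are present, so leave-one-session-out
condition-split decoding is always defined.  The constraint is symmetric
under within-cell label exchange, so permutation inference remains exact
and expected chance accuracy stays 0.5 (verified by the null-calibration
test).  Threat is balanced n/2 : n/2 within each session.

Deliberate non-realisms: rectangular region blocks on a small grid (default
24³) instead of anatomical masks; no physiological noise, motion, or
spatial noise correlation (smoothing can induce the latter); no
psychometric threshold process — the near-threshold regime is represented
directly as a weak amplitude difference.  Consequently, passing tests show
that the *statistical machinery* behaves correctly under the structure it
assumes (session exchangeability, random effects, AR(1) noise); they do not
certify performance under real-scanner artifacts.

### Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| sessions × trials | 4 × 30 | the target experimental design |
| TR | 3 s | volume sampling interval |
| anticipation | U(4, 8) s | trial-specific cue–stimulus interval |
| inter-trial rest | U(6, 10) s | unreported in the design; a stand-in |
| effect μ_e, σ_e | 0.5, 0.25 | weak distributed signal, heterogeneous across subjects |
| noise sd, ρ | 1.0, 0.3 | AR(1) BOLD noise |
| drift amplitude | 1.0 | low-frequency confound scale |
| atlas | 26 + 2 regions | pain-related masks + auditory controls |

## Trial-wise GLM

One GLM per subject contains two regressors per trial (anticipation,
stimulation) plus one constant per session: for 120 trials, 240 trial
regressors.  Boxcars are built on a 0.1 s microtime grid, convolved with
the canonical HRF (response gamma shape 6, undershoot gamma shape 16, unit
dispersions, undershoot ratio 1/6, 32 s support, unit peak normalization),
and sampled at volume onsets (slice-time 0; no slice-timing correction).
Overlapping regressor support across trials is expected and allowed; the
design must merely be full-rank after filtering (a rank-deficient design
raises an error naming the collinear columns, found by pivoted QR).

High-pass filtering residualizes both data and design against an
orthonormalized discrete-cosine basis up to 1/128 s⁻¹, per session;
session constants are dropped under filtering because they lie in the
basis span.  Serial autocorrelation is handled by a single pooled AR(1)
coefficient estimated from the OLS residuals (sums over voxels and
sessions of lagged cross-products), followed by exact stationary AR(1)
whitening of data and design and one re-fit.  This one-pass
estimate-then-whiten scheme is a deliberate simplification of iterative
restricted-maximum-likelihood schemes used by standard fMRI packages; for
the simulated noise it recovers ρ and decorrelates residuals (tested), and
because the identical projection is applied to data and design, noiseless
recovery stays exact (tested to 1e−7).  Estimates of |ρ| ≥ 1 are clipped
to ±0.95 with a warning.  The beta series comes from one least-squares
solve per subject (`numpy.linalg.lstsq`); equality with the
normal-equations solution is an acceptance-level test (1e−8).

Whether trial-wise betas should come from one big GLM or from one GLM per
trial is a known fork (least-squares-all vs least-squares-single); the
240-regressor design implies the former, which is what is implemented.

## Feature pipeline and non-circularity

Within every outer fold, in order: ROI masking (fold-independent),
per-voxel standardization with mean/sd estimated on **training rows only**
(population, divide-by-n convention, so the fit-set sd is exactly 1;
zero-variance voxels get sd 1 and a flag), per-trial l2 scaling to unit
norm (row-local, hence leakage-free), then — for top-k analyses — a
two-sample pooled-variance t-contrast computed on training rows, ranking
by |t| descending with stable index tie-breaks and infinite |t|
(zero pooled variance, distinct means) above all finite values.  A
`scaling="global"` switch reproduces the variant in which standardization
precedes cross-validation on all trials; the default is the non-circular
per-fold fit, consistent with the principle that test data influence
neither training nor hyperparameters.  The mutation test asserts that
altering any fold's test trials changes none of that fold's trained
weights, chosen C, scaling parameters, or selected voxels.

## Decoding

The classifier is a soft-margin linear SVM (libsvm via scikit-learn,
`tol = 1e-6`; deterministic for binary problems).  Outer folds leave one
session out; C is chosen per fold by inner leave-one-trial-out accuracy
over the grid {10⁻³ … 10³} (configurable), ties resolved toward the
smallest C (stronger regularization); inner folds that would empty a class
are skipped.  Decoding runs separately per threat level so threat cannot
confound the percept classification; the subject value is the mean of the
two stratum accuracies, each pooled over test trials across folds (the
mean of per-fold accuracies is also reported; pooling weights unequal
folds naturally).  A training fold containing a single class is skipped
with a warning; a stratum with no usable folds is an error.  Class
imbalance within training folds is left unweighted and reported per fold.

## Permutation inference

Accuracy nulls shuffle labels within each session × threat cell — the unit
of exchangeability for the condition-split analyses (each analysis sees one
stratum's trials, within which serial dependence ties trials to their
session).  The full pipeline (scaling, ranking, nested C, CV) is re-run per
permutation; at group level every subject is permuted independently and the
group mean recorded.  The p-value is (#null ≥ observed)/N floored at 1/N,
ties counting against the observation — a valid (never anticonservative)
convention that attains 1/N.  `required_N(α, m) = ⌈m/α⌉` gives the smallest
N at which Bonferroni-corrected significance is attainable.

Weight-map inference trains one classifier per subject on **all** trials
(no condition split), refits it N times on within-session-shuffled labels,
and summarizes each voxel's null by its sample mean μ̂_v and sd σ̂_v
(ddof = 1); t_v = (w_v − μ̂_v)/σ̂_v is referred two-sided to Student's
t(N−1).  Zero-variance nulls are flagged and excluded with a count.  For
small designs the null can be enumerated exhaustively (every distinct
within-session arrangement once); equality with a brute-force enumeration
oracle is an acceptance test.  The Gaussian summary is audited per voxel
with the Lilliefors test — the Kolmogorov–Smirnov statistic against a
Gaussian with that voxel's estimated mean/sd, with the null distribution
corrected for the estimation so the audit attains its nominal size (an
uncorrected KS test with estimated parameters rejects far below α).  The
audit's own size is tested at 200 draws × 1000 voxels, where the
finite-sample critical-value tables are most accurate.

Family-wise error control defaults to Bonferroni at α/V on the two-sided
t(N−1) p-values — more conservative than random-field theory.  An RFT
option computes the expected-Euler-characteristic threshold for a 3D
t-field (3D density term plus the point term), with isotropic smoothness
estimated from residual-map gradients; it requires a 3D grid and residual
maps and is intended for smoothed, field-like maps.  Significant voxels
are reported split by sign (positive = more active on perceived-pain
trials).  Paired comparisons between analyses use a two-sided sign-flip
permutation test on per-subject accuracy differences (mean difference
statistic; exhaustive over 2ⁿ flips for n ≤ 12), with the same ≥-counting
rule.

## Spatial scales

Regions are ranked by group-level permutation p ascending (ties: higher
mean accuracy, then name), with Bonferroni flags at α divided by the
number of regions tested, controls included.  Cumulative combinations take
unions of the top-k ranked regions; the `pain_matrix` preset is the union
of all non-control regions, and the whole-brain point is always appended.
The voxel-count curve follows 3⁰, 3¹, … capped at V with the whole-brain
point explicit, rankings recomputed inside each training fold; ROI points
are placed on the same voxel-count axis by their mask sizes so anatomical
and t-contrast feature selection can be compared directly.  Ranking
regions on the same data that the combination runs then use is mildly
circular at the group level; the curve is reproducible as a pure function
of (group seed, config seed), and `split_half_combination_curve` provides
the non-circular variant (rank on one half of the subjects, evaluate the
unions on the other half).  Phase-matched rankings are used (each
phase's combinations come from that phase's ranking).

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script run desk-scale versions
of the study: 5–12 subjects, 2–4 sessions of 10 trials, grids of 6³–12³
with the full 26 + 2 region atlas where the region count matters.  The
statistical structure (session/threat layout, weak distributed signal,
AR(1) noise, drift, between-subject variability) is unchanged; only
counts shrink.  Heavy permutation loops fix C = 1 (the l2-normalized,
standardized features make the default-scale SVM well-conditioned);
nested C selection is exercised wherever hyperparameter choice is itself
under test.  Permutation counts are chosen by `required_N` for the
resolution each analysis needs (e.g. N = 199 where p ≤ 0.01 must be
attainable).  Calibration checks use bands wide enough for Monte-Carlo
error at the stated replication counts.

Known limitations: the AR(1) estimate is biased toward zero in short
sessions with many regressors (the design absorbs autocorrelated
variance); the weight-map t-scores inherit the well-known caveat that
highly separable data produce *small* SVM weights (large margins), so
weight maps are illustrative rather than a substitute for regional
accuracy analyses; and the RFT threshold assumes smooth, stationary,
isotropic fields that the unsmoothed simulator does not produce.
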