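# Methods

This note documents the models, estimators and numerical choices behind
`limbrsa`, and what the synthetic-data generator does and does not emulate.

## Data-generating model

Each simulated participant contributes, per region of interest (ROI), four
runs of digit-condition beta patterns plus a synthetic GLM residual matrix.

**Canonical geometry.** The reference inter-digit dissimilarity structure is
parametric: `d(i,j) = a + b·|i−j| + c·[thumb involved]` with defaults
`a = 1.0`, `b = 0.5`, `c = 0.5` — a baseline dissimilarity, a neighbourhood
gradient (non-neighbouring digits more distinct) and extra thumb
distinctiveness. The default matrix is Euclidean-embeddable and its 2-D MDS
places the digits in anatomical order. It is a synthetic stand-in for an
empirical two-hander reference RDM; users analysing real data should supply
their own reference.

**Exact geometry injection.** True condition mean patterns are constructed
by double-centering the target squared-distance matrix
(`signal_scale × canonical × V`), factoring the resulting Gram matrix, and
embedding the low-rank configuration into voxel space through a random
orthonormal basis. The *realized* pairwise distances therefore equal the
target exactly (not just in expectation), which removes sampling
variability from the ground truth.

**Inter-individual variability.** Two variability sources scale with the
signal, so zero-signal configurations remain exactly null:

- *Geometry jitter* (`geometry_jitter = 0.15`): each participant's true
  configuration is perturbed by Gaussian jitter proportional to the RMS
  coordinate. Real cohorts show high within-participant reliability but
  imperfect agreement with the canonical geometry; jitter reproduces this by
  lowering typicality while leaving split-half consistency intact.
- *Amplitude variability* (`signal_amplitude_sd = 0.4`, lognormal): overall
  signal strength differs between participants, which keeps between-group
  dissimilarity contrasts at realistic effect sizes.

**Noise.** Run-wise pattern noise and residuals share a spatial covariance:
exponential-decay correlation over a 1-D voxel index
(`corr(i,j) = exp(−|i−j|/λ)`, λ = 5 voxels) scaled by mildly heteroscedastic
per-voxel variances (log-SD 0.15). This is the simplest structure that makes
multivariate noise normalization non-trivial. Residuals are drawn from the
same covariance so the noise model estimated downstream is consistent with
the pattern noise. Per run, 264 residual timepoints with 244 error degrees
of freedom mirror the block-design run length at TR 1.5 s.

**Group calibration.** Signal scales are calibration constants chosen once
so the default pipeline lands near the group statistics reported for
comparable human cohorts — contralateral-SI typicality ≈ 0.75 (amputees),
≈ 0.75–0.78 (controls), ≈ 0.3 (congenital one-handers); split-half ≈ 0.45 /
0.55 / ≈ 0; weaker individuation in M1 and ipsilateral SI; zero everywhere
in V5. These defaults are tuning of the simulation, not validation of the
method.

**Covariates.** Phantom kinaesthesia (integer 0–5) is driven linearly by
standardized realized typicality plus independent Gaussian noise, then
discretized to six levels. A linear latent (rather than a rank copula) is
used because the downstream regression analysis probes a linear relation.
The coupling parameter is the Spearman correlation between the discretized
score and typicality; it is treated as cohort ground truth: the latent
correlation is calibrated per cohort (bisection against a Monte-Carlo
estimate of the attained rank correlation, compensating discretization
attenuation), and the noise realization whose realized rank correlation is
closest to the target is selected from 64 candidates — the same
realized-parameter philosophy as the geometry injection. Remaining
covariates (vividness, pain, amputation history, intact-hand typicality)
are independent of typicality, with ranges and moments matching a typical
acquired-amputee cohort.

## Estimators

**Noise covariance.** Residuals pooled across runs; sample covariance
normalized by the summed error degrees of freedom; shrinkage toward its
diagonal with a Ledoit–Wolf-style analytic intensity (ratio of summed
sampling variances of off-diagonal entries to their summed squares, clipped
to [0, 1]). Near-zero voxel variances are floored at 10⁻⁶ of the mean
variance; all-zero residuals fall back to the identity (no normalization),
with warnings. A per-run estimation option is available by passing a single
run's residuals.

**Crossnobis.** Pattern differences for all 10 digit pairs are whitened by
the inverse Cholesky factor of the noise covariance; distances average
`δₘᵀΣ⁻¹δₙ/V` over all unordered pairs of distinct runs (computed via the
sum-of-runs identity, O(runs) rather than O(runs²)). Division by voxel count
makes values comparable across ROI sizes. Distances are unbiased under the
null and may be negative.

**Typicality.** Spearman correlation (midranks) between the 10-vector of a
measured RDM and the canonical RDM. Both vectors are quantized to ten
decimals relative to their largest magnitude before ranking so that
mathematically tied canonical entries are not un-tied by floating-point
rounding; constant vectors yield NaN with a warning.

**Split-half.** Odd runs (1, 3, …) versus even runs (2, 4, …) by 1-based
index; each half needs at least two runs for cross-validation; the two
half-RDMs are compared by Spearman correlation using the noise model from
all runs.

**GLM.** Boxcar regressors convolved with a double-gamma HRF (peak delay
6 s, undershoot delay 16 s, undershoot ratio 6, unit dispersions — the
conventional parameterization), sampled at TR with 15× oversampling. Note
that a sustained 12-s block accumulates response until about block offset,
so the convolved regressor peaks ~12 s after onset (a brief event peaks at
the familiar 4–8 s). High-pass filtering is implemented as confound
regressors: a constant, an explicit linear trend, and discrete-cosine
components with periods above the 100 s cutoff (the linear term is needed
to remove ramps to below 1% residual amplitude). Estimation is OLS;
user-supplied per-timepoint weights are applied as diagonal weighting (the
interface for down-weighting corrupted volumes); the full robust-WLS
variance estimation of fMRI toolboxes is out of scope.

**Geometry.** Classical (Torgerson) MDS: square the dissimilarities,
double-center, eigendecompose; non-positive eigenvalue axes are dropped.
Procrustes alignment is rigid by default (rotation/reflection after
centering; optional scaling), aligning to the first participant and then
refining once against the running mean — order-stable and cheap.
Per-digit between-subject standard errors of the aligned coordinates give
the dispersion ellipses. No statistics are computed from projections.

**Stepwise regression and bootstrap.** Greedy forward selection on raw R²
gain with threshold 0.1 (adjusted R² is reported for the final model); ties
broken by column order; predictors enter in raw units (standardization by
flag). The bootstrap resamples rows of the full data matrix with
replacement, reruns the selection, and reports per-predictor inclusion
proportions and percentile bounds on adjusted R²; resamples in which a
predictor is constant skip that predictor.

**Calibrated Bayes factor.** `BF = ∫ L(obs|δ) π(δ) dδ / L(obs|0)` with a
scaled, shifted t likelihood (degrees of freedom of the observed
comparison) and a half-t prior centred at zero with scale equal to the
calibrating group difference, truncated to the deficit tail. Integration is
adaptive quadrature in units of the prior scale over [0, 12] widths
(absolute tolerance 10⁻¹²) with the prior renormalized to unit mass on the
truncated support, so BF → 1 exactly as the width → 0. The prior's degrees
of freedom default to those of the calibrating comparison. In the pipeline
the prior width is the congenital-vs-control mean difference and the tested
effect the amputee-vs-control difference (deficit-positive orientation).

**Classical tests.** Pooled-variance Student's t (paired and independent)
with Bonferroni-adjusted alpha recorded per family; Spearman with midranks;
partial correlation as the coefficient t-test in `y ~ 1 + x + covariates`;
mixed ANOVA via pingouin (interaction term reported); Mann-Whitney exact
for combined n ≤ 20 without ties, tie-corrected normal approximation
otherwise; ICC(3,1) (two-way mixed, consistency, single measure) with
F-based 95% CI. Trial classification assigns each trial to the digit whose
force channel correlates most strongly with the instructed timecourse, ties
to the lowest digit with a warning.

## Problem sizes and determinism

Default study: 18 amputees, 13 congenital one-handers, 12 controls; 4 runs;
100-voxel ROIs (80 for V5). Monte-Carlo calibration checks use 500–1000
zero-signal participants, 20 replicate cohorts for bootstrap replicability
(B = 1000), and 1000 null families for family-wise error. All randomness
flows from a single configuration seed through per-participant,
per-region seed sequences, so any subset of regions reproduces the full
simulation bit-for-bit and repeated runs are identical.

## What the generator does not emulate

No hemodynamic nonlinearity, motion or physiological artefacts, no real
cortical geometry or surface processing, no task-correlated confounds, and
no heavy-tailed noise: passing tests demonstrate correctness and
calibration of the estimators and inference under the stated model, not
robustness to every property of real scanner data. The canonical RDM is a
parametric stand-in, so absolute typicality values depend on its shape;
group *differences* are insensitive to this choice. Ipsilateral and V5
analyses share the beta-mode generator; the timeseries mode exists to
exercise the GLM end-to-end and is not the default for speed.
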