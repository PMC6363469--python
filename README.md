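# limbrsa

Representational similarity analysis (RSA) of sensorimotor digit maps after
hand loss — a complete, tested analysis pipeline driven entirely by a
synthetic-study generator with known ground truth.

## The scientific problem

The hand area of primary somatosensory cortex (SI) carries a fine-grained map
of the five digits: activity patterns evoked by moving neighbouring fingers
overlap more than those of non-neighbouring fingers. A central question in
sensory neuroscience is what happens to this representational structure when
the hand is lost — does the map dissolve without peripheral input, or does it
persist? Comparing acquired amputees (who lost a hand after the map formed),
congenital one-handers (who never had one), and two-handed controls separates
the roles of *forming* and *maintaining* the representation.

`limbrsa` implements the full multivariate analysis used for this question:

- **Crossnobis RDMs.** For each participant and region, the dissimilarity
  between digit-evoked activity patterns is the cross-validated squared
  Mahalanobis ("crossnobis") distance:
  `d(a,b) = mean over run pairs m≠n of δₘᵀ Σ⁻¹ δₙ / V`,
  where `δᵣ = βᵣ(a) − βᵣ(b)` is the pattern difference in run `r`, `Σ` the
  shrunk voxel noise covariance estimated from GLM residuals
  (multivariate noise normalization), and `V` the voxel count. Because the
  two factors come from independent runs the estimator is unbiased — its
  expectation is zero when two conditions are indistinguishable, and single
  estimates may go negative.
- **Summary statistics.** Mean dissimilarity (strength of digit
  individuation), *typicality* (Spearman correlation of the 10-pair RDM with
  a canonical two-hander RDM — how normally organised the map is), and
  split-half consistency (odd-run versus even-run RDM correlation).
- **Block-design GLM.** Double-gamma HRF regressors, discrete-cosine
  high-pass filtering (100 s cutoff) as confounds, per-run OLS with optional
  volume weights.
- **Geometry.** Classical MDS projections, Procrustes-aligned across
  participants for group visualisation.
- **Inference.** Bonferroni-controlled group contrasts, mixed group-by-area
  ANOVA, Mann-Whitney (exact for small samples), ICC(3,1), forward stepwise
  regression (ΔR² > 0.1 inclusion rule) with bootstrap replicability, and a
  *calibrated Bayes factor*: the alternative is a one-tailed t prior centred
  at zero whose width is set by the congenital-vs-control difference, tested
  against the amputee-vs-control difference; BF < 1/3 is read as evidence
  for preserved representation.

The synthetic generator emulates the study design (three groups, four runs,
12-s blocks, TR 1.5 s, four regions including a V5 control region with no
digit signal) and injects a known canonical geometry with configurable
signal scales, spatially correlated noise, inter-individual geometry
variability, and behavioural covariates whose kinaesthesia–typicality
coupling is a ground-truth parameter.

## Worked example

```python
from limbrsa import StudyConfig, run_study

results = run_study(StudyConfig(rng_seed=1), n_boot=1000)
si = results.participant_measures.query("roi == 'SI_contra'")
print(si.groupby("group")["typicality"].mean().round(3))
print("BF (amputee vs control typicality):", round(results.bayes["typicality"].bf, 3))
print("kinaesthesia inclusion:", results.bootstrap.inclusion_proportion["kinaesthesia"])
```

Output from this exact run:

```
group
amputee       0.747
congenital    0.314
control       0.752
Name: typicality, dtype: float64
BF (amputee vs control typicality): 0.13
kinaesthesia inclusion: 0.963
```

Read: amputees' missing-hand typicality (0.75) is indistinguishable from
controls' (0.75) — and the calibrated Bayes factor (0.13 < 1/3) provides
positive evidence for that equivalence — while congenital one-handers show
strongly reduced typicality (0.31). Across the simulated amputee cohort,
bootstrap stepwise regression selects phantom kinaesthesia as the predictor
of typicality in 96% of resamples.

A command-line interface mirrors the library:

```bash
limbrsa simulate --out sim_dir --seed 5        # per-participant pattern files
limbrsa report --in sim_dir --out results_dir  # RDMs + summary measures
limbrsa analyze --out results_dir --seed 5     # full pipeline + report files
```

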