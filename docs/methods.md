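# Methods

## Phenome construction

Diagnosis records (individual, ICD-9-CM code) are mapped through a phecode
table (CSV with `icd9` and `phecode` columns; many-to-many supported) and
binarized: X[i, j] = 1 iff individual *i* has at least one record mapping to
phecode *j*. Codes are matched as exact strings after whitespace trimming —
no hierarchical rollup beyond what the map file encodes. Record multiplicity
is deliberately discarded (presence/absence phenotyping); individuals with
no mapped record are excluded, since an all-zero row contributes nothing to
the factorization and has no defined topic assignment. Unmapped records are
counted and logged, not errors. Columns are ordered lexicographically by
phecode, rows by first appearance.

## Factorization

The objective is

  ‖X − WH‖_F² + λ[γ(‖W‖₁ + ‖H‖₁) + ½(1 − γ)(‖W‖_F² + ‖H‖_F²)],  W, H ≥ 0.

λ multiplies the penalty exactly as written. Many libraries rescale the
regularization by the number of samples or features; here λ is the knob,
verbatim, so λ = 0.2 means the same thing at every matrix size. This is
worth knowing when comparing with sklearn's `alpha_W`/`alpha_H` convention.

**Solver.** HALS block coordinate descent: each column W[:, t] (row H[t, :])
is minimized exactly with everything else fixed. For the stated objective
the update is

  W[:, t] ← max(0, (XHᵀ − W HHᵀ + W[:, t]·(HHᵀ)_tt − λγ/2) / ((HHᵀ)_tt + λ(1−γ)/2)),

symmetrically for H. The L1 term appears as the constant −λγ/2 shift in the
numerator and the L2 term inflates the denominator, so each block update is
a closed-form non-negative least-squares solution and the objective can
never increase; every fit asserts a non-increasing trace (slack 1e-10).
If a topic's denominator degenerates to 0 (empty topic, γ = 1) the block is
zeroed when the penalty is active, preserving monotonicity.

**Initialization.** Default: uniform random entries in
[0, sqrt(mean(X)/k)] from a seeded generator, which puts the initial
reconstruction on the data's scale; NNDSVD is available for deterministic
warm starts. Fits are bit-reproducible given (X, config).

**Convergence.** Relative objective change < `tol` (default 1e-6) or
`max_iter` (default 500) sweeps. Tests and the acceptance script use
tol = 1e-4..1e-5 with 60–300 sweeps; on planted-structure cohorts the
descriptor sets stabilize one to two orders of magnitude before the
objective meets 1e-6.

**Choosing k.** `scree()` returns the top singular values of the
column-mean-centered X and cumulative explained-variance fractions. For
matrices up to 2·10⁶ cells the exact dense SVD is used; above that the
spectrum comes from an eigendecomposition of the centered Gram matrix
XᵀX − n·μμᵀ (m × m), which is accurate to ~1e-7 relative — ample for
locating an elbow. On default synthetic cohorts the planted rank is
unmistakable (σ₆ ≈ 50 → σ₇ ≈ 24).

## Topic metrics

**Descriptors.** Top-t phecodes per topic by H weight (default t = 10),
ties broken lexicographically so output is deterministic. An all-zero topic
row yields the t lexicographically-first labels, flagged degenerate.

**Dependency.** Mean pairwise Jaccard similarity between descriptor sets;
1 iff all sets identical, 0 iff pairwise disjoint.

**Coherence.** UMass-style: for descriptors ranked w₁ … w_t, the pair score
for i < j is log[(D(w_i, w_j) + 1)/D(w_j)], where D counts individuals
carrying the phecode(s); per-topic mean over pairs, topics averaged for the
summary. The smoothing constant ε = 1 bounds the effect of cohort
duplication at log 2 per pair. Pairs whose later-ranked descriptor occurs in
no individual are skipped rather than scored −∞: the corpus carries no
evidence about them, and a degenerate column should not dominate the mean.
The exact coherence variant is isolated behind `topic_coherence` so an
alternative (e.g. NPMI) can be swapped in one place.

**Agreement / stability.** Between two models: k × k Jaccard matrix of
descriptor sets, optimal assignment by the Hungarian method
(`scipy.optimize.linear_sum_assignment`), agreement = mean matched
similarity. Label sets only — descriptor order does not matter. Models with
different k are compared after padding the smaller with empty topics that
score 0, so agreement is penalized, not undefined. `stability_scan` refits
one-at-a-time over λ, γ, k and seed grids against the base setting
(λ = 0.2, γ = 0.5) and records a row per (cell, seed); per-cell failures are
recorded in a status column.

## Association testing

**Pearson.** Each W column against allele counts; r and the two-sided p
from t = r√((n−2)/(1−r²)) on n−2 df (via `scipy.stats.pearsonr`).
Loadings enter raw: Pearson r is scale-invariant per column, so L2
normalization (available as `normalize_rows_l2`, used for plotting-style
summaries) does not change it.

**Logistic regression.** Outcome is the carrier indicator (allele count ≥ 1
→ 1) — with counts in {0,1,2}, "more than one record of the allele" and
"at least one allele" coincide for hets, and carrier coding is the
conventional reading. Default is one joint model: all k topic loadings plus
age and sex as simultaneous predictors, so each coefficient is adjusted for
the others; a marginal mode (one topic per model) is available behind a
flag. Estimation is maximum likelihood via `statsmodels.Logit`
(Newton/IRLS), Wald p-values from coefficient/SE against the standard
normal. Complete separation is flagged and the result marked non-converged
rather than raised.

**PheWAS.** Per phecode: logistic regression of the phecode on allele count,
age and sex. Phecodes with fewer than 20 cases (or controls) are skipped —
below that, Wald statistics from quasi-separated fits are noise — and the
Bonferroni threshold is α divided by the number actually tested.
Orientation follows PheWAS convention (phenotype as outcome, genotype as
predictor).

## Synthetic cohorts

The generator's job is to produce data with exactly the structure the
analysis assumes, plus known ground truth:

- **Topics.** H_true: k disjoint cores of `core_size` phecodes at
  `core_weight` (default 10 at 1.0), `background_weight` (0.01) elsewhere;
  core positions are a seeded random subset of columns. W_true: i.i.d.
  Gamma(shape 0.5, scale 1) — non-negative, right-skewed, mostly-small
  loadings. Disjoint cores make descriptor recovery unambiguous.
- **Phenome.** X_ij ~ Bernoulli(1 − exp(−(W_true·H_true)_ij)), independent
  cells. The exponential-saturation link is smooth, monotone in the
  intensity and maps [0, ∞) into [0, 1) without clipping artifacts. No
  generative model is canonical for binary phenomes; this choice is a
  stand-in, stated as such. Defaults give density ≈ 0.07.
- **Genotype.** g_i ~ Binomial(2, q) (Hardy–Weinberg), default q = 0.077 —
  the LPA rs10455872 minor-allele frequency in European-ancestry cohorts.
- **Covariates.** Age ~ Normal(70.3, 12.3) truncated at 18; sex ~
  Bernoulli(0.472) (fraction female in the emulated cohort); both
  independent of genotype unless `confound_genotype_age` is set (adds 5
  years per allele, for exercising the adjusted regression).
- **Planted effect.** W'[i, t*] = W[i, t*] + β·g_i with β = 0.8 by default —
  additive on the loading, so the signal the Pearson test assumes (a linear
  mean shift) exists by construction. Negative planted loadings (possible
  only with a negative β) are clamped at 0 with a warning.
- **Determinism.** Sub-streams for genotype/topics/phenome/covariates are
  spawned from the config seed; identical configs give bitwise-identical
  cohorts.

Default sizes (n = 3000, m = 400, k = 6) are a desk-scale stand-in for a
biobank phenome; they keep every fit in seconds while leaving the planted
structure comfortably above the noise floor. What passing on these cohorts
does *not* show: robustness to phecode-frequency skew spanning four orders
of magnitude, correlated topics sharing prevalent phenotypes, missingness
informative of care utilization, or linkage structure across variants —
none of which the generator emulates.

## Study conditions used by the checks

- Descriptor recovery: 5 cohorts at default conditions, λ = 0.2, γ = 0.5;
  Hungarian-matched Jaccard of fitted top-10 vs planted cores (observed
  ≈ 1.0, required ≥ 0.8).
- Planted association: 20 default cohorts (β = 0.8, MAF 0.077); the fitted
  topic matched to the planted one must carry the largest |r| at p < 0.001.
- Null calibration: 200 cohorts at β = 0 and reduced size (n = 500, m = 120,
  k = 4, 60 sweeps) — valid because genotype independent of X makes the
  test's calibration independent of cohort size — pooled per-topic rejection
  at α = 0.05 within 5% ± 2%.
- Dependency vs k: with perfectly disjoint cores, dependency is exactly 0
  whenever the fitted k is at or below the planted rank, and peaks just
  above it (surplus topics duplicate cores); the qualitative decline from
  k = 5 to k = 15 therefore shows on cohorts whose latent rank (3) lies
  below the scanned range — the regime a scree-guided real-data fit
  occupies, where redundancy dilutes as k grows.

## Known limitations

- The coherence formula is one defensible variant of a family; absolute
  coherence values are not comparable across variants, only across models
  under the same variant.
- The joint logistic model assumes the k loadings are not collinear; at
  large k on small cohorts the marginal mode is the safer default.
- The PheWAS skip rule (20 cases) trades sensitivity on rare phecodes for
  stable Wald statistics; Firth-type corrections are out of scope.
- λ is applied unscaled, so its useful range shifts with matrix size;
  the stability scan is the intended tool for checking that conclusions
  survive the choice.
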