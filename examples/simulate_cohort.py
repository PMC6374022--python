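"""Generate a synthetic cohort with planted disease topics and a SNP effect.

The cohort mimics a biobank phenome: a sparse binary individual x phecode
matrix driven by latent disease topics, Hardy-Weinberg genotypes at
MAF 0.077, and one topic whose loading is shifted by 0.8 per minor allele.
"""

import numpy as np

import genotopics as gt

config = gt.SimulationConfig(seed=1)  # n=3000, m=400, k=6 defaults
cohort = gt.simulate_cohort(config)

freqs = np.bincount(cohort.genotype.counts, minlength=3) / len(cohort.genotype)
print(f"cohort: {cohort.X.shape[0]} individuals x {cohort.X.shape[1]} phecodes")
print(f"phenome density: {cohort.X.density:.3f}  (fraction of 1s in X)")
print(f"genotype frequencies (0/1/2 minor alleles): {np.round(freqs, 3)}")
print(f"empirical MAF: {cohort.genotype.maf:.4f}  (target {config.maf})")
print(f"mean age: {cohort.age.mean():.1f}  sd: {cohort.age.std():.1f}")
print(f"planted effect: +{config.effect_beta}/allele on topic {config.target_topic}")

# The planted signal is visible in the ground-truth loadings before any fit:
r, p = gt.pearson_test(cohort.W_true[:, config.target_topic],
                       cohort.genotype.counts)
print(f"true-loading vs genotype Pearson r = {r:.3f} (p = {p:.2e})")
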