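"""Scan regularization strength and seeds, scoring topic stability.

For each setting the model is refit and its top-descriptor sets are matched
to the base model's (lam=0.2, gamma=0.5) by the Hungarian method; the
agreement score is the mean Jaccard similarity of matched topic pairs.
Scores near 1 mean the topics' meaning survives the parameter change.
"""

import genotopics as gt

cohort = gt.simulate_cohort(gt.SimulationConfig(
    n_individuals=1000, n_phecodes=200, n_topics=5, core_size=10, seed=3,
))
base = gt.NMFConfig(k=5, lam=0.2, gamma=0.5, seed=3, max_iter=200, tol=1e-5)

report = gt.stability_scan(
    cohort.X, base,
    lam_grid=[0.0, 0.2, 0.5, 1.0, 2.0],
    gamma_grid=[0.5, 1.0],
    seeds=[3, 4],
    t=10,
)
print("agreement with the base setting (lam=0.2, gamma=0.5):")
print(report.table[["param", "value", "seed", "agreement", "status"]]
      .to_string(index=False))
print("\nhigh agreement across the grid = the topics are stable, not an "
      "artifact of one regularization choice")
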