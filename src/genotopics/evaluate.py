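"""Topic quality and stability metrics.

Three complementary diagnostics for a fitted topic model:

* **dependency** — mean pairwise Jaccard similarity between the topics'
  descriptor sets; high values mean redundant, overlapping topics;
* **coherence** — a UMass-style co-occurrence score of each topic's
  descriptors over the cohort; higher (closer to 0) means the descriptors
  tend to appear in the same individuals, i.e. the topic reads as one theme;
* **agreement / stability** — mean Jaccard similarity of optimally matched
  (Hungarian assignment) topic pairs between two fitted models, used to
  scan robustness over random seeds and the regularization grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .nmf import NMFConfig, TopicModel, fit_nmf
from .phecodes import PhenotypeMatrix

__all__ = [
    "TopicDescriptors",
    "StabilityReport",
    "top_descriptors",
    "topic_dependency",
    "topic_coherence",
    "topic_agreement",
    "stability_scan",
]


@dataclass
class TopicDescriptors:
    """Per-topic ordered lists of the top-t phecode labels with weights."""

    topics: list[list[str]]
    weights: list[np.ndarray]
    t: int
    degenerate: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.degenerate:
            self.degenerate = [False] * len(self.topics)

    @property
    def k(self) -> int:
        return len(self.topics)

    def sets(self) -> list[frozenset[str]]:
        return [frozenset(labels) for labels in self.topics]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"topic": i, "rank": r, "phecode": lab, "weight": w}
            for i, (labs, ws) in enumerate(zip(self.topics, self.weights))
            for r, (lab, w) in enumerate(zip(labs, ws), start=1)
        ]
        return pd.DataFrame(rows)


def top_descriptors(H: np.ndarray, phecodes: list[str], t: int = 10) -> TopicDescriptors:
    """The t highest-weight phecodes per topic, descending by H weight.

    Ties break lexicographically by label.  An all-zero topic row yields the
    t lexicographically-first labels (all weight 0) and is flagged degenerate.
    """
    if t < 1:
        raise ValueError("descriptor size t must be >= 1")
    H = np.asarray(H, dtype=float)
    k, m = H.shape
    if t > m:
        raise ValueError(f"t={t} exceeds number of phecodes m={m}")
    if len(phecodes) != m:
        raise ValueError("phecode label count does not match H columns")
    topics, weights, degenerate = [], [], []
    for row in H:
        order = sorted(range(m), key=lambda j: (-row[j], phecodes[j]))[:t]
        topics.append([phecodes[j] for j in order])
        weights.append(row[order])
        degenerate.append(not np.any(row))
    return TopicDescriptors(topics=topics, weights=weights, t=t, degenerate=degenerate)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def topic_dependency(desc: TopicDescriptors) -> float:
    """Mean pairwise Jaccard similarity between descriptor sets, in [0, 1]."""
    if desc.k < 2:
        raise ValueError("topic dependency needs at least 2 topics")
    sets = desc.sets()
    sims = [_jaccard(a, b) for a, b in itertools.combinations(sets, 2)]
    return float(np.mean(sims))


def topic_coherence(
    desc: TopicDescriptors, pm: PhenotypeMatrix, eps: float = 1.0
) -> tuple[np.ndarray, float]:
    """UMass-style coherence of each topic's descriptors over the cohort.

    For each ordered descriptor pair (w_i ranked above w_j) the pair score is
    log[(D(w_i, w_j) + eps) / D(w_j)], where D counts individuals carrying
    the phecode(s).  Pairs whose later-ranked descriptor occurs in no
    individual are skipped (no document evidence either way).  Returns the
    per-topic means and their average.
    """
    col = pm.column_index()
    for labels in desc.topics:
        for lab in labels:
            if lab not in col:
                raise ValueError(f"descriptor {lab!r} absent from matrix columns")
    Xc = pm.X.tocsc().astype(np.int64)
    doc_count = np.asarray(Xc.sum(axis=0)).ravel()

    per_topic = np.full(desc.k, np.nan)
    for ti, labels in enumerate(desc.topics):
        idx = [col[lab] for lab in labels]
        sub = Xc[:, idx]
        co = np.asarray((sub.T @ sub).todense())  # t x t co-occurrence counts
        scores = []
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                d_j = doc_count[idx[j]]
                if d_j == 0:
                    continue
                scores.append(math.log((co[i, j] + eps) / d_j))
        if scores:
            per_topic[ti] = float(np.mean(scores))
    return per_topic, float(np.nanmean(per_topic))


def topic_agreement(
    desc_a: TopicDescriptors, desc_b: TopicDescriptors
) -> tuple[float, list[tuple[int, int]]]:
    """Best-matching mean Jaccard similarity between two descriptor sets.

    Builds the k x k Jaccard matrix, solves the optimal assignment
    (Hungarian method) maximising total similarity, and returns the mean of
    the matched similarities together with the matching itself.  If the two
    models differ in k, the smaller side is padded with empty topics that
    score 0 against everything.
    """
    sets_a, sets_b = desc_a.sets(), desc_b.sets()
    k = max(len(sets_a), len(sets_b))
    sets_a = sets_a + [frozenset()] * (k - len(sets_a))
    sets_b = sets_b + [frozenset()] * (k - len(sets_b))
    sim = np.array([[_jaccard(a, b) for b in sets_b] for a in sets_a])
    rows, cols = linear_sum_assignment(-sim)
    agreement = float(sim[rows, cols].mean())
    return agreement, list(zip(rows.tolist(), cols.tolist()))


@dataclass
class StabilityReport:
    """Agreement scores of refits across a (lam, gamma, k, seed) grid."""

    table: pd.DataFrame
    base_config: NMFConfig
    t: int


def stability_scan(
    X: PhenotypeMatrix,
    base_config: NMFConfig,
    lam_grid=None,
    gamma_grid=None,
    k_grid=None,
    seeds=None,
    t: int = 10,
) -> StabilityReport:
    """Refit under one-at-a-time parameter changes and score agreement.

    Every grid value replaces the corresponding field of ``base_config``
    (other fields held at base), the model is refit for each seed, and the
    Hungarian-matched Jaccard agreement of its top-``t`` descriptors against
    the base model's is recorded.  Per-cell failures are recorded in the
    ``status`` column rather than raised.
    """
    lam_grid = list(lam_grid) if lam_grid is not None else [base_config.lam]
    gamma_grid = list(gamma_grid) if gamma_grid is not None else [base_config.gamma]
    k_grid = list(k_grid) if k_grid is not None else [base_config.k]
    seeds = list(seeds) if seeds is not None else [base_config.seed]
    if not (lam_grid and gamma_grid and k_grid and seeds):
        raise ValueError("stability grid must be non-empty")

    base_model = fit_nmf(X, base_config)
    base_desc = top_descriptors(base_model.H, X.phecodes, t=t)

    cells = (
        [("lam", v) for v in lam_grid]
        + [("gamma", v) for v in gamma_grid]
        + [("k", v) for v in k_grid]
    )
    rows = []
    for param, value in cells:
        for seed in seeds:
            cfg = NMFConfig(
                k=int(value) if param == "k" else base_config.k,
                lam=float(value) if param == "lam" else base_config.lam,
                gamma=float(value) if param == "gamma" else base_config.gamma,
                max_iter=base_config.max_iter,
                tol=base_config.tol,
                seed=int(seed),
                init=base_config.init,
            )
            row = {"param": param, "value": value, "lam": cfg.lam,
                   "gamma": cfg.gamma, "k": cfg.k, "seed": cfg.seed}
            try:
                if cfg == base_config:
                    agr, _ = topic_agreement(base_desc, base_desc)
                else:
                    model = fit_nmf(X, cfg)
                    desc = top_descriptors(model.H, X.phecodes, t=t)
                    agr, _ = topic_agreement(base_desc, desc)
                row.update(agreement=agr, status="ok")
            except Exception as exc:
                row.update(agreement=np.nan, status=f"error: {exc}")
            rows.append(row)
    return StabilityReport(table=pd.DataFrame(rows), base_config=base_config, t=t)
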