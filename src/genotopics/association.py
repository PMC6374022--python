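"""Genotype-topic association testing and the conventional PheWAS comparison.

Two complementary tests relate a single SNP (minor-allele counts 0/1/2) to
the fitted individual-topic loadings W:

* Pearson correlation of each topic column against allele count, with the
  usual t-distributed two-sided p-value;
* logistic regression with the carrier indicator (>= 1 minor allele) as the
  outcome and all topic loadings plus age and sex as joint predictors, so
  each topic coefficient is adjusted for the others and for the covariates.

The conventional PheWAS fits one logistic regression per phecode (phecode
as outcome; allele count, age and sex as predictors) and applies a
Bonferroni threshold of alpha / #tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .errors import AlignmentError, DegenerateInputError
from .nmf import TopicModel
from .phecodes import PhenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeVector",
    "LogisticResult",
    "PhewasResult",
    "compute_maf",
    "pearson_test",
    "logistic_fit",
    "topic_association",
    "phewas",
]


@dataclass
class GenotypeVector:
    """Minor-allele counts (0/1/2) per individual, keyed by individual id."""

    counts: np.ndarray
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("genotype counts must be a 1-D vector")
        if self.counts.size and not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("genotype counts must take values in {0, 1, 2}")
        if self.individual_ids is not None and len(self.individual_ids) != len(
            self.counts
        ):
            raise AlignmentError("genotype ids and counts differ in length")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def maf(self) -> float:
        return compute_maf(self.counts)

    def aligned_to(self, individual_ids: list[str]) -> np.ndarray:
        """Reorder counts to match ``individual_ids``; by id, never position."""
        if self.individual_ids is None:
            if len(self.counts) != len(individual_ids):
                raise AlignmentError(
                    "unlabeled genotype vector has wrong length "
                    f"({len(self.counts)} vs {len(individual_ids)})"
                )
            return self.counts
        index = {g: i for i, g in enumerate(self.individual_ids)}
        missing = [i for i in individual_ids if i not in index]
        if missing:
            raise AlignmentError(
                f"{len(missing)} individuals lack genotypes, e.g. {missing[:5]}"
            )
        return self.counts[[index[i] for i in individual_ids]]


def compute_maf(g) -> float:
    """Allele frequency of the counted allele: (#het + 2*#hom) / 2n.

    Warns if the result exceeds 0.5, i.e. the "minor" allele is actually the
    major one under the chosen coding.
    """
    counts = g.counts if isinstance(g, GenotypeVector) else np.asarray(g)
    if counts.size == 0:
        raise DegenerateInputError("cannot compute MAF of an empty vector")
    maf = float((counts == 1).sum() + 2 * (counts == 2).sum()) / (2 * counts.size)
    if maf > 0.5:
        warnings.warn(
            f"allele frequency {maf:.3f} > 0.5: the counted allele is the major one",
            stacklevel=2,
        )
    return maf


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class LogisticResult:
    """Logistic-regression fit: coefficients (intercept first), Wald stats."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    llf: float
    converged: bool
    separation_flagged: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.coef, "se": self.se, "p": self.pvalues},
            index=self.names,
        )


def logistic_fit(
    y, predictors, names: list[str] | None = None
) -> LogisticResult:
    """Maximum-likelihood logistic regression of binary ``y`` on ``predictors``.

    An intercept is prepended automatically.  Wald p-values come from
    coefficient/SE against the standard normal.  Complete separation is
    flagged (non-converged result returned) rather than raised; a singular
    design is an error.
    """
    y = np.asarray(y, dtype=float)
    Xd = np.atleast_2d(np.asarray(predictors, dtype=float))
    if Xd.shape[0] != y.size:
        Xd = Xd.T
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    design = sm.add_constant(Xd, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("design matrix is singular")
    if names is None:
        names = [f"x{j}" for j in range(Xd.shape[1])]
    names = ["intercept"] + list(names)

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
        except Exception as exc:
            if "separation" not in str(exc).lower() and not isinstance(
                exc, PerfectSeparationWarning
            ):
                raise
            separation = True
            logger.warning("complete separation detected: %s", exc)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(
                    disp=0, maxiter=100, method="bfgs"
                )
    return LogisticResult(
        names=names,
        coef=np.asarray(fit.params, dtype=float),
        se=np.asarray(fit.bse, dtype=float),
        pvalues=np.asarray(fit.pvalues, dtype=float),
        llf=float(fit.llf),
        converged=bool(fit.mle_retvals.get("converged", False)) and not separation,
        separation_flagged=separation,
    )


def topic_association(
    model: TopicModel,
    genotype: GenotypeVector,
    age,
    sex,
    joint: bool = True,
    descriptors=None,
) -> pd.DataFrame:
    """Per-topic association table: Pearson r/p and adjusted logistic fit.

    The logistic outcome is the carrier indicator (allele count >= 1); by
    default all k topic loadings enter one joint model together with age and
    sex, so the table mirrors a single adjusted regression.  ``joint=False``
    fits one model per topic instead (each still adjusted for age and sex).
    Rows for the age and sex coefficients are appended after the topics.
    """
    W = model.W
    n, k = W.shape
    ids = model.individual_ids or [str(i) for i in range(n)]
    g = genotype.aligned_to(ids) if isinstance(genotype, GenotypeVector) else np.asarray(genotype)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if not (len(g) == n == age.size == sex.size):
        raise AlignmentError("genotype/covariate lengths do not match W rows")

    carrier = (g >= 1).astype(float)
    topic_names = [f"topic_{t}" for t in range(k)]

    rows = []
    pcc = [pearson_test(W[:, t], g) for t in range(k)]
    if joint:
        lr = logistic_fit(
            carrier,
            np.column_stack([W, age, sex]),
            names=topic_names + ["age", "sex"],
        )
        coefs = dict(zip(lr.names, zip(lr.coef, lr.pvalues)))
    else:
        coefs = {}
        for t in range(k):
            lr_t = logistic_fit(
                carrier,
                np.column_stack([W[:, t], age, sex]),
                names=[topic_names[t], "age", "sex"],
            )
            coefs[topic_names[t]] = (lr_t.coef[1], lr_t.pvalues[1])
        coefs["age"] = (np.nan, np.nan)
        coefs["sex"] = (np.nan, np.nan)

    for t in range(k):
        c, p = coefs[topic_names[t]]
        rows.append(
            {
                "predictor": topic_names[t],
                "top_phenotypes": "; ".join(descriptors.topics[t])
                if descriptors is not None
                else "",
                "r": pcc[t][0],
                "p_pcc": pcc[t][1],
                "lr_coefficient": c,
                "p_lr": p,
            }
        )
    for cov in ("age", "sex"):
        c, p = coefs[cov]
        rows.append(
            {
                "predictor": cov,
                "top_phenotypes": "",
                "r": np.nan,
                "p_pcc": np.nan,
                "lr_coefficient": c,
                "p_lr": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PhewasResult:
    """Per-phecode association table plus the Bonferroni threshold used."""

    table: pd.DataFrame
    bonferroni: float
    n_tested: int
    n_skipped: int


def phewas(
    pm: PhenotypeMatrix,
    genotype: GenotypeVector,
    age,
    sex,
    alpha: float = 0.05,
    min_cases: int = 20,
) -> PhewasResult:
    """One logistic regression per phecode against allele count, age, sex.

    Phecodes with fewer than ``min_cases`` cases (or fewer than ``min_cases``
    controls) are skipped to avoid unstable fits; per-phecode failures are
    recorded in the ``status`` column rather than raised.  The Bonferroni
    threshold is alpha divided by the number of phecodes actually tested.
    """
    ids = pm.individual_ids
    g = genotype.aligned_to(ids) if isinstance(genotype, GenotypeVector) else np.asarray(genotype)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n = len(ids)
    if not (len(g) == n == age.size == sex.size):
        raise AlignmentError("genotype/covariate lengths do not match matrix rows")

    Xc = pm.X.tocsc()
    design = np.column_stack([g.astype(float), age, sex])
    rows = []
    n_skipped = 0
    for j, phe in enumerate(pm.phecodes):
        y = np.asarray(Xc[:, j].todense()).ravel().astype(float)
        cases = int(y.sum())
        if cases < min_cases or (n - cases) < min_cases:
            n_skipped += 1
            rows.append(
                {"phecode": phe, "n_cases": cases, "coefficient": np.nan,
                 "se": np.nan, "p": np.nan, "status": "skipped_min_cases"}
            )
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, sm.add_constant(design)).fit(disp=0, maxiter=100)
            rows.append(
                {"phecode": phe, "n_cases": cases,
                 "coefficient": float(fit.params[1]), "se": float(fit.bse[1]),
                 "p": float(fit.pvalues[1]),
                 "status": "ok" if fit.mle_retvals.get("converged", False)
                 else "not_converged"}
            )
        except Exception as exc:  # per-phecode failures recorded, not fatal
            rows.append(
                {"phecode": phe, "n_cases": cases, "coefficient": np.nan,
                 "se": np.nan, "p": np.nan, "status": f"error: {exc}"}
            )
    if n_skipped:
        logger.info("phewas skipped %d phecodes with <%d cases", n_skipped, min_cases)
    table = pd.DataFrame(rows)
    n_tested = int((table["status"] != "skipped_min_cases").sum())
    bonf = alpha / n_tested if n_tested else np.nan
    return PhewasResult(table=table, bonferroni=bonf, n_tested=n_tested,
                        n_skipped=n_skipped)
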