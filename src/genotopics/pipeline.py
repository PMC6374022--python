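"""End-to-end orchestration: simulate/load -> scree -> fit -> evaluate ->
associate -> PheWAS, driven by a YAML run configuration.

Every stage writes its outputs (TSV/YAML) into the run directory together
with the exact configuration that produced them, and a ``summary.yaml``
collects the headline numbers.  All randomness is threaded through explicit
seeds in the config; a failure halts with the stage name while earlier
outputs are retained.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import evaluate as ev
from . import nmf, phecodes, simulate
from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_end_to_end"]


@dataclass
class RunConfig:
    out_dir: str
    nmf: nmf.NMFConfig = field(default_factory=nmf.NMFConfig)
    simulate: simulate.SimulationConfig | None = None
    matrix_dir: str | None = None      # used when simulate is absent
    covariates: str | None = None      # TSV: individual_id, g, age, sex
    descriptor_size: int = 10
    scree_kmax: int = 12
    joint_lr: bool = True
    phewas_alpha: float = 0.05
    phewas_min_cases: int = 20
    log_level: str = "INFO"


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, reporting all violations at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"run config {path} is not a YAML mapping")

    errors: list[str] = []

    def build(cls, section, label):
        try:
            return cls(**section)
        except TypeError as exc:
            errors.append(f"{label}: {exc}")
        except ConfigurationError as exc:
            errors.append(f"{label}: {exc}")
        return None

    out_dir = raw.get("out_dir")
    if not out_dir:
        errors.append("out_dir: required field is missing")
    nmf_cfg = build(nmf.NMFConfig, raw.get("nmf", {}), "nmf") or nmf.NMFConfig()
    sim_cfg = None
    if "simulate" in raw:
        sim_cfg = build(simulate.SimulationConfig, raw["simulate"] or {}, "simulate")
    elif not raw.get("matrix_dir"):
        errors.append("matrix_dir: required when no simulate section is given")

    extras = {}
    for key in ("descriptor_size", "scree_kmax", "joint_lr", "phewas_alpha",
                "phewas_min_cases", "log_level", "matrix_dir", "covariates"):
        if key in raw:
            extras[key] = raw[key]
    if extras.get("descriptor_size", 10) < 1:
        errors.append("descriptor_size: must be >= 1")
    if extras.get("scree_kmax", 12) < 1:
        errors.append("scree_kmax: must be >= 1")

    if errors:
        raise ConfigurationError(
            "invalid run config:\n  " + "\n  ".join(errors)
        )
    return RunConfig(out_dir=out_dir, nmf=nmf_cfg, simulate=sim_cfg, **extras)


def _load_covariates(path: str, ids: list[str]):
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    for col in ("individual_id", "g", "age", "sex"):
        if col not in df.columns:
            raise FormatError(f"covariates file lacks column '{col}'")
    g = assoc.GenotypeVector(
        counts=df["g"].to_numpy(), individual_ids=df["individual_id"].tolist()
    )
    df = df.set_index("individual_id").loc[ids]
    return g, df["age"].to_numpy(float), df["sex"].to_numpy(float)


def run_end_to_end(config: RunConfig) -> dict:
    """Run every stage and return the summary dict (also written as YAML)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    summary: dict = {}

    # --- stage: input (simulate or load) ---
    cohort = None
    try:
        if config.simulate is not None:
            cohort = simulate.simulate_cohort(config.simulate)
            simulate.write_cohort(cohort, out / "cohort")
            pm = cohort.X
            genotype, age, sex = cohort.genotype, cohort.age, cohort.sex
        else:
            pm = phecodes.read_matrix(config.matrix_dir)
            if config.covariates:
                genotype, age, sex = _load_covariates(
                    config.covariates, pm.individual_ids
                )
            else:
                genotype = age = sex = None
    except Exception:
        logger.exception("stage 'input' failed")
        raise
    summary["n_individuals"], summary["n_phecodes"] = map(int, pm.shape)
    summary["density"] = float(pm.density)

    # --- stage: scree ---
    kmax = min(config.scree_kmax, min(pm.shape))
    s, shares = nmf.scree(pm, kmax)
    pd.DataFrame(
        {"component": np.arange(1, kmax + 1), "singular_value": s,
         "cum_explained_variance": shares}
    ).to_csv(out / "scree.tsv", sep="\t", index=False)
    summary["scree_top_singular_values"] = [float(v) for v in s[: config.nmf.k + 2]]

    # --- stage: fit ---
    model = nmf.fit_nmf(pm, config.nmf)
    np.savetxt(out / "W.tsv", model.W, delimiter="\t")
    np.savetxt(out / "H.tsv", model.H, delimiter="\t")
    np.savetxt(out / "objective_trace.tsv", model.objective_trace, delimiter="\t")
    with open(out / "nmf_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config.nmf), fh, sort_keys=False)
    summary["k"] = config.nmf.k
    summary["n_iter"] = model.n_iter
    summary["converged"] = bool(model.converged)
    summary["final_objective"] = float(model.objective_trace[-1])

    labels, counts, n_unassigned = nmf.assign_topics(model.W)
    summary["topic_prevalence"] = [int(c) for c in counts]
    summary["n_unassigned"] = n_unassigned
    pd.DataFrame(
        {"individual_id": pm.individual_ids, "topic": labels}
    ).to_csv(out / "topic_assignments.tsv", sep="\t", index=False)

    # --- stage: evaluate ---
    desc = ev.top_descriptors(model.H, pm.phecodes, t=config.descriptor_size)
    desc.to_frame().to_csv(out / "descriptors.tsv", sep="\t", index=False)
    summary["topic_dependency"] = float(ev.topic_dependency(desc)) if model.k >= 2 else None
    per_topic, mean_coh = ev.topic_coherence(desc, pm)
    summary["topic_coherence_mean"] = float(mean_coh)

    if cohort is not None:
        truth = ev.TopicDescriptors(
            topics=[sorted(s) for s in cohort.core_phecodes],
            weights=[np.ones(len(s)) for s in cohort.core_phecodes],
            t=cohort.config.core_size,
        )
        fitted_core = ev.top_descriptors(
            model.H, pm.phecodes, t=cohort.config.core_size
        )
        recovery, matching = ev.topic_agreement(fitted_core, truth)
        summary["core_recovery_jaccard"] = float(recovery)
        summary["topic_matching"] = [list(p) for p in matching]

    # --- stage: association + phewas ---
    if genotype is not None:
        summary["maf"] = float(assoc.compute_maf(genotype))
        table = assoc.topic_association(
            model, genotype, age, sex, joint=config.joint_lr, descriptors=desc
        )
        table.to_csv(out / "topic_association.tsv", sep="\t", index=False)
        topic_rows = table[table["predictor"].str.startswith("topic_")]
        best = topic_rows.loc[topic_rows["r"].abs().idxmax()]
        summary["strongest_topic"] = {
            "predictor": str(best["predictor"]),
            "r": float(best["r"]),
            "p_pcc": float(best["p_pcc"]),
            "lr_coefficient": float(best["lr_coefficient"]),
            "p_lr": float(best["p_lr"]),
        }
        ph = assoc.phewas(
            pm, genotype, age, sex,
            alpha=config.phewas_alpha, min_cases=config.phewas_min_cases,
        )
        ph.table.to_csv(out / "phewas.tsv", sep="\t", index=False)
        manhattan = ph.table.dropna(subset=["p"]).copy()
        manhattan["neg_log10_p"] = -np.log10(manhattan["p"])
        manhattan[["phecode", "neg_log10_p"]].to_csv(
            out / "phewas_manhattan.tsv", sep="\t", index=False
        )
        summary["phewas_bonferroni"] = float(ph.bonferroni)
        summary["phewas_n_tested"] = ph.n_tested
        ok = ph.table.dropna(subset=["p"])
        if len(ok):
            top = ok.loc[ok["p"].idxmin()]
            summary["phewas_top_hit"] = {
                "phecode": str(top["phecode"]), "p": float(top["p"]),
                "coefficient": float(top["coefficient"]),
                "crosses_bonferroni": bool(top["p"] < ph.bonferroni),
            }
    else:
        logger.info("no genotype input: association and PheWAS stages skipped")
        summary["association"] = "skipped (no genotype input)"

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return summary
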