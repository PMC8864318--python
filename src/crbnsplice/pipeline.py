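"""End-to-end orchestration: cohorts -> classification -> DE -> enrichment ->
master regulators -> consensus -> signatures -> group tests and correlations.

Every stage writes plain TSV/GMT/JSON artifacts so it can be rerun and
inspected independently; the final ``report.json`` is fully deterministic for
a fixed config (bit-identical across reruns).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import (
    ConsensusReport,
    build_signature,
    merge_reports,
    signatures_to_collection,
    significant_tf_consensus,
    top_k_pathway_consensus,
)
from .diffexpr import log_cpm, run_de, write_de_table
from .enrichment import gsea_significance, rank_from_de, write_scores
from .errors import ConfigurationError, CrbnSpliceError, ValidationError
from .io_formats import (
    GeneSet,
    GeneSetCollection,
    RegulonDB,
    read_expression,
    read_gmt,
    read_metadata,
    read_regulons,
    read_transcripts,
    write_gmt,
    write_regulons,
)
from .regulons import master_regulators, write_mra_table
from .signatures import (
    compare_groups,
    comparisons_to_frame,
    correlation_matrix,
    correlations_to_frame,
    score_signatures,
)
from .splice_classify import classify, prevalence, write_calls
from .synthetic_data import (
    LatentFactorConfig,
    SimulationConfig,
    SyntheticCohort,
    default_genes,
    make_gene_sets,
    make_regulon_db,
    simulate_cohorts,
    write_cohort,
)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

def default_pipeline_config(seed: int = 17) -> dict:
    """A 4-cohort synthetic scenario (2 NDMM-like, 2 RRMM-like) with two
    planted TF programs, three planted pathway programs and a drug-sensitivity
    set tied to the first TF through a shared latent factor."""
    return {
        "seed": seed,
        "cutoff": 2.6,
        "pseudocount": 0.0,
        "de": {"covariates": ["batch"], "q_max": 0.05, "logfc_min": 0.0},
        "gsea": {"n_perm": 500, "weight": 1.0},
        "consensus": {"k": 10, "tf_fdr": 0.05, "min_signature_size": 5},
        "regulons": {"n_tfs": 30, "targets_per_tf": 40},
        "gene_sets": {"n_sets": 20, "set_size": 40, "extra": {"VENETO": 110}},
        "score_sets": ["VENETO"],
        "simulation": {
            "n_cohorts": 4,
            "n_samples": 120,
            "n_genes": 1200,
            "prevalence_high": 0.25,
            "settings": ["NDMM", "NDMM", "RRMM", "RRMM"],
            "active_tfs": {"TF001": 2.0, "TF002": 2.0},
            "pathway_effects": {"SET001": 1.0, "SET002": 1.0, "SET003": 1.0},
            "latent": {
                "programs": ["TF001", "VENETO"],
                "loading_log2": 1.2,
                "program_noise": 0.42,
                "group_shift": 1.5,
            },
        },
    }


def validate_config(config: dict) -> None:
    """Check seed presence and that every referenced path exists, before compute."""
    if "seed" not in config or config["seed"] is None:
        raise ConfigurationError("pipeline config requires a seed")
    for key in ("regulons", "gene_sets"):
        section = config.get(key, {})
        if "path" in section and not Path(section["path"]).exists():
            raise ConfigurationError(f"{key} path does not exist: {section['path']}")
    for entry in config.get("datasets", []):
        for field in ("counts", "transcripts", "metadata"):
            if field not in entry:
                raise ConfigurationError(f"dataset entry missing {field!r}")
            if not Path(entry[field]).exists():
                raise ConfigurationError(f"dataset path does not exist: {entry[field]}")
    if "datasets" not in config and "simulation" not in config:
        raise ConfigurationError("config needs either 'datasets' or 'simulation'")


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0])


def build_resources(config: dict) -> tuple[list[str], RegulonDB, GeneSetCollection]:
    """Load or deterministically generate the gene universe, regulons and sets."""
    seed = int(config["seed"])
    sim = config.get("simulation", {})
    genes = default_genes(int(sim.get("n_genes", 2000)))

    reg_cfg = config.get("regulons", {})
    if "path" in reg_cfg:
        db = read_regulons(reg_cfg["path"])
    else:
        db = make_regulon_db(
            genes,
            n_tfs=int(reg_cfg.get("n_tfs", 50)),
            targets_per_tf=int(reg_cfg.get("targets_per_tf", 40)),
            seed=_derived_seed(seed, 1),
        )

    sets_cfg = config.get("gene_sets", {})
    if "path" in sets_cfg:
        collection = read_gmt(sets_cfg["path"])
    else:
        collection = make_gene_sets(
            genes,
            n_sets=int(sets_cfg.get("n_sets", 30)),
            set_size=int(sets_cfg.get("set_size", 40)),
            seed=_derived_seed(seed, 2),
        )
        for name, size in (sets_cfg.get("extra") or {}).items():
            rng = np.random.default_rng(_derived_seed(seed, 3, zlib.crc32(name.encode())))
            members = rng.choice(len(genes), size=int(size), replace=False)
            collection.add(
                GeneSet(name, "extra synthetic set", tuple(genes[i] for i in members))
            )
    return genes, db, collection


def simulation_config_from_dict(sim: dict, seed: int) -> SimulationConfig:
    sim = copy.deepcopy(sim)
    latent = sim.pop("latent", None)
    if latent is not None:
        latent = LatentFactorConfig(
            programs=tuple(latent["programs"]),
            loading_log2=float(latent.get("loading_log2", 1.0)),
            program_noise=float(latent.get("program_noise", 0.42)),
            group_shift=float(latent.get("group_shift", 1.5)),
        )
    if "settings" in sim and sim["settings"] is not None:
        sim["settings"] = tuple(sim["settings"])
    return SimulationConfig(**sim, latent=latent, seed=seed)


def _load_datasets(config: dict) -> list[SyntheticCohort]:
    cohorts = []
    for entry in config["datasets"]:
        counts = read_expression(entry["counts"], kind="counts")
        transcripts = read_transcripts(entry["transcripts"])
        metadata = read_metadata(entry["metadata"])
        cohorts.append(
            SyntheticCohort(entry["name"], counts, transcripts, metadata, truth={
                "group": {}, "log2fc": {}, "active_tfs": [], "active_pathways": [],
            })
        )
    return cohorts


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage=%s status=ok elapsed=%.2fs", name, elapsed)
            else:
                log.error("stage=%s status=failed error=%s", name, exc)
            return False

    return _Timer()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage, write artifacts under ``outdir`` and return the report."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    cutoff = float(config.get("cutoff", 2.6))
    pseudocount = float(config.get("pseudocount", 0.0))
    de_cfg = config.get("de", {})
    covariates = list(de_cfg.get("covariates", []))
    q_max = float(de_cfg.get("q_max", 0.05))
    logfc_min = float(de_cfg.get("logfc_min", 0.0))
    gsea_cfg = config.get("gsea", {})
    n_perm = int(gsea_cfg.get("n_perm", 1000))
    cons_cfg = config.get("consensus", {})
    top_k = int(cons_cfg.get("k", 50))
    tf_fdr = float(cons_cfg.get("tf_fdr", 0.05))
    min_sig = int(cons_cfg.get("min_signature_size", 5))

    config_canonical = json.dumps(config, sort_keys=True)
    config_hash = hashlib.sha256(config_canonical.encode()).hexdigest()

    with _stage("resources"):
        genes, db, gene_sets = build_resources(config)
        write_regulons(db, outdir / "regulons.tsv")
        write_gmt(gene_sets, outdir / "gene_sets.gmt")

    with _stage("cohorts"):
        if "datasets" in config:
            cohorts = _load_datasets(config)
        else:
            sim_config = simulation_config_from_dict(config["simulation"], seed)
            cohorts = simulate_cohorts(sim_config, db, gene_sets, genes)
            for cohort in cohorts:
                write_cohort(cohort, outdir / "cohorts")

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash,
        "cohorts": {},
    }

    calls_by_cohort = {}
    de_by_cohort = {}
    gsea_by_cohort = {}
    mra_by_cohort = {}
    logcpm_by_cohort = {}
    for i, cohort in enumerate(cohorts):
        with _stage(f"classify[{cohort.name}]"):
            calls = classify(cohort.transcripts, cutoff=cutoff, pseudocount=pseudocount)
            write_calls(calls, outdir / f"{cohort.name}_calls.tsv")
            calls_by_cohort[cohort.name] = calls
            prev = prevalence(calls)
            report["cohorts"][cohort.name] = {
                "n_samples": len(calls),
                "setting": str(cohort.metadata["setting"].iloc[0]),
                "n_high": int(prev.loc["all", "n_high"]),
                "prevalence": float(prev.loc["all", "prevalence"]),
                "prevalence_ci": [
                    float(prev.loc["all", "ci_low"]),
                    float(prev.loc["all", "ci_high"]),
                ],
            }
        with _stage(f"de[{cohort.name}]"):
            de = run_de(cohort.counts, cohort.metadata, calls, covariates)
            write_de_table(de, outdir / f"{cohort.name}_de.tsv")
            de_by_cohort[cohort.name] = de
            logcpm_by_cohort[cohort.name] = log_cpm(cohort.counts)
        with _stage(f"gsea[{cohort.name}]"):
            ranked = rank_from_de(de)
            gsea = gsea_significance(
                ranked, gene_sets, n_perm=n_perm, seed=_derived_seed(seed, 10, i)
            )
            gsea.to_csv(outdir / f"{cohort.name}_gsea.tsv", sep="\t", float_format="%.10g")
            gsea_by_cohort[cohort.name] = gsea
        with _stage(f"mra[{cohort.name}]"):
            mra = master_regulators(de, db, logfc_min=logfc_min, q_max=q_max)
            write_mra_table(mra, outdir / f"{cohort.name}_mra.tsv")
            mra_by_cohort[cohort.name] = mra

    with _stage("consensus"):
        pathway_report = top_k_pathway_consensus(gsea_by_cohort, k=top_k)
        tf_report = significant_tf_consensus(mra_by_cohort, fdr=tf_fdr)
        cons = merge_reports(pathway_report, tf_report)
        report["consensus"] = cons.to_dict()

    with _stage("signatures"):
        signature_defs = []
        rejected = {}
        for tf in cons.tf_intersection:
            try:
                signature_defs.append(
                    build_signature(tf, de_by_cohort, db, logfc_min, q_max, min_sig)
                )
            except ValidationError as exc:
                rejected[tf] = str(exc)
        score_collection = GeneSetCollection()
        for sig in signature_defs:
            score_collection.add(sig.as_gene_set())
        for name in config.get("score_sets", []):
            if name not in gene_sets:
                raise ConfigurationError(f"score set {name!r} absent from the collection")
            score_collection.add(gene_sets[name])
        for name in cons.pathway_intersection:
            if name in gene_sets and name not in score_collection:
                score_collection.add(gene_sets[name])
        if signature_defs:
            write_gmt(signatures_to_collection(signature_defs), outdir / "signatures.gmt")
        report["signatures"] = {s.name: list(s.members) for s in signature_defs}
        report["signatures_rejected"] = rejected

    report["group_tests"] = {}
    report["correlations"] = {}
    if len(score_collection):
        for cohort in cohorts:
            with _stage(f"score[{cohort.name}]"):
                scores = score_signatures(
                    logcpm_by_cohort[cohort.name], score_collection, min_size=min(min_sig, 5)
                )
                write_scores(scores, outdir / f"{cohort.name}_scores.tsv")
                comparisons = compare_groups(scores, calls_by_cohort[cohort.name])
                report["group_tests"][cohort.name] = {
                    c.signature: {
                        "median_high": c.median_high,
                        "median_wt": c.median_wt,
                        "p": c.p,
                        "direction": c.direction,
                    }
                    for c in comparisons
                }
                if len(scores) >= 2:
                    records = correlation_matrix(scores, "all")
                    report["correlations"][cohort.name] = [
                        {"a": r.name_a, "b": r.name_b, "r": r.r, "p": r.p, "n": r.n}
                        for r in records
                    ]

    report_text = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_text)
    report["report_hash"] = hashlib.sha256(report_text.encode()).hexdigest()
    return report
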