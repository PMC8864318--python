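"""Multi-cohort synthetic transcriptomics with planted ground truth.

Each cohort carries:

* a negative-binomial count matrix (log-normal baseline means, log-normal
  library sizes, one batch covariate) with group effects planted on the
  log2 scale for the targets of "active" TFs and the members of perturbed
  pathway sets;
* two-isoform transcript quantification whose log-ratio is drawn from
  group-specific normal distributions (so the HIGH group sits above the
  classifier cutoff with a computable probability);
* sample metadata (cohort, disease setting, purity, batch);
* a truth record: per-sample group, per-gene planted log2 fold change, the
  active TFs and pathways.

An optional shared latent factor lets several gene programs (for example a
TF's targets and a drug-sensitivity set) co-vary across samples with a
configurable latent correlation, and be elevated in the HIGH group.

All randomness flows from the mandatory seed; identical configs are
bit-for-bit reproducible.  Cohorts use identical generative code with
independent draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RegulonDB,
    write_expression,
    write_metadata,
    write_transcripts,
)
from .splice_classify import LABEL_HIGH, LABEL_WT

GROUP_HIGH = LABEL_HIGH
GROUP_WT = LABEL_WT


@dataclass(frozen=True)
class LatentFactorConfig:
    """A per-sample latent factor driving several gene programs at once.

    ``programs`` lists TF ids (resolved to regulon targets) or gene-set names
    (resolved to members).  Each program's genes receive a log2 shift of
    ``loading_log2 * (f + program_noise * u) / sqrt(1 + program_noise^2)``
    where ``f`` is the shared standard-normal factor (offset by
    ``group_shift`` in HIGH samples) and ``u`` a program-specific independent
    standard normal; the latent correlation between two programs is therefore
    ``1 / (1 + program_noise^2)``.
    """

    programs: tuple[str, ...]
    loading_log2: float = 1.0
    program_noise: float = 0.42
    group_shift: float = 1.5


@dataclass
class SimulationConfig:
    n_cohorts: int = 2
    n_samples: int | Sequence[int] = 100
    n_genes: int = 2000
    prevalence_high: float = 0.1
    # isoform log-ratio distributions (natural log)
    wt_log_ratio_loc: float = math.log(0.2)
    wt_log_ratio_scale: float = 0.5
    high_log_ratio_loc: float = math.log(5.0)
    high_log_ratio_scale: float = 0.4
    full_length_log_mean: float = math.log(20.0)
    full_length_log_sd: float = 0.5
    # counts
    nb_dispersion: float = 0.2
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    libsize_cv: float = 0.3
    batch_effect_log2: float = 0.5
    n_batches: int = 2
    # annotations
    purity_low: float = 0.86
    purity_high: float = 0.98
    settings: Sequence[str] | None = None  # per cohort; default alternates NDMM/RRMM
    # planted effects (log2 fold change in the HIGH group)
    active_tfs: dict[str, float] = field(default_factory=dict)
    pathway_effects: dict[str, float] = field(default_factory=dict)
    latent: LatentFactorConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        if self.n_cohorts < 1:
            raise ConfigurationError("n_cohorts must be >= 1")
        if not 0.0 < self.prevalence_high < 1.0:
            raise ConfigurationError("prevalence_high must lie in (0, 1)")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        for name, eff in {**self.active_tfs, **self.pathway_effects}.items():
            if not math.isfinite(eff):
                raise ConfigurationError(f"non-finite effect size for {name!r}")

    def samples_for(self, cohort_index: int) -> int:
        if isinstance(self.n_samples, int):
            return self.n_samples
        return int(self.n_samples[cohort_index])

    def setting_for(self, cohort_index: int) -> str:
        if self.settings is not None:
            return self.settings[cohort_index]
        return "NDMM" if cohort_index % 2 == 0 else "RRMM"


@dataclass
class SyntheticCohort:
    name: str
    counts: ExpressionMatrix
    transcripts: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict

    def validate(self) -> None:
        samples = set(self.counts.samples)
        if set(self.truth["group"]) != samples:
            raise ValidationError("truth groups do not cover the cohort samples")
        if set(self.metadata.index) != samples:
            raise ValidationError("metadata does not cover the cohort samples")


# ---------------------------------------------------------------------------
# Primitive draws
# ---------------------------------------------------------------------------

def draw_nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with variance ``mu + dispersion * mu^2``.

    ``dispersion == 0`` degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if (mean < 0).any():
        raise ValueError("negative mean")
    if dispersion < 0:
        raise ValueError("negative dispersion")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def plant_ratio(
    group: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw a (full_length, del_exon10) abundance pair for one sample.

    The spliced/full-length ratio is log-normal with the group's configured
    location and scale; the full-length abundance is an independent log-normal.
    """
    if group == GROUP_HIGH:
        loc, scale = config.high_log_ratio_loc, config.high_log_ratio_scale
    elif group == GROUP_WT:
        loc, scale = config.wt_log_ratio_loc, config.wt_log_ratio_scale
    else:
        raise ValueError(f"unknown group {group!r}")
    full_length = math.exp(rng.normal(config.full_length_log_mean, config.full_length_log_sd))
    ratio = math.exp(rng.normal(loc, scale))
    return full_length, full_length * ratio


def high_ratio_tail_probability(config: SimulationConfig, cutoff: float) -> float:
    """Analytic P(ratio >= cutoff) for a HIGH sample under the config."""
    from scipy.stats import norm

    return float(
        norm.sf((math.log(cutoff) - config.high_log_ratio_loc) / config.high_log_ratio_scale)
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _resolve_program(
    name: str,
    regulons: RegulonDB | None,
    gene_sets: GeneSetCollection | None,
    gene_index: dict[str, int],
) -> np.ndarray:
    if regulons is not None and name in regulons:
        members = regulons.targets(name)
    elif gene_sets is not None and name in gene_sets:
        members = gene_sets[name].members
    else:
        raise ConfigurationError(f"unknown TF or gene-set name {name!r}")
    idx = np.array(sorted(gene_index[g] for g in members if g in gene_index), dtype=np.intp)
    if idx.size == 0:
        raise ConfigurationError(f"program {name!r} has no gene in the simulated universe")
    return idx


def default_genes(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def simulate_cohorts(
    config: SimulationConfig,
    regulons: RegulonDB | None = None,
    gene_sets: GeneSetCollection | None = None,
    genes: list[str] | None = None,
) -> list[SyntheticCohort]:
    """Generate ``config.n_cohorts`` independent cohorts with shared truth structure."""
    rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = default_genes(config.n_genes)
    if len(genes) != config.n_genes:
        raise ConfigurationError("gene list length does not match n_genes")
    gene_index = {g: i for i, g in enumerate(genes)}

    for tf in config.active_tfs:
        if regulons is None or tf not in regulons:
            raise ConfigurationError(f"active TF {tf!r} absent from the regulon database")
    for name in config.pathway_effects:
        if gene_sets is None or name not in gene_sets:
            raise ConfigurationError(f"pathway {name!r} absent from the gene-set collection")

    # fixed per-gene planted log2FC, shared across cohorts
    true_fx = np.zeros(config.n_genes)
    for tf, eff in config.active_tfs.items():
        true_fx[_resolve_program(tf, regulons, None, gene_index)] += eff
    for name, eff in config.pathway_effects.items():
        true_fx[_resolve_program(name, None, gene_sets, gene_index)] += eff

    latent_programs: list[tuple[str, np.ndarray]] = []
    if config.latent is not None:
        for name in config.latent.programs:
            latent_programs.append(
                (name, _resolve_program(name, regulons, gene_sets, gene_index))
            )

    cohorts = []
    for c in range(config.n_cohorts):
        name = f"cohort{c + 1}"
        n = config.samples_for(c)
        samples = [f"{name}_S{j:04d}" for j in range(n)]

        high = rng.random(n) < config.prevalence_high
        batch = rng.integers(0, config.n_batches, n)
        purity = rng.uniform(config.purity_low, config.purity_high, n)

        base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
        log2mu = base[:, None] + true_fx[:, None] * high[None, :]
        log2mu = log2mu + config.batch_effect_log2 * (batch > 0)[None, :]

        if config.latent is not None:
            lf = config.latent
            f = lf.group_shift * high + rng.normal(size=n)
            norm = math.sqrt(1.0 + lf.program_noise**2)
            for _, idx in latent_programs:
                u = rng.normal(size=n)
                shift = lf.loading_log2 * (f + lf.program_noise * u) / norm
                log2mu[idx, :] += shift[None, :]

        sigma_ls = math.sqrt(math.log(1.0 + config.libsize_cv**2))
        lib_factor = np.exp(rng.normal(-sigma_ls**2 / 2.0, sigma_ls, n))
        mu = np.exp2(log2mu) * lib_factor[None, :]
        counts = draw_nb_counts(mu, config.nb_dispersion, rng)

        fl = np.empty(n)
        dl = np.empty(n)
        for j in range(n):
            fl[j], dl[j] = plant_ratio(GROUP_HIGH if high[j] else GROUP_WT, config, rng)

        matrix = ExpressionMatrix(
            pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples),
            "counts",
        )
        transcripts = pd.DataFrame(
            {"full_length": fl, "del_exon10": dl, "purity": purity},
            index=pd.Index(samples, name="sample"),
        )
        metadata = pd.DataFrame(
            {
                "cohort": name,
                "setting": config.setting_for(c),
                "purity": purity,
                "batch": [f"b{b}" for b in batch],
            },
            index=pd.Index(samples, name="sample"),
        )
        truth = {
            "group": {s: (GROUP_HIGH if h else GROUP_WT) for s, h in zip(samples, high)},
            "log2fc": {genes[i]: float(true_fx[i]) for i in np.flatnonzero(true_fx != 0)},
            "active_tfs": sorted(config.active_tfs),
            "active_pathways": sorted(config.pathway_effects),
        }
        cohort = SyntheticCohort(name, matrix, transcripts, metadata, truth)
        cohort.validate()
        cohorts.append(cohort)
    return cohorts


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write counts/transcripts/metadata TSVs and the truth JSON for one cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{cohort.name}_counts.tsv",
        "transcripts": outdir / f"{cohort.name}_transcripts.tsv",
        "metadata": outdir / f"{cohort.name}_metadata.tsv",
        "truth": outdir / f"{cohort.name}_truth.json",
    }
    write_expression(cohort.counts, paths["counts"])
    write_transcripts(cohort.transcripts, paths["transcripts"])
    write_metadata(cohort.metadata, paths["metadata"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Companion databases for simulations
# ---------------------------------------------------------------------------

def make_regulon_db(
    genes: list[str],
    n_tfs: int,
    targets_per_tf: int,
    seed: int,
    tf_prefix: str = "TF",
) -> RegulonDB:
    """Random regulons: each TF gets ``targets_per_tf`` distinct random targets."""
    rng = np.random.default_rng(seed)
    if targets_per_tf > len(genes):
        raise ConfigurationError("targets_per_tf exceeds the gene universe")
    edges = {}
    for t in range(n_tfs):
        targets = rng.choice(len(genes), size=targets_per_tf, replace=False)
        edges[f"{tf_prefix}{t + 1:03d}"] = frozenset(genes[i] for i in targets)
    return RegulonDB(edges)


def make_gene_sets(
    genes: list[str],
    n_sets: int,
    set_size: int,
    seed: int,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Random gene sets of a fixed size over the given universe."""
    rng = np.random.default_rng(seed)
    if set_size > len(genes):
        raise ConfigurationError("set_size exceeds the gene universe")
    collection = GeneSetCollection()
    for s in range(n_sets):
        members = rng.choice(len(genes), size=set_size, replace=False)
        collection.add(
            GeneSet(f"{prefix}{s + 1:03d}", "synthetic", tuple(genes[i] for i in members))
        )
    return collection
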