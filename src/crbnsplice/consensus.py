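"""Cross-cohort consensus: shared top pathways, shared significant TFs, and
consensus regulon signatures built from targets upregulated in every dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import upregulated_genes
from .errors import ValidationError
from .io_formats import GeneSet, GeneSetCollection, RegulonDB

log = logging.getLogger(__name__)

DEFAULT_TOP_K = 50
DEFAULT_MIN_SIGNATURE_SIZE = 5


@dataclass
class ConsensusReport:
    """Per-dataset top pathways / significant TFs and their strict intersections."""

    pathway_lists: dict[str, list[str]] = field(default_factory=dict)
    pathway_intersection: list[str] = field(default_factory=list)
    tf_lists: dict[str, list[str]] = field(default_factory=dict)
    tf_intersection: list[str] = field(default_factory=list)
    k: int = DEFAULT_TOP_K
    tf_fdr: float = 0.05

    def validate(self) -> None:
        for name, members in self.pathway_lists.items():
            if not set(self.pathway_intersection) <= set(members):
                raise ValidationError(f"pathway intersection not contained in {name!r}")
        for name, members in self.tf_lists.items():
            if not set(self.tf_intersection) <= set(members):
                raise ValidationError(f"TF intersection not contained in {name!r}")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "tf_fdr": self.tf_fdr,
            "pathway_lists": self.pathway_lists,
            "pathway_intersection": self.pathway_intersection,
            "tf_lists": self.tf_lists,
            "tf_intersection": self.tf_intersection,
        }


@dataclass
class SignatureDefinition:
    """A consensus regulon signature: common upregulated direct targets of a TF.

    ``evidence`` maps each dataset name to a per-member (logFC, q) table.
    """

    name: str
    members: tuple[str, ...]
    evidence: dict[str, pd.DataFrame] = field(default_factory=dict)

    def as_gene_set(self, description: str = "consensus regulon signature") -> GeneSet:
        return GeneSet(self.name, description, self.members)


def _normalize_tables(tables) -> dict[str, pd.DataFrame]:
    if isinstance(tables, dict):
        return dict(tables)
    return {f"dataset{i + 1}": t for i, t in enumerate(tables)}


def top_k_pathways(table: pd.DataFrame, k: int = DEFAULT_TOP_K) -> list[str]:
    """The k most positively enriched set names (NES desc, ties by q then name)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    positive = table[table["NES"] > 0]
    order = sorted(
        range(len(positive)),
        key=lambda i: (-positive["NES"].iloc[i], positive["q"].iloc[i], positive.index[i]),
    )
    return positive.index[order][:k].tolist()


def top_k_pathway_consensus(
    tables, k: int = DEFAULT_TOP_K, direction: str = "up"
) -> ConsensusReport:
    """Intersect per-dataset top-k positively enriched pathway names.

    ``tables`` is a dict (or list) of enrichment tables with ES/NES/p/q
    columns indexed by set name.  Only the activated direction is supported.
    """
    if direction != "up":
        raise ValueError("only the activated (up) direction is supported")
    named = _normalize_tables(tables)
    if len(named) < 2:
        raise ValueError("consensus needs at least two datasets")
    lists = {name: top_k_pathways(t, k) for name, t in named.items()}
    common = set.intersection(*(set(v) for v in lists.values()))
    report = ConsensusReport(
        pathway_lists=lists, pathway_intersection=sorted(common), k=k
    )
    report.validate()
    return report


def significant_tf_consensus(tables, fdr: float = 0.05) -> ConsensusReport:
    """Intersect per-dataset significant TFs from master-regulator tables."""
    named = _normalize_tables(tables)
    if len(named) < 2:
        raise ValueError("consensus needs at least two datasets")
    lists = {
        name: t.index[t["q"] < fdr].tolist() for name, t in named.items()
    }
    common = set.intersection(*(set(v) for v in lists.values()))
    report = ConsensusReport(tf_lists=lists, tf_intersection=sorted(common), tf_fdr=fdr)
    report.validate()
    return report


def merge_reports(pathways: ConsensusReport, tfs: ConsensusReport) -> ConsensusReport:
    merged = ConsensusReport(
        pathway_lists=pathways.pathway_lists,
        pathway_intersection=pathways.pathway_intersection,
        tf_lists=tfs.tf_lists,
        tf_intersection=tfs.tf_intersection,
        k=pathways.k,
        tf_fdr=tfs.tf_fdr,
    )
    merged.validate()
    return merged


def build_signature(
    tf: str,
    de_tables,
    db: RegulonDB,
    logfc_min: float = 0.0,
    q_max: float = 0.05,
    min_size: int = DEFAULT_MIN_SIGNATURE_SIZE,
) -> SignatureDefinition:
    """Signature = regulon(tf) intersected with genes upregulated in EVERY dataset.

    A target missing the up-rule in even one dataset is excluded.  Raises with
    a diagnostic when fewer than ``min_size`` members survive.
    """
    if tf not in db:
        raise KeyError(f"TF {tf!r} not present in the regulon database")
    named = _normalize_tables(de_tables)
    if not named:
        raise ValueError("at least one DE table is required")
    up_sets = {
        name: set(upregulated_genes(t, logfc_min, q_max)) for name, t in named.items()
    }
    members = set(db.targets(tf))
    for up in up_sets.values():
        members &= up
    members = tuple(sorted(members))
    if len(members) < min_size:
        raise ValidationError(
            f"signature for {tf!r} has {len(members)} common upregulated target(s), "
            f"below the minimum size {min_size} "
            f"(per-dataset upregulated target counts: "
            + ", ".join(
                f"{name}={len(set(db.targets(tf)) & up)}" for name, up in up_sets.items()
            )
            + ")"
        )
    evidence = {
        name: t.loc[list(members), ["logFC", "q"]].copy() for name, t in named.items()
    }
    return SignatureDefinition(name=tf, members=members, evidence=evidence)


def signature_overlap(a: SignatureDefinition, b: SignatureDefinition) -> list[str]:
    """Sorted list of genes shared by two signatures."""
    return sorted(set(a.members) & set(b.members))


def signatures_to_collection(sigs) -> GeneSetCollection:
    return GeneSetCollection(s.as_gene_set() for s in sigs)
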