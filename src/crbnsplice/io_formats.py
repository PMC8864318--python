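"""Flat-file readers and writers for every external representation of the pipeline.

Formats handled
---------------
* GMT gene-set collections (tab-separated, MSigDB dialect: name, description,
  members...; the description field may be empty but must exist).
* Regulon edge lists (TSV with columns ``tf``, ``target`` and optional ``mode``).
* Expression matrices (TSV, first column gene identifier, remaining columns
  samples; values are either non-negative integer counts or real log-expression).
* Sample metadata (TSV with columns ``sample``, ``cohort``, ``setting``,
  ``purity`` followed by arbitrary covariate columns).
* Transcript quantification for a two-isoform locus (TSV with columns
  ``sample``, ``full_length``, ``del_exon10``, ``purity``).

Gene identifiers are opaque, case-sensitive strings; no symbol mapping is ever
performed.  All readers either load everything or raise — nothing is silently
dropped; deduplication events are logged with counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

log = logging.getLogger(__name__)

MODE_UNKNOWN = 0
MODE_ACTIVATING = 1
MODE_REPRESSING = -1


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene identifiers."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if len(self.members) == 0:
            raise ValidationError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


class GeneSetCollection:
    """An ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, s: GeneSet) -> None:
        if s.name in self._sets:
            raise ValidationError(f"duplicate gene set name {s.name!r}")
        self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must have at least three tab-separated fields: name, description
    (may be empty) and one or more members.  Duplicate members within a line
    are dropped with a logged warning; a duplicate set name is an error.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m != ""]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            seen: dict[str, None] = {}
            n_dup = 0
            for m in members:
                if m in seen:
                    n_dup += 1
                else:
                    seen[m] = None
            if n_dup:
                log.warning(
                    "gene set %r: dropped %d duplicate member(s)", name, n_dup
                )
            try:
                collection.add(GeneSet(name, description, tuple(seen)))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# Regulons
# ---------------------------------------------------------------------------

@dataclass
class RegulonDB:
    """Transcription-factor -> direct-target edges with optional mode labels.

    ``edges`` maps each TF to a deduplicated, non-empty frozenset of targets;
    ``modes`` maps (tf, target) to +1 / -1 / 0 (unknown, the default).
    """

    edges: dict[str, frozenset[str]]
    modes: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, targets in self.edges.items():
            if not targets:
                raise ValidationError(f"TF {tf!r} has an empty target set")

    @property
    def tfs(self) -> list[str]:
        return list(self.edges)

    def targets(self, tf: str) -> frozenset[str]:
        return self.edges[tf]

    def __contains__(self, tf: str) -> bool:
        return tf in self.edges

    def __len__(self) -> int:
        return len(self.edges)


def read_regulons(path: str | Path) -> RegulonDB:
    """Read a TF -> target edge list (TSV with header ``tf``, ``target`` [, ``mode``])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tf", "target"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df["tf"].isna().any() or (df["tf"] == "").any():
        raise SchemaError(f"{path}: empty tf identifier")
    if df["target"].isna().any() or (df["target"] == "").any():
        raise SchemaError(f"{path}: empty target identifier")

    edges: dict[str, set[str]] = {}
    modes: dict[tuple[str, str], int] = {}
    has_mode = "mode" in df.columns
    n_dup = 0
    for row in df.itertuples(index=False):
        tf, target = row.tf, row.target
        bucket = edges.setdefault(tf, set())
        if target in bucket:
            n_dup += 1
        bucket.add(target)
        if has_mode:
            raw = getattr(row, "mode")
            mode = MODE_UNKNOWN if pd.isna(raw) else int(raw)
            if mode not in (MODE_UNKNOWN, MODE_ACTIVATING, MODE_REPRESSING):
                raise SchemaError(f"{path}: invalid mode {raw!r} for edge ({tf}, {target})")
            modes[(tf, target)] = mode
    if n_dup:
        log.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return RegulonDB({tf: frozenset(t) for tf, t in edges.items()}, modes)


def write_regulons(db: RegulonDB, path: str | Path) -> None:
    rows = []
    for tf in sorted(db.edges):
        for target in sorted(db.edges[tf]):
            rows.append((tf, target, db.modes.get((tf, target), MODE_UNKNOWN)))
    pd.DataFrame(rows, columns=["tf", "target", "mode"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples values, flagged as raw counts or log-expression.

    ``data`` is a DataFrame with unique gene identifiers as the index and
    unique sample identifiers as columns.  When ``kind == "counts"`` the values
    must be non-negative integers (any numeric dtype with integral values).
    """

    data: pd.DataFrame
    kind: str  # "counts" | "log"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "log"):
            raise ValidationError(f"kind must be 'counts' or 'log', got {self.kind!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.kind == "counts" and values.size:
            if (values < 0).any():
                raise ValidationError("counts matrix contains negative values")
            if not np.array_equal(values, np.floor(values)):
                raise ValidationError("counts matrix contains non-integer values")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_expression(path: str | Path, kind: str) -> ExpressionMatrix:
    """Read a genes x samples TSV.  A missing cell is a parse error."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().to_numpy().any():
        n = int(df.isna().to_numpy().sum())
        raise ParseError(f"{path}: {n} missing expression value(s)")
    try:
        return ExpressionMatrix(df, kind)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene"
    if matrix.kind == "counts":
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Sample metadata and transcript quantification
# ---------------------------------------------------------------------------

METADATA_REQUIRED = ("sample", "cohort", "setting", "purity")
TRANSCRIPT_REQUIRED = ("sample", "full_length", "del_exon10", "purity")
DISEASE_SETTINGS = ("NDMM", "RRMM")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample annotations; index = sample id, covariates in extra columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in METADATA_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample identifiers")
    bad = ~df["setting"].isin(DISEASE_SETTINGS)
    if bad.any():
        raise SchemaError(
            f"{path}: invalid disease setting(s) {sorted(df.loc[bad, 'setting'].unique())}"
        )
    df["purity"] = df["purity"].astype(float)
    purity = df["purity"].to_numpy()
    if ((purity < 0) | (purity > 1)).any():
        raise SchemaError(f"{path}: purity outside [0, 1]")
    return df.set_index("sample")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_transcripts(path: str | Path) -> pd.DataFrame:
    """Read two-isoform transcript quantification; index = sample id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in TRANSCRIPT_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample identifiers")
    for col in ("full_length", "del_exon10", "purity"):
        df[col] = df[col].astype(float)
    for col in ("full_length", "del_exon10"):
        if (df[col].to_numpy() < 0).any():
            raise SchemaError(f"{path}: negative abundance in column {col!r}")
    purity = df["purity"].to_numpy(dtype=float)
    if ((purity < 0) | (purity > 1)).any():
        raise SchemaError(f"{path}: purity outside [0, 1]")
    return df.set_index("sample")


def write_transcripts(quant: pd.DataFrame, path: str | Path) -> None:
    out = quant.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.10g")


def check_annotation_pairing(meta: pd.DataFrame, matrix: ExpressionMatrix) -> None:
    """Every annotated sample must appear in the paired expression matrix."""
    missing = sorted(set(meta.index) - set(matrix.samples))
    if missing:
        raise ValidationError(
            f"{len(missing)} annotated sample(s) absent from expression matrix: {missing[:5]}"
        )
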