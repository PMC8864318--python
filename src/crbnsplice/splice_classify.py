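"""Isoform-ratio computation and HIGH-variant vs wild-type classification.

The per-sample statistic is the ratio of the exon-10-deleted isoform abundance
to the full-length isoform abundance.  Samples at or above the cutoff
(default 2.6) are labelled HIGH; all others WT.  The published cutoff already
folds in the purity adjustment for high-purity (>85% tumor cell) samples, so
purity is carried and reported but no per-sample correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 2.6

LABEL_HIGH = "HIGH"
LABEL_WT = "WT"


@dataclass(frozen=True)
class TranscriptQuant:
    """Two-isoform abundances (TPM-like) plus tumor purity for one sample."""

    sample: str
    abundance_full_length: float
    abundance_del_exon10: float
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.abundance_full_length < 0 or self.abundance_del_exon10 < 0:
            raise ValidationError(f"sample {self.sample!r}: negative abundance")
        if not 0.0 <= self.purity <= 1.0:
            raise ValidationError(f"sample {self.sample!r}: purity outside [0, 1]")


@dataclass(frozen=True)
class SpliceCall:
    sample: str
    ratio: float
    label: str
    cutoff_used: float

    def __post_init__(self) -> None:
        expected = LABEL_HIGH if self.ratio >= self.cutoff_used else LABEL_WT
        if self.label != expected:
            raise ValidationError(
                f"sample {self.sample!r}: label {self.label!r} inconsistent with "
                f"ratio {self.ratio} at cutoff {self.cutoff_used}"
            )


def compute_ratio(q: TranscriptQuant, pseudocount: float = 0.0) -> float:
    """Spliced/full-length ratio ``(del + pc) / (fl + pc)``.

    With a zero pseudocount, ``del > 0, fl == 0`` yields ``+inf`` and the
    degenerate ``0/0`` yields 0.0 with a logged warning.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    num = q.abundance_del_exon10 + pseudocount
    den = q.abundance_full_length + pseudocount
    if den == 0.0:
        if num == 0.0:
            log.warning("sample %r: 0/0 isoform ratio, reporting 0.0", q.sample)
            return 0.0
        return math.inf
    return num / den


def classify(
    quants: list[TranscriptQuant] | pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    pseudocount: float = 0.0,
) -> list[SpliceCall]:
    """Label each sample HIGH (ratio >= cutoff) or WT.

    Accepts either a list of :class:`TranscriptQuant` or a transcript table as
    returned by :func:`crbnsplice.io_formats.read_transcripts`.  Ties at the
    cutoff are HIGH by the documented ``>=`` rule.  Empty input yields an
    empty result.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if isinstance(quants, pd.DataFrame):
        quants = [
            TranscriptQuant(
                sample=str(sample),
                abundance_full_length=float(row["full_length"]),
                abundance_del_exon10=float(row["del_exon10"]),
                purity=float(row.get("purity", 1.0)),
            )
            for sample, row in quants.iterrows()
        ]
    calls = []
    for q in quants:
        ratio = compute_ratio(q, pseudocount)
        label = LABEL_HIGH if ratio >= cutoff else LABEL_WT
        calls.append(SpliceCall(q.sample, ratio, label, cutoff))
    return calls


def calls_to_frame(calls: list[SpliceCall]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "ratio": [c.ratio for c in calls],
            "label": [c.label for c in calls],
            "cutoff": [c.cutoff_used for c in calls],
        }
    )
    return df.set_index("sample")


def read_calls(path: str | Path) -> list[SpliceCall]:
    df = pd.read_csv(path, sep="\t").set_index("sample")
    return [
        SpliceCall(str(s), float(r["ratio"]), str(r["label"]), float(r["cutoff"]))
        for s, r in df.iterrows()
    ]


def write_calls(calls: list[SpliceCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", float_format="%.10g")


def prevalence(
    calls: list[SpliceCall],
    annotations: pd.DataFrame | None = None,
    stratum: str | None = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Fraction of HIGH calls, overall or per stratum, with exact binomial CI.

    Returns a DataFrame indexed by stratum level (single row ``all`` when no
    stratum is given) with columns ``n_high``, ``n_total``, ``prevalence``,
    ``ci_low``, ``ci_high`` (Clopper-Pearson).
    """
    if stratum is not None:
        if annotations is None:
            raise ValueError("stratified prevalence requires annotations")
        if stratum not in annotations.columns:
            raise KeyError(f"unknown stratum key {stratum!r}")
        groups: dict[str, list[SpliceCall]] = {}
        for c in calls:
            level = str(annotations.loc[c.sample, stratum])
            groups.setdefault(level, []).append(c)
    else:
        groups = {"all": list(calls)}

    rows = []
    for level in sorted(groups):
        members = groups[level]
        if not members:
            raise ValueError(f"stratum {level!r} has no calls")
        n_high = sum(c.label == LABEL_HIGH for c in members)
        n_total = len(members)
        ci = stats.binomtest(n_high, n_total).proportion_ci(
            confidence_level=confidence, method="exact"
        )
        rows.append((level, n_high, n_total, n_high / n_total, ci.low, ci.high))
    return pd.DataFrame(
        rows, columns=["stratum", "n_high", "n_total", "prevalence", "ci_low", "ci_high"]
    ).set_index("stratum")
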