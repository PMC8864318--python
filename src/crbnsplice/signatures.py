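"""Per-sample signature scoring, HIGH-vs-WT group tests, and score correlations.

Scoring delegates to the per-sample activity scorer in :mod:`.enrichment`;
group comparison is a two-sided Wilcoxon rank-sum (exact for small untied
groups, normal approximation with tie correction otherwise); correlations are
Pearson by default with Spearman behind a flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import gsva_scores
from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneSetCollection
from .splice_classify import LABEL_HIGH, LABEL_WT, SpliceCall

log = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 5
EXACT_MAX_GROUP = 20


@dataclass(frozen=True)
class GroupComparison:
    signature: str
    median_high: float
    median_wt: float
    statistic: float
    p: float
    direction: str  # "up" | "down" | "none"


@dataclass(frozen=True)
class CorrelationRecord:
    name_a: str
    name_b: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"|r| > 1 for pair ({self.name_a}, {self.name_b})")
        if self.n < 3:
            raise ValidationError("correlation needs n >= 3")


def score_signatures(
    logexpr: ExpressionMatrix,
    sigs: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.DataFrame:
    """One activity-score row per signature (signatures below min size skipped)."""
    return gsva_scores(logexpr, sigs, min_size=min_size)


def compare_groups(
    scores: pd.DataFrame, calls: list[SpliceCall]
) -> list[GroupComparison]:
    """Two-sided rank-sum test of HIGH vs WT scores for every signature.

    Uses the exact null when both groups are small (<= 20) and untied, the
    tie-corrected normal approximation otherwise.  Either group being empty is
    an error naming the group.
    """
    label = {c.sample: c.label for c in calls}
    missing = [s for s in scores.columns if s not in label]
    if missing:
        raise ValidationError(f"no splice call for scored sample(s) {missing[:5]}")
    high = [s for s in scores.columns if label[s] == LABEL_HIGH]
    wt = [s for s in scores.columns if label[s] == LABEL_WT]
    if not high:
        raise ValidationError("group HIGH is empty")
    if not wt:
        raise ValidationError("group WT is empty")

    results = []
    for name, row in scores.iterrows():
        x = row[high].to_numpy(dtype=float)
        y = row[wt].to_numpy(dtype=float)
        has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        method = (
            "exact"
            if max(x.size, y.size) <= EXACT_MAX_GROUP and not has_ties
            else "asymptotic"
        )
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        med_x, med_y = float(np.median(x)), float(np.median(y))
        direction = "up" if med_x > med_y else ("down" if med_x < med_y else "none")
        results.append(
            GroupComparison(
                signature=str(name),
                median_high=med_x,
                median_wt=med_y,
                statistic=float(res.statistic),
                p=float(min(res.pvalue, 1.0)),
                direction=direction,
            )
        )
    return results


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.signature, c.median_high, c.median_wt, c.statistic, c.p, c.direction)
            for c in comparisons
        ],
        columns=["signature", "median_high", "median_wt", "statistic", "p", "direction"],
    ).set_index("signature")


def correlate_scores(
    a: pd.Series | np.ndarray,
    b: pd.Series | np.ndarray,
    name_a: str = "a",
    name_b: str = "b",
    method: str = "pearson",
) -> CorrelationRecord:
    """Correlation between two per-sample score vectors over the same samples."""
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if not a.index.equals(b.index):
            raise ValidationError("score vectors cover different samples")
        name_a = a.name if a.name is not None else name_a
        name_b = b.name if b.name is not None else name_b
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("score vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValidationError("correlation needs n >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant score vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationRecord(str(name_a), str(name_b), r, float(res.pvalue), x.size)


def correlation_matrix(
    scores: pd.DataFrame,
    pairs: list[tuple[str, str]] | str = "all",
    method: str = "pearson",
) -> list[CorrelationRecord]:
    """Correlation records for all (or the requested) unordered signature pairs."""
    names = scores.index.tolist()
    if pairs == "all":
        wanted = list(itertools.combinations(names, 2))
    else:
        wanted = []
        for a, b in pairs:
            for name in (a, b):
                if name not in scores.index:
                    raise KeyError(f"unknown signature {name!r}")
            wanted.append((a, b))
    return [
        correlate_scores(scores.loc[a], scores.loc[b], a, b, method=method)
        for a, b in wanted
    ]


def correlations_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.name_a, r.name_b, r.r, r.p, r.n) for r in records],
        columns=["a", "b", "r", "p", "n"],
    )
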