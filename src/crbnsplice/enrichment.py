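"""Preranked gene-set enrichment and per-sample gene-set activity scoring.

Two related random-walk statistics live here:

* :func:`enrichment_score` / :func:`gsea_significance` — the weighted
  Kolmogorov-Smirnov-like running sum over a single ranked gene list, with a
  gene-label permutation null (set membership randomized at fixed set size),
  sign-matched normalized scores, nominal permutation p-values and the
  positive/negative pooled-null FDR.
* :func:`gsva_scores` — a phenotype-free per-sample activity score: each
  gene's expression is transformed by a Gaussian-kernel cross-sample CDF,
  genes are ranked within each sample, and a rank-weighted random walk over
  each set yields ``max deviation + min deviation`` as the score.

Ranking ties are always broken by gene identifier so results are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

log = logging.getLogger(__name__)

DEFAULT_WEIGHT = 1.0
DEFAULT_NPERM = 1000
_PERM_CHUNK = 250


# ---------------------------------------------------------------------------
# Ranked lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a real statistic, descending; ties broken by gene id."""

    genes: tuple[str, ...]
    stats: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.stats):
            raise ValidationError("genes and stats length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        if np.any(np.diff(self.stats) > 0):
            raise ValidationError("stats are not in descending order")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_stats(cls, stats: pd.Series | dict[str, float]) -> "RankedList":
        s = pd.Series(stats, dtype=float)
        if s.index.has_duplicates:
            raise ValidationError("duplicate genes in ranking statistic")
        if not np.isfinite(s.to_numpy()).all():
            raise ValidationError("non-finite ranking statistic")
        order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
        return cls(
            genes=tuple(str(s.index[i]) for i in order),
            stats=s.to_numpy()[order].astype(float),
        )


def rank_from_de(de: pd.DataFrame, by: str = "t") -> RankedList:
    """Build the preranked list from a DE table column (default moderated t)."""
    if by not in de.columns:
        raise ValueError(f"unknown ranking column {by!r}")
    return RankedList.from_stats(de[by])


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def _es_from_positions(absw: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Signed maximum deviation of the running sum, vectorized over rows.

    ``absw`` is |stat|^weight in ranked order (length N); ``positions`` is an
    (R, m) array of sorted 0-based hit indices, one row per instance.  The sum
    increments at hit i by its weight share and decrements by 1/(N-m) per
    miss; local maxima sit just after hits and local minima just before them
    (the walk ends at exactly zero), so only those 2m candidates are scanned.
    """
    positions = np.atleast_2d(positions)
    n_rows, m = positions.shape
    n = absw.shape[0]
    hit_w = absw[positions]
    denom = hit_w.sum(axis=1, keepdims=True)
    flat = denom[:, 0] == 0.0
    if flat.any():  # all member stats are zero: fall back to equal increments
        hit_w = np.where(flat[:, None], 1.0, hit_w)
        denom = np.where(flat[:, None], float(m), denom)
    cumw = np.cumsum(hit_w, axis=1) / denom
    miss_step = 0.0 if n == m else 1.0 / (n - m)
    idx = np.arange(m)
    after = cumw - (positions - idx) * miss_step
    before = cumw - hit_w / denom - (positions - idx) * miss_step
    vmax = np.maximum(after.max(axis=1), 0.0)
    vmin = np.minimum(before.min(axis=1), 0.0)
    return np.where(vmax >= -vmin, vmax, vmin)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_exponent: float = DEFAULT_WEIGHT
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score and the full running-sum profile.

    Hits step up proportionally to |stat|^weight_exponent; misses step down by
    1/(N - n_hits).  The score is the running sum's signed extreme.  Raises
    when the set has no member in the ranked universe.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    index = {g: i for i, g in enumerate(ranked.genes)}
    positions = np.array(sorted(index[g] for g in gene_set.members if g in index))
    if positions.size == 0:
        raise ValidationError(
            f"gene set {gene_set.name!r} has no overlap with the ranked universe"
        )
    n = len(ranked)
    m = positions.size
    hit = np.zeros(n, dtype=bool)
    hit[positions] = True
    absw = np.abs(ranked.stats) ** weight_exponent
    denom = absw[hit].sum()
    inc = (absw if denom > 0 else np.ones(n)) * hit
    inc = inc / (denom if denom > 0 else m)
    dec = np.zeros(n)
    if n > m:
        dec[~hit] = 1.0 / (n - m)
    running = np.cumsum(inc - dec)
    vmax = max(float(running.max()), 0.0)
    vmin = min(float(running.min()), 0.0)
    # signed extreme; on an exact magnitude tie the positive extreme wins
    es = vmax if vmax >= -vmin else vmin
    return es, running


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def _null_positions(rng: np.random.Generator, n: int, m: int, n_perm: int) -> np.ndarray:
    """(n_perm, m) sorted random hit positions (membership permutation)."""
    out = np.empty((n_perm, m), dtype=np.intp)
    for start in range(0, n_perm, _PERM_CHUNK):
        stop = min(start + _PERM_CHUNK, n_perm)
        keys = rng.random((stop - start, n))
        part = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[start:stop] = np.sort(part, axis=1)
    return out


def _signed_normalize(es: np.ndarray, mean_pos: float, mean_neg: float) -> np.ndarray:
    out = np.where(es >= 0, es / mean_pos, es / mean_neg)
    return out


def gsea_significance(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = DEFAULT_NPERM,
    seed: int | None = None,
    weight_exponent: float = DEFAULT_WEIGHT,
) -> pd.DataFrame:
    """Permutation NES, nominal p and pooled-null FDR for every gene set.

    The null fixes the ranked list and redraws set membership at the observed
    (universe-restricted) set size.  NES divides each score by the mean
    magnitude of same-sign null scores for its set size; nominal p counts
    same-sign null scores at least as extreme, with a +1 floor; FDR follows
    the pooled positive/negative null procedure.  Sets with no universe
    overlap are skipped with a warning.  Results are sorted by NES descending.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if seed is None:
        raise ValueError("a seed is required for permutation significance")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    index = {g: i for i, g in enumerate(ranked.genes)}
    absw = np.abs(ranked.stats) ** weight_exponent

    kept: list[tuple[str, np.ndarray]] = []
    for s in sets:
        positions = np.array(sorted(index[g] for g in s.members if g in index))
        if positions.size == 0:
            log.warning("set %r has no overlap with the ranked universe; skipped", s.name)
            continue
        kept.append((s.name, positions))
    if not kept:
        raise ValidationError("no gene set overlaps the ranked universe")

    sizes = sorted({p.size for _, p in kept})
    null_es: dict[int, np.ndarray] = {}
    null_means: dict[int, tuple[float, float]] = {}
    for m in sizes:
        es_null = _es_from_positions(absw, _null_positions(rng, n, m, n_perm))
        pos = es_null[es_null >= 0]
        neg = es_null[es_null < 0]
        mean_pos = float(pos.mean()) if pos.size else np.nan
        mean_neg = float(np.abs(neg).mean()) if neg.size else np.nan
        null_es[m] = es_null
        null_means[m] = (mean_pos, mean_neg)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, positions in kept:
        m = positions.size
        es = float(_es_from_positions(absw, positions[None, :])[0])
        es_null = null_es[m]
        mean_pos, mean_neg = null_means[m]
        same_sign = es_null >= 0 if es >= 0 else es_null < 0
        n_sign = int(same_sign.sum())
        if n_sign == 0:
            log.warning("set %r: no same-sign permutations; p at floor", name)
            p = 1.0 / (1.0 + n_perm)
            nes = np.nan
        else:
            extreme = es_null[same_sign] >= es if es >= 0 else es_null[same_sign] <= es
            p = (1.0 + int(extreme.sum())) / (1.0 + n_sign)
            nes = es / mean_pos if es >= 0 else es / mean_neg
        rows.append((name, m, es, nes, p))
    for m in sizes:
        mean_pos, mean_neg = null_means[m]
        es_null = null_es[m]
        norm = np.where(
            es_null >= 0,
            es_null / (mean_pos if np.isfinite(mean_pos) else np.nan),
            es_null / (mean_neg if np.isfinite(mean_neg) else np.nan),
        )
        null_nes_pool.append(norm[np.isfinite(norm)])
    pool = np.concatenate(null_nes_pool)

    table = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "p"]).set_index("set")
    obs = table["NES"].to_numpy()
    pool_pos = pool[pool >= 0]
    pool_neg = pool[pool < 0]
    obs_pos = obs[np.isfinite(obs) & (obs >= 0)]
    obs_neg = obs[np.isfinite(obs) & (obs < 0)]
    q = np.full(obs.shape, np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            frac_null = (pool_pos >= nes).mean() if pool_pos.size else 1.0
            frac_obs = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            frac_null = (pool_neg <= nes).mean() if pool_neg.size else 1.0
            frac_obs = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        q[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
    table["q"] = q
    return table.sort_values(["NES", "q"], ascending=[False, True], kind="stable")


# ---------------------------------------------------------------------------
# Per-sample activity scores
# ---------------------------------------------------------------------------

def _kernel_cdf(values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel cross-sample CDF transform, gene-wise (bandwidth sd/4)."""
    n_genes, n_samples = values.shape
    sd = values.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    out = np.empty_like(values)
    chunk = max(1, 4_000_000 // (n_samples * n_samples))
    for start in range(0, n_genes, chunk):
        stop = min(start + chunk, n_genes)
        block = values[start:stop]
        diff = (block[:, :, None] - block[:, None, :]) / h[start:stop, None, None]
        out[start:stop] = special.ndtr(diff).mean(axis=2)
    # constant genes get an uninformative CDF value
    out[sd == 0] = 0.5
    return out


def gsva_scores(
    logexpr: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    min_size: int = 1,
) -> pd.DataFrame:
    """Per-sample gene-set activity scores (sets x samples).

    Per gene, expression is transformed by a smoothed cross-sample CDF
    (Gaussian kernel, bandwidth = gene sd / 4).  Per sample, genes are ranked
    by the transformed value (ties broken by gene id) and assigned the
    symmetric rank statistic |rank - (G+1)/2|.  Per set, a weighted random
    walk (|statistic|^tau on hits, uniform decrements on misses) gives
    ``max deviation + min deviation`` as the signed score, always in [-1, 1].
    Sets with fewer than ``min_size`` members in the matrix are skipped with a
    warning.
    """
    if logexpr.kind != "log":
        raise ValidationError("gsva_scores expects log-scale expression")
    values = logexpr.values()
    n_genes, n_samples = values.shape
    if n_samples < 3:
        raise ValidationError("per-sample scoring needs >= 3 samples")

    genes = np.array(logexpr.genes)
    kept_sets: list[tuple[str, np.ndarray]] = []
    gene_index = {g: i for i, g in enumerate(genes)}
    for s in sets:
        idx = np.array(sorted(gene_index[g] for g in s.members if g in gene_index))
        if idx.size < max(1, min_size):
            log.warning(
                "set %r has %d member(s) in the matrix (< %d); skipped",
                s.name, idx.size, max(1, min_size),
            )
            continue
        if idx.size >= n_genes:
            log.warning("set %r covers the whole universe; skipped", s.name)
            continue
        kept_sets.append((s.name, idx))
    if not kept_sets:
        raise ValidationError("no scorable gene set")

    z = _kernel_cdf(values)
    # per-sample walk order: decreasing transformed value, ties by gene id
    order = np.empty((n_genes, n_samples), dtype=np.intp)
    for j in range(n_samples):
        order[:, j] = np.lexsort((genes, -z[:, j]))
    ranks = np.arange(1, n_genes + 1, dtype=float)
    pos_w = np.abs(ranks - (n_genes + 1) / 2.0) ** tau

    scores = np.empty((len(kept_sets), n_samples))
    member = np.zeros(n_genes, dtype=bool)
    for si, (_, idx) in enumerate(kept_sets):
        member[:] = False
        member[idx] = True
        m_ord = member[order]  # (G, n) membership in walk order
        w = pos_w[:, None] * m_ord
        denom = w.sum(axis=0)
        flat = denom == 0
        if flat.any():
            w[:, flat] = m_ord[:, flat].astype(float)
            denom = np.where(flat, m_ord.sum(axis=0), denom)
        walk = np.cumsum(w, axis=0) / denom - np.cumsum(~m_ord, axis=0) / (
            n_genes - idx.size
        )
        scores[si] = np.maximum(walk.max(axis=0), 0.0) + np.minimum(walk.min(axis=0), 0.0)
    return pd.DataFrame(
        scores,
        index=pd.Index([name for name, _ in kept_sets], name="signature"),
        columns=logexpr.data.columns,
    )


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="signature")


def write_scores(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out.index.name = "signature"
    out.to_csv(path, sep="\t", float_format="%.10g")
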