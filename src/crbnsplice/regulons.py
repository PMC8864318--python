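"""Master-regulator identification by hypergeometric regulon over-representation.

Each transcription factor's regulon (restricted to the tested-gene universe)
is tested for over-representation in the upregulated differential-expression
gene set with the upper hypergeometric tail, computed in log space; BH FDR is
applied across the tested factors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special

from .diffexpr import bh_fdr, upregulated_genes
from .io_formats import RegulonDB

log = logging.getLogger(__name__)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    ``N`` is the universe size, ``K`` the number of marked items (regulon
    genes in the universe), ``n`` the draw size (upregulated genes), ``k`` the
    observed overlap.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if value < 0 or int(value) != value:
            raise ValueError(f"{name} must be a non-negative integer, got {value}")
    if K > N or n > N:
        raise ValueError(f"marked ({K}) and drawn ({n}) must not exceed universe ({N})")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    j = np.arange(k, min(K, n) + 1)
    logpmf = (
        _log_comb(K, j)
        + _log_comb(N - K, n - j)
        - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(special.logsumexp(logpmf))))


def hypergeom_tail_all_k(K: int, n: int, N: int) -> np.ndarray:
    """Upper-tail probabilities for every overlap ``k = 0..min(K, n)`` at once.

    Same log-space computation as :func:`hypergeom_tail` (suffix log-sum-exp
    of the log pmf), vectorized over k.
    """
    for name, value in (("K", K), ("n", n), ("N", N)):
        if value < 0 or int(value) != value:
            raise ValueError(f"{name} must be a non-negative integer, got {value}")
    if K > N or n > N:
        raise ValueError(f"marked ({K}) and drawn ({n}) must not exceed universe ({N})")
    kmax = min(K, n)
    j = np.arange(0, kmax + 1)
    logpmf = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    tail = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    p = np.minimum(np.exp(tail), 1.0)
    p[0] = 1.0
    return p


def _log_comb(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return special.gammaln(a + 1) - special.gammaln(b + 1) - special.gammaln(a - b + 1)


def master_regulators(
    de: pd.DataFrame,
    db: RegulonDB,
    universe: list[str] | None = None,
    logfc_min: float = 0.0,
    q_max: float = 0.05,
    direction: str = "up",
) -> pd.DataFrame:
    """Rank TFs by regulon enrichment in the (default upregulated) DE set.

    The universe defaults to the genes present in the DE table (all tested
    genes).  Every regulon is intersected with the universe before testing;
    TFs with no universe target are dropped with a warning.  Output is sorted
    by (q, p, tf) and carries the overlap gene list (comma-joined).  An empty
    selected gene set yields an empty table with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if universe is None:
        universe = de.index.tolist()
    universe_set = set(universe)
    if direction == "up":
        selected = set(upregulated_genes(de, logfc_min, q_max))
    else:
        mask = (de["logFC"] < -logfc_min) & (de["q"] < q_max)
        selected = set(de.index[mask])
    if not selected <= universe_set:
        raise ValueError("selected DE genes are not contained in the universe")

    columns = ["tf", "N", "K", "n", "k", "p", "q", "overlap"]
    if not selected:
        log.warning("no %sregulated genes at logFC>%.3g, q<%.3g", direction, logfc_min, q_max)
        return pd.DataFrame(columns=columns).set_index("tf")

    N = len(universe_set)
    n = len(selected)
    rows = []
    for tf in db.tfs:
        targets = db.targets(tf) & universe_set
        if not targets:
            log.warning("TF %r has no target in the universe; skipped", tf)
            continue
        overlap = sorted(targets & selected)
        K = len(targets)
        k = len(overlap)
        p = hypergeom_tail(k, K, n, N)
        rows.append((tf, N, K, n, k, p, ",".join(overlap)))
    if not rows:
        return pd.DataFrame(columns=columns).set_index("tf")
    table = pd.DataFrame(rows, columns=["tf", "N", "K", "n", "k", "p", "overlap"])
    table["q"] = bh_fdr(table["p"].to_numpy())
    table = table.sort_values(["q", "p", "tf"], kind="stable").set_index("tf")
    return table[["N", "K", "n", "k", "p", "q", "overlap"]]


def read_mra_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="tf")
    if "overlap" in df.columns:
        df["overlap"] = df["overlap"].fillna("")
    return df


def write_mra_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")
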