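"""Covariate-adjusted differential expression from counts.

The chain is: log-CPM normalization, mean-variance precision weights from a
lowess trend, gene-wise weighted least squares, empirical-Bayes variance
moderation with a scaled-inverse-chi-squared prior estimated by moment
matching on log residual variances, and Benjamini-Hochberg FDR.

Library sizes are plain column totals; compositional normalization factors are
deliberately omitted (see package docs).  Per-gene weights are normalized to
mean one, which leaves coefficients, moderated statistics and p-values
unchanged but makes ``s2`` invariant to a uniform rescaling of the weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .splice_classify import LABEL_HIGH, SpliceCall

log = logging.getLogger(__name__)

DEFAULT_PRIOR_COUNT = 0.5
DEFAULT_SPAN = 0.5
GROUP_COLUMN = "group"


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def log_cpm(counts: ExpressionMatrix, prior_count: float = DEFAULT_PRIOR_COUNT) -> ExpressionMatrix:
    """log2 counts-per-million: ``log2((count + pc_j) / (libsize_j + 2 pc_j) * 1e6)``.

    ``prior_count`` must be positive so zero counts stay finite.  The prior is
    scaled per sample in proportion to library size (``pc_j = prior_count *
    libsize_j / mean(libsize)``) so that samples with proportional counts map
    to identical log-CPM columns.
    """
    if counts.kind != "counts":
        raise ValidationError("log_cpm expects a counts matrix")
    if prior_count <= 0:
        raise ValueError(f"prior_count must be > 0, got {prior_count}")
    values = counts.values()
    libsize = values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        bad = [counts.samples[i] for i in zero]
        raise ValidationError(f"zero library size for sample(s) {bad}")
    pc = prior_count * libsize / libsize.mean()
    out = np.log2((values + pc) / (libsize + 2 * pc) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(out, index=counts.data.index, columns=counts.data.columns), "log"
    )


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def build_design(
    meta: pd.DataFrame,
    calls: list[SpliceCall],
    covariates: list[str] | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Intercept + HIGH indicator + dummy/numeric covariate columns.

    Row order follows ``samples`` when given, else the call order.  Categorical
    covariates are expanded to treatment-coded dummies.
    """
    label_by_sample = {c.sample: c.label for c in calls}
    if samples is None:
        samples = [c.sample for c in calls]
    missing = [s for s in samples if s not in label_by_sample]
    if missing:
        raise ValidationError(f"no splice call for sample(s) {missing[:5]}")
    design = pd.DataFrame(index=pd.Index(samples, name="sample"))
    design["intercept"] = 1.0
    design[GROUP_COLUMN] = [
        1.0 if label_by_sample[s] == LABEL_HIGH else 0.0 for s in samples
    ]
    for cov in covariates or []:
        if cov not in meta.columns:
            raise ValidationError(f"covariate {cov!r} absent from metadata")
        col = meta.loc[samples, cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = col.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                design[name] = dummies[name].to_numpy(dtype=float)
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full column rank
        collinear = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {collinear}")


# ---------------------------------------------------------------------------
# Precision weights
# ---------------------------------------------------------------------------

def voom_weights(
    logcpm: ExpressionMatrix, design: pd.DataFrame, span: float = DEFAULT_SPAN
) -> np.ndarray:
    """Inverse fourth-power precision weights from the sqrt-sd vs mean trend.

    An unweighted linear model is fitted per gene; the square root of the
    residual standard deviation is smoothed against mean log-expression by
    lowess (one pass, the given span) and the trend, evaluated at each fitted
    value, is raised to the -4 to give a strictly positive weight matrix of
    the same shape as the expression matrix.
    """
    if logcpm.kind != "log":
        raise ValidationError("voom_weights expects log-expression")
    Y = logcpm.values()
    n_genes, n_samples = Y.shape
    if n_genes < 10:
        raise ValidationError(f"need >= 10 genes to fit a trend, got {n_genes}")
    X = design.to_numpy(dtype=float)
    if n_samples < X.shape[1]:
        raise ValidationError(
            f"fewer samples ({n_samples}) than design columns ({X.shape[1]})"
        )
    if n_samples <= X.shape[1]:
        raise ValidationError("no residual degrees of freedom for the trend fit")

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    resid = Y - fitted
    df_res = n_samples - X.shape[1]
    sigma = np.sqrt((resid**2).sum(axis=1) / df_res)
    sqrt_sd = np.sqrt(sigma)
    mean_expr = Y.mean(axis=1)

    trend = lowess(sqrt_sd, mean_expr, frac=span, it=0, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # lowess returns sorted unique-x pairs; interp clamps outside the range
    pred = np.interp(fitted, tx, ty)
    floor = max(1e-6, float(np.min(ty[ty > 0], initial=1e-6)) * 1e-3)
    pred = np.clip(pred, floor, None)
    weights = pred**-4.0
    if not np.isfinite(weights).all() or (weights <= 0).any():
        raise ValidationError("non-finite or non-positive precision weights")
    return weights


# ---------------------------------------------------------------------------
# Linear models and moderation
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Gene-wise weighted least-squares results."""

    genes: list[str]
    coef_names: list[str]
    coefficients: np.ndarray  # (genes, coefs)
    stdev_unscaled: np.ndarray  # (genes, coefs)
    sigma2: np.ndarray  # (genes,)
    df_residual: int
    mean_expression: np.ndarray  # (genes,)


def fit_lm(
    logcpm: ExpressionMatrix,
    design: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> LinearFit:
    """Weighted least squares per gene; ``sigma2`` uses mean-one weights."""
    Y = logcpm.values()
    n_genes, n_samples = Y.shape
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n != n_samples:
        raise ValidationError("design rows do not match expression samples")
    _check_full_rank(design)
    if n <= p:
        raise ValidationError("no residual degrees of freedom")
    if weights is None:
        W = np.ones_like(Y)
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != Y.shape:
            raise ValidationError("weight matrix shape does not match expression")
        if (W <= 0).any() or not np.isfinite(W).all():
            raise ValidationError("weights must be positive and finite")
        W = W / W.mean(axis=1, keepdims=True)

    xtwx = np.einsum("ni,gn,nj->gij", X, W, X)
    xtwy = np.einsum("ni,gn,gn->gi", X, W, Y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    covu = np.linalg.inv(xtwx)
    stdev_unscaled = np.sqrt(np.einsum("gii->gi", covu))
    resid = Y - beta @ X.T
    sigma2 = np.einsum("gn,gn->g", W, resid**2) / (n - p)
    return LinearFit(
        genes=logcpm.genes,
        coef_names=design.columns.tolist(),
        coefficients=beta,
        stdev_unscaled=stdev_unscaled,
        sigma2=sigma2,
        df_residual=n - p,
        mean_expression=Y.mean(axis=1),
    )


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (monotone decreasing)
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the marginal distribution of log sigma2.

    Returns ``(inf, exp(mean adjusted log s2))`` when the excess variance of
    log residual variances is non-positive (complete pooling), with a warning.
    """
    z = np.log(sigma2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        log.warning("moment estimator gave non-positive prior df; pooling completely")
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def ebayes(
    fit: LinearFit,
    coef: str = GROUP_COLUMN,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated t-table for one coefficient, with BH FDR appended.

    ``prior_df``/``prior_var`` override the estimated hyperparameters
    (``prior_df=0`` reproduces the ordinary t-test; ``prior_df=inf`` pools the
    variances completely).  Genes with non-finite residual variance are
    dropped with a warning.
    """
    if coef not in fit.coef_names:
        raise ValueError(f"unknown coefficient {coef!r}")
    ci = fit.coef_names.index(coef)
    keep = np.isfinite(fit.sigma2) & (fit.sigma2 > 0)
    if not keep.all():
        log.warning("dropping %d gene(s) with non-finite residual variance", int((~keep).sum()))
    sigma2 = fit.sigma2[keep]
    genes = [g for g, k in zip(fit.genes, keep) if k]
    d = fit.df_residual

    if prior_df is None:
        d0, s0sq = estimate_prior(sigma2, d)
        if prior_var is not None:
            s0sq = prior_var
    else:
        d0 = prior_df
        if d0 < 0:
            raise ValueError("prior_df must be >= 0")
        if prior_var is not None:
            s0sq = prior_var
        elif np.isinf(d0):
            _, s0sq = estimate_prior(sigma2, d)
        else:
            s0sq = float(np.median(sigma2)) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(sigma2, s0sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = sigma2
        df_total = float(d)
    else:
        s2_post = (d0 * s0sq + d * sigma2) / (d0 + d)
        df_total = d0 + d

    coefs = fit.coefficients[keep, ci]
    su = fit.stdev_unscaled[keep, ci]
    tstat = coefs / (np.sqrt(s2_post) * su)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    table = pd.DataFrame(
        {
            "logFC": coefs,
            "aveExpr": fit.mean_expression[keep],
            "t": tstat,
            "p": p,
            "q": bh_fdr(p),
            "df_res": float(d),
            "df_prior": d0,
        },
        index=pd.Index(genes, name="gene"),
    )
    return table


def bh_fdr(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def run_de(
    counts: ExpressionMatrix,
    meta: pd.DataFrame,
    calls: list[SpliceCall],
    covariates: list[str] | None = None,
    prior_count: float = DEFAULT_PRIOR_COUNT,
    span: float = DEFAULT_SPAN,
) -> pd.DataFrame:
    """Counts -> moderated-t DE table for the HIGH vs WT contrast."""
    design = build_design(meta, calls, covariates, samples=counts.samples)
    logexpr = log_cpm(counts, prior_count)
    weights = voom_weights(logexpr, design, span)
    fit = fit_lm(logexpr, design, weights)
    return ebayes(fit, GROUP_COLUMN)


def upregulated_genes(
    de: pd.DataFrame, logfc_min: float = 0.0, q_max: float = 0.05
) -> list[str]:
    """Genes with positive effect above ``logfc_min`` and q below ``q_max``."""
    mask = (de["logFC"] > logfc_min) & (de["q"] < q_max)
    return de.index[mask].tolist()


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", float_format="%.10g")
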