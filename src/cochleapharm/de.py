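"""Negative-binomial two-group Wald differential expression.

A deliberately transparent reimplementation of the standard bulk RNA-seq
workflow: per-gene method-of-moments dispersion with a mean-dispersion trend
fallback, a per-gene NB GLM (log link, size-factor offset, intercept + group
indicator) fitted by IRLS, a Wald test on the group coefficient, and
Benjamini-Hochberg FDR control.  No empirical-Bayes dispersion shrinkage,
no fold-change shrinkage, no independent filtering, no outlier handling:
every component is testable against first principles.

The negative binomial is parameterized by mean mu and dispersion alpha with
variance mu + alpha * mu^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DispersionEstimate",
    "estimate_dispersion",
    "wald_de",
    "bh_adjust",
    "classify_direction",
    "venn_degs",
    "top_table",
    "ALPHA_MIN",
]

ALPHA_MIN = 1e-8
_MAX_ITER = 100
_TOL = 1e-8
_BETA_BOUND = 30.0  # natural-log scale; caps separation when one group is all zero


@dataclass
class DispersionEstimate:
    """Per-gene NB dispersion used for testing, plus the raw moments estimates.

    ``alpha`` holds the values the Wald engine uses; ``alpha_gene`` the raw
    per-gene method-of-moments estimates (NaN where not estimable); the
    method tag records whether a gene's ``alpha`` came from its own moments
    estimate or from the fitted mean-dispersion trend.
    """

    gene_ids: list[str]
    alpha: np.ndarray
    method: list[str]  # "moments" | "trend-fallback"
    trend_coef: tuple[float, float] | None  # (a0, a1) of alpha = a0/mu + a1, if fitted
    alpha_gene: np.ndarray | None = None


def estimate_dispersion(
    counts: CountMatrix,
    factors: np.ndarray,
    groups: np.ndarray,
    alpha_min: float = ALPHA_MIN,
    fit_type: str = "trend",
) -> DispersionEstimate:
    """Method-of-moments dispersion on normalized counts, pooled within groups.

    Per gene: mu_bar is the grand mean of normalized counts and s2 the
    pooled within-group sample variance (group means removed, Bessel
    correction with n - n_groups degrees of freedom), giving the raw
    moments estimate (s2 - mu_bar) / mu_bar^2.  A mean-dispersion trend
    alpha(mu) = a0/mu + a1 is fitted to the estimable (positive) raw
    estimates by least squares with one outlier-trimming refit.

    fit_type="trend" (default): the trend value is used for every gene.
    With few replicates the gene-wise moments estimate is far too noisy to
    plug into a Wald statistic — sampling noise in alpha translates into
    anti-conservative tests — so gene-wise values only inform the trend.

    fit_type="gene-wise": each estimable gene keeps its own moments value
    (floored at ``alpha_min``); only genes with a non-positive raw estimate
    fall back to the trend.  Appropriate when replication is large.
    """
    if fit_type not in ("trend", "gene-wise"):
        raise ValueError(f"unknown fit_type {fit_type!r}")
    groups = np.asarray(groups)
    levels = np.unique(groups)
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 replicates")
    norm = counts.counts / np.asarray(factors, dtype=float)[None, :]
    n = norm.shape[1]
    mu_bar = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    for lev in levels:
        sub = norm[:, groups == lev]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    dof = n - len(levels)
    s2 = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu_bar) / mu_bar**2
    estimable = np.isfinite(raw) & (raw > 0) & (mu_bar > 0)
    alpha_gene = np.where(estimable, raw, np.nan)

    trend_coef = None
    trend_alpha = np.full(norm.shape[0], alpha_min)
    if estimable.sum() >= 2 and np.unique(mu_bar[estimable]).size >= 2:
        sel = estimable.copy()
        for _ in range(2):  # plain fit, then refit without gross outliers
            X = np.column_stack([1.0 / mu_bar[sel], np.ones(int(sel.sum()))])
            coef, *_ = np.linalg.lstsq(X, raw[sel], rcond=None)
            a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
            pred = a0 / mu_bar + a1
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = raw / np.maximum(pred, alpha_min)
            new_sel = estimable & (ratio > 1e-2) & (ratio < 1e2)
            if new_sel.sum() < 2 or new_sel.sum() == sel.sum():
                break
            sel = new_sel
        trend_coef = (a0, a1)
        with np.errstate(divide="ignore"):
            trend_alpha = np.where(mu_bar > 0, a0 / np.maximum(mu_bar, 1e-300) + a1, a1)
        trend_alpha = np.maximum(trend_alpha, alpha_min)

    if fit_type == "trend":
        alpha = trend_alpha.copy()
        method = ["trend-fallback"] * norm.shape[0]
    else:
        alpha = np.where(estimable, np.maximum(raw, alpha_min), trend_alpha)
        method = ["moments" if e else "trend-fallback" for e in estimable]
    return DispersionEstimate(list(counts.gene_ids), alpha, method, trend_coef, alpha_gene)


def _irls_nb(
    counts: np.ndarray,
    offset: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-gene NB GLMs sharing a two-column design.

    counts: genes x samples; offset: log size factors (samples,);
    x: group indicator (samples,); alpha: per-gene dispersion.
    Returns (beta [genes x 2], se_beta1, converged).
    """
    g, n = counts.shape
    X = np.column_stack([np.ones(n), x])  # n x 2
    # initialise from group means of normalized counts
    norm = counts / np.exp(offset)[None, :]
    m0 = norm[:, x == 0].mean(axis=1)
    m1 = norm[:, x == 1].mean(axis=1)
    eps = 0.5 / n
    beta = np.column_stack([np.log(np.maximum(m0, eps)), np.log(np.maximum(m1, eps)) - np.log(np.maximum(m0, eps))])
    beta = np.clip(beta, -_BETA_BOUND, _BETA_BOUND)
    converged = np.zeros(g, dtype=bool)
    alpha = alpha[:, None]

    def deviance(beta):
        eta = beta @ X.T + offset[None, :]
        mu = np.exp(np.clip(eta, -700, 700))
        mu = np.maximum(mu, 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            term1 = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
            term2 = (counts + 1.0 / alpha) * np.log((1.0 + alpha * counts) / (1.0 + alpha * mu))
        return 2.0 * (term1 - term2).sum(axis=1)

    dev = deviance(beta)
    active = np.ones(g, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = beta[active] @ X.T + offset[None, :]
        mu = np.exp(np.clip(eta, -700, 700))
        mu = np.maximum(mu, 1e-12)
        a = alpha[active]
        W = mu / (1.0 + a * mu)  # IRLS weights for NB log link
        z = eta - offset[None, :] + (counts[active] - mu) / mu  # working response minus offset
        # per-gene 2x2 weighted least squares
        Sw = W.sum(axis=1)
        Swx = (W * x[None, :]).sum(axis=1)
        Swxx = (W * (x**2)[None, :]).sum(axis=1)
        Swz = (W * z).sum(axis=1)
        Swxz = (W * x[None, :] * z).sum(axis=1)
        det = Sw * Swxx - Swx**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        b0 = (Swxx * Swz - Swx * Swxz) / det
        b1 = (Sw * Swxz - Swx * Swz) / det
        new_beta = np.clip(np.column_stack([b0, b1]), -_BETA_BOUND, _BETA_BOUND)
        beta_full = beta.copy()
        beta_full[active] = new_beta
        new_dev = deviance(beta_full)
        moved = np.abs(new_dev - dev) > tol * (np.abs(new_dev) + 0.1)
        beta = beta_full
        dev = new_dev
        newly_done = active.copy()
        newly_done[active] = ~moved[active]
        converged |= newly_done
        active &= moved
    # standard errors from the expected Fisher information at the optimum
    eta = beta @ X.T + offset[None, :]
    mu = np.maximum(np.exp(np.clip(eta, -700, 700)), 1e-12)
    W = mu / (1.0 + alpha * mu)
    Sw = W.sum(axis=1)
    Swx = (W * x[None, :]).sum(axis=1)
    Swxx = (W * (x**2)[None, :]).sum(axis=1)
    det = Sw * Swxx - Swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = Sw / det
    se_b1 = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    return beta, se_b1, converged


def wald_de(
    counts: CountMatrix,
    factors: np.ndarray,
    dispersions: DispersionEstimate,
    groups: np.ndarray,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test between two groups.

    ``groups`` is a two-level factor over samples; ``reference`` names the
    baseline level (defaults to the first level in sorted order), so a
    positive log2 fold change means higher expression in the non-reference
    level.  Returns a DataFrame indexed by gene with columns base_mean,
    log2fc, se, wald, p.  Genes whose IRLS fit did not converge get p = NaN
    and are excluded from later BH adjustment.
    """
    groups = np.asarray(groups)
    levels = sorted(np.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError(f"wald_de requires exactly two groups, got {levels}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among groups {levels}")
    other = next(l for l in levels if l != reference)
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
    x = (groups == other).astype(float)
    factors = np.asarray(factors, dtype=float)
    offset = np.log(factors)
    mat = counts.counts.astype(float)

    beta, se_b1, converged = _irls_nb(mat, offset, x, dispersions.alpha)
    ln2 = np.log(2.0)
    log2fc = beta[:, 1] / ln2
    se = se_b1 / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(wald))
    ok = converged & np.isfinite(p)
    p = np.where(ok, p, np.nan)
    if (~ok).any():
        logger.info("wald_de: %d genes failed to converge; p set to NaN", int((~ok).sum()))
    base_mean = (mat / factors[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "converged": ok,
        },
        index=pd.Index(counts.gene_ids, name="gene"),
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested hypotheses) are excluded from the number of tests
    m and returned as NaN.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    tested = ~np.isnan(arr)
    vals = arr[tested]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    result = np.empty(m)
    result[order] = adjusted
    out[tested] = result
    return out


def classify_direction(de: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Attach BH-adjusted p-values and up/down/ns direction calls.

    A gene is up iff fdr < threshold and log2fc > 0, down iff fdr < threshold
    and log2fc < 0, and ns otherwise (including an exactly-zero fold change).
    """
    out = de.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    sig = out["fdr"] < fdr_threshold
    direction = np.where(
        sig & (out["log2fc"] > 0), "up", np.where(sig & (out["log2fc"] < 0), "down", "ns")
    )
    direction = np.where(out["fdr"].isna(), "ns", direction)
    out["direction"] = direction
    return out


def venn_degs(deg_a: set[str], deg_b: set[str]) -> dict:
    """Two-set Venn arithmetic over DEG identifiers, with shared percentages."""
    shared = deg_a & deg_b
    return {
        "unique_a": sorted(deg_a - deg_b),
        "unique_b": sorted(deg_b - deg_a),
        "shared": sorted(shared),
        "n_unique_a": len(deg_a - deg_b),
        "n_unique_b": len(deg_b - deg_a),
        "n_shared": len(shared),
        "pct_shared_of_a": 100.0 * len(shared) / len(deg_a) if deg_a else 0.0,
        "pct_shared_of_b": 100.0 * len(shared) / len(deg_b) if deg_b else 0.0,
    }


def top_table(de: pd.DataFrame, k: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top k up- and downregulated significant genes, ranked by log2 fold change.

    Ties break lexicographically by gene id.  If fewer than k significant
    genes exist in a direction, all of them are returned with a warning.
    """
    if "direction" not in de.columns:
        raise ValueError("run classify_direction first")
    sortable = de.reset_index().rename(columns={de.index.name or "index": "gene"})
    up = sortable[sortable["direction"] == "up"].sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="stable"
    )
    down = sortable[sortable["direction"] == "down"].sort_values(
        ["log2fc", "gene"], ascending=[True, True], kind="stable"
    )
    for name, table in (("up", up), ("down", down)):
        if len(table) < k:
            warnings.warn(
                f"only {len(table)} significant {name} genes available (k={k})",
                stacklevel=2,
            )
    return up.head(k).set_index("gene"), down.head(k).set_index("gene")
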