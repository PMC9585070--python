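"""Stratified LD score regression at desk scale.

Under a polygenic model in which the causal-effect variance of SNP j is
the sum of coefficients tau_c over the annotations containing j, the
expected GWAS association statistic follows

    E[chi2_j] = 1 + N * sum_c tau_c * l(j, c),

where N is the GWAS sample size and l(j, c) is the stratified LD score
of SNP j with annotation c: the sum of squared genotype correlations
between j and every SNP of c within a genetic-distance window
(1 centimorgan by default).  Regressing chi2 on the annotation LD
scores with a free intercept yields per-annotation coefficients tau_c;
these partition SNP heritability, and the heritability enrichment of an
annotation is its share of h2 divided by its share of SNPs.

Standard errors come from a delete-one block jackknife over contiguous
SNP blocks (200 by default), which respects local LD dependence;
significance uses a Wald statistic against tau = 0 (or enrichment = 1)
and Benjamini-Hochberg FDR across the tested grid.

The r^2 estimator is bias-adjusted for reference-panel size:
r2_adj = r2 - (1 - r2) / (n - 2), which is unbiased to first order
under independence, so LD scores of unlinked SNPs average to ~1 (their
own term) instead of inflating with panel noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

BASE = "base"  # conventional name of the all-SNPs annotation column


# ---------------------------------------------------------------------------
# LD scores

def compute_ld_scores(
    genotypes: np.ndarray,
    cm: np.ndarray,
    annotations: pd.DataFrame,
    window_cm: float = 1.0,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Stratified LD scores from a reference genotype panel.

    Parameters
    ----------
    genotypes
        (n individuals, m SNPs) dosage matrix, SNPs ordered along the
        genome.
    cm
        Genetic-map position of each SNP in centimorgans, nondecreasing.
    annotations
        (m, C) 0/1 DataFrame, one column per annotation (include an
        all-SNPs ``base`` column for regression use).
    window_cm
        Pairs farther apart than this are treated as unlinked.  A window
        of 0 keeps only each SNP's own term.
    adjusted
        Apply the small-sample adjustment r2 - (1-r2)/(n-2).

    Monomorphic SNPs cannot be standardized; they are excluded from all
    pair sums with a warning and receive NaN scores.
    """
    X = np.asarray(genotypes, dtype=np.float64)
    n, m = X.shape
    cm = np.asarray(cm, dtype=np.float64)
    if cm.shape != (m,):
        raise ValueError("cm must have one entry per SNP")
    if np.any(np.diff(cm) < 0):
        raise ValueError("cm positions must be nondecreasing")
    if list(annotations.index) != list(range(m)) and len(annotations) != m:
        raise ValueError("annotations must have one row per SNP")
    if adjusted and n < 3:
        raise ValueError("adjusted estimator requires n >= 3")

    sd = X.std(axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(f"{mono.sum()} monomorphic SNPs excluded from LD scores", stacklevel=2)
    sd_safe = np.where(mono, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / sd_safe
    Xs[:, mono] = 0.0

    A = annotations.to_numpy(dtype=np.float64).copy()
    A[mono] = 0.0

    L = A.copy()  # own term: r2(j,j)=1, adjusted value 1 - 0/(n-2) = 1
    for d in range(1, m):
        within = (cm[d:] - cm[:-d]) <= window_cm
        if not within.any():
            break  # min gap over offset d is nondecreasing for sorted cm
        r = (Xs[:, d:] * Xs[:, :-d]).sum(axis=0) / n
        r2 = r * r
        if adjusted:
            r2 = r2 - (1.0 - r2) / (n - 2)
        v = np.where(within, r2, 0.0)
        L[:-d] += v[:, None] * A[d:]
        L[d:] += v[:, None] * A[:-d]
    L[mono] = np.nan
    return pd.DataFrame(L, columns=annotations.columns)


# ---------------------------------------------------------------------------
# Regression

@dataclass
class SldscFit:
    """Fitted stratified regression: tau per annotation plus intercept."""

    tau: pd.Series
    intercept: float
    columns: tuple[str, ...]
    design: np.ndarray = field(repr=False)  # (m, 1+C): intercept col first
    y: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name near-duplicate column pairs to aid diagnosis
        sd = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if sd[i] > 0 and sd[j] > 0 and abs(C[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {pairs}")


def _proxy_weights(chi2: np.ndarray, n_eff: np.ndarray, l_total: np.ndarray, m: int) -> np.ndarray:
    # heteroskedasticity proxy: Var(chi2_j) ~ 2 * E[chi2_j]^2 with
    # E[chi2_j] approximated via an aggregate h2 estimate
    denom = float(np.mean(n_eff * l_total))
    h2_agg = 0.0 if denom <= 0 else (np.mean(chi2) - 1.0) * m / denom
    h2_agg = float(np.clip(h2_agg, 0.0, 1.0))
    mean_chi2 = 1.0 + n_eff * l_total * h2_agg / m
    return 1.0 / (2.0 * mean_chi2**2)


def stratified_regression(
    chi2: np.ndarray,
    ldscores: pd.DataFrame,
    n_samples: float | np.ndarray,
    weights: str | np.ndarray = "proxy",
) -> SldscFit:
    """Weighted least squares of chi2 on N-scaled annotation LD scores.

    The model is chi2_j = intercept + sum_c tau_c * N_j * l(j,c); the
    intercept is free (its deviation from 1 absorbs confounding).
    ``weights='proxy'`` uses the inverse squared predicted mean of chi2
    (a heteroskedasticity proxy seeded by an aggregate h2 estimate);
    ``'none'`` is unweighted; an array gives explicit weights.
    """
    chi2 = np.asarray(chi2, dtype=np.float64)
    m = len(chi2)
    cols = tuple(ldscores.columns)
    if len(cols) < 1:
        raise ValueError("need at least one annotation column")
    L = ldscores.to_numpy(dtype=np.float64)
    if L.shape[0] != m:
        raise ValueError("ldscores and chi2 differ in length")
    if np.isnan(L).any():
        raise ValueError("NaN LD scores; drop monomorphic SNPs before regression")
    n_eff = np.broadcast_to(np.asarray(n_samples, dtype=np.float64), (m,))
    X = np.column_stack([np.ones(m), n_eff[:, None] * L])
    _check_full_rank(X, ("intercept", *cols))

    if isinstance(weights, str) and weights == "proxy":
        l_total = L[:, cols.index(BASE)] if BASE in cols else L.sum(axis=1)
        w = _proxy_weights(chi2, n_eff, np.maximum(l_total, 1.0), m)
    elif isinstance(weights, str) and weights == "none":
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (m,) or np.any(w <= 0):
            raise ValueError("explicit weights must be positive, one per SNP")

    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], chi2 * sw, rcond=None)
    return SldscFit(
        tau=pd.Series(beta[1:], index=list(cols), name="tau"),
        intercept=float(beta[0]),
        columns=cols,
        design=X,
        y=chi2,
        weights=w,
    )


# ---------------------------------------------------------------------------
# Partitioning and enrichment

def partition_and_enrich(
    tau: pd.Series | np.ndarray, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Partition heritability across annotations and compute enrichment.

    Per-SNP heritability is sigma2_j = sum_c tau_c a_jc; an annotation's
    h2 is the sum of sigma2_j over its member SNPs (overlapping
    annotations double-count by design, as in the standard partitioned
    model).  Enrichment = (h2 share) / (SNP share).  Negative tau can
    produce negative h2 shares; they are reported untruncated.
    """
    A = annotations.to_numpy(dtype=np.float64)
    tau_v = np.asarray(tau, dtype=np.float64)
    if A.shape[1] != len(tau_v):
        raise ValueError("tau and annotation columns differ")
    m = A.shape[0]
    m_c = A.sum(axis=0)
    if np.any(m_c == 0):
        empty = [c for c, n in zip(annotations.columns, m_c) if n == 0]
        raise ValueError(f"annotations with no SNPs have undefined enrichment: {empty}")
    per_snp = A @ tau_v
    h2_total = float(per_snp.sum())
    h2_c = A.T @ per_snp
    snp_share = m_c / m
    h2_share = h2_c / h2_total if h2_total != 0 else np.full_like(h2_c, np.nan)
    return pd.DataFrame(
        {
            "M_c": m_c.astype(np.int64),
            "snp_share": snp_share,
            "h2_c": h2_c,
            "h2_share": h2_share,
            "enrichment": h2_share / snp_share,
        },
        index=annotations.columns,
    )


# ---------------------------------------------------------------------------
# Jackknife

def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if n_blocks > m:
        raise ValueError("more jackknife blocks than SNPs")
    return np.linspace(0, m, n_blocks + 1).round().astype(int)


def delete_block_estimates(fit: SldscFit, n_blocks: int = 200) -> np.ndarray:
    """Delete-one-block WLS estimates of (intercept, tau) — (g, 1+C) array."""
    X, y, w = fit.design, fit.y, fit.weights
    m, p = X.shape
    bounds = _block_bounds(m, n_blocks)
    Xw = X * w[:, None]
    A_full = Xw.T @ X
    b_full = Xw.T @ y
    out = np.empty((n_blocks, p))
    for g in range(n_blocks):
        s, e = bounds[g], bounds[g + 1]
        A_g = (X[s:e] * w[s:e, None]).T @ X[s:e]
        b_g = (X[s:e] * w[s:e, None]).T @ y[s:e]
        out[g] = np.linalg.solve(A_full - A_g, b_full - b_g)
    return out


def jackknife_se(delete_values: np.ndarray) -> np.ndarray:
    """Delete-one jackknife SE from a (g, ...) array of leave-block stats."""
    dv = np.asarray(delete_values, dtype=np.float64)
    g = dv.shape[0]
    if g < 2:
        raise ValueError("need at least 2 delete-block values")
    mean = dv.mean(axis=0)
    return np.sqrt((g - 1) / g * ((dv - mean) ** 2).sum(axis=0))


def wald_p(estimate: np.ndarray, se: np.ndarray, null: float = 0.0) -> np.ndarray:
    """Two-sided normal-approximation p-value; p = 1 when estimate == null."""
    estimate = np.asarray(estimate, dtype=np.float64)
    se = np.asarray(se, dtype=np.float64)
    at_null = np.isclose(estimate, null, rtol=0.0, atol=1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(at_null, 0.0, (estimate - null) / se)
    return 2.0 * stats.norm.sf(np.abs(z))


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level q."""
    p = np.asarray(pvalues, dtype=np.float64)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# High-level driver

def enrichment_analysis(
    chi2: np.ndarray,
    ldscores: pd.DataFrame,
    annotations: pd.DataFrame,
    n_samples: float | np.ndarray,
    weights: str | np.ndarray = "proxy",
    n_blocks: int = 200,
) -> pd.DataFrame:
    """Full stratified analysis: tau, h2 partition, jackknife SE, Wald p.

    Returns one row per annotation with tau and its SE/p (against 0),
    SNP and h2 shares, and enrichment with its SE/p (against 1).  The
    fitted intercept and total h2 are exposed via ``DataFrame.attrs``.
    """
    fit = stratified_regression(chi2, ldscores, n_samples, weights=weights)
    base_part = partition_and_enrich(fit.tau, annotations)

    dels = delete_block_estimates(fit, n_blocks=n_blocks)
    tau_se = jackknife_se(dels[:, 1:])
    enr_dels = np.stack(
        [
            partition_and_enrich(dels[g, 1:], annotations)["enrichment"].to_numpy()
            for g in range(dels.shape[0])
        ]
    )
    enr_se = jackknife_se(enr_dels)

    out = base_part.copy()
    out["tau"] = fit.tau
    out["tau_se"] = tau_se
    out["tau_p"] = wald_p(fit.tau.to_numpy(), tau_se, null=0.0)
    out["enrichment_se"] = enr_se
    out["enrichment_p"] = wald_p(out["enrichment"].to_numpy(), enr_se, null=1.0)
    out.attrs["intercept"] = fit.intercept
    out.attrs["h2_total"] = float(
        (annotations.to_numpy(dtype=np.float64) @ fit.tau.to_numpy()).sum()
    )
    return out


# ---------------------------------------------------------------------------
# File dialects (LDSC-compatible, text or gzip by extension)

def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited sumstats file (SNP A1 A2 N Z)."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in ("SNP", "N", "Z") if c not in df.columns]
    if missing:
        raise ValueError(f"sumstats file lacks columns: {missing}")
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_ldscore(
    panel: pd.DataFrame, ldscores: pd.DataFrame, path: str | Path
) -> None:
    """Write an ``.l2.ldscore``-style table: CHR SNP BP + one column per annotation."""
    out = pd.DataFrame(
        {"CHR": panel["chrom"].values, "SNP": panel["snp"].values, "BP": panel["pos"].values}
    )
    for col in ldscores.columns:
        out[f"{col}L2"] = ldscores[col].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_ldscore(path: str | Path) -> pd.DataFrame:
    """Read an ``.l2.ldscore``-style table; strips the ``L2`` column suffix."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    scores = df[[c for c in df.columns if c.endswith("L2")]].copy()
    scores.columns = [c[:-2] for c in scores.columns]
    scores.index = df.index
    for c in ("CHR", "SNP", "BP"):
        scores.attrs[c] = df[c].tolist() if c in df.columns else None
    scores.insert(0, "SNP", df["SNP"])
    return scores
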