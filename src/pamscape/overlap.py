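"""Annotation overlap odds ratios, Fisher-Z correlations, off-target matching.

Two binary SNP annotations define a 2x2 contingency table; the odds
ratio of joint membership, its log, and an exact two-sided p-value
quantify whether SNPs inside one annotation (e.g. a Cas-enriched region
set) are over-represented inside another (e.g. coding regions or
histone marks).  A matrix of such tests across annotation pairs gives
the overlap heat map.

Pearson correlations are tested with the Fisher Z transform:
z = atanh(r) * sqrt(n - 3) against a standard normal.

Off-target cleavage sites are matched to genome segments by interval
membership, yielding per-segment site counts and mean cleavage
frequencies for correlation against PAM density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import GenomeConcat


@dataclass(frozen=True)
class FisherOR:
    """Result of a 2x2 Fisher exact test on two binary annotations.

    ``odds_ratio`` is the sample cross-product (a*d)/(b*c); a zero in
    b or c makes it infinite (``degenerate`` flag set), a zero in a or
    d makes it 0.  ``log_or`` is the natural log.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    log_or: float
    p: float
    degenerate: bool = False

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_or_table(a: int, b: int, c: int, d: int, conditional: bool = False) -> FisherOR:
    """Fisher exact test from explicit 2x2 cell counts.

    The default odds ratio is the unconditional sample cross-product;
    ``conditional=True`` reports the conditional maximum-likelihood OR
    instead.  The p-value is the exact two-sided hypergeometric tail
    (all tables with probability <= the observed), in either case.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    table = [[a, b], [c, d]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    degenerate = (b == 0 or c == 0 or a == 0 or d == 0)
    if conditional:
        or_ = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    elif b == 0 or c == 0:
        or_ = math.inf if a * d > 0 else math.nan
    else:
        or_ = (a * d) / (b * c)
    log_or = math.log(or_) if or_ > 0 else (-math.inf if or_ == 0 else math.nan)
    if math.isinf(or_):
        log_or = math.inf
    return FisherOR(a, b, c, d, float(or_), float(log_or), float(p), degenerate)


def fisher_or(annot_a: np.ndarray, annot_b: np.ndarray, conditional: bool = False) -> FisherOR:
    """Fisher exact overlap test between two aligned binary annotations."""
    x = np.asarray(annot_a).astype(bool)
    y = np.asarray(annot_b).astype(bool)
    if x.shape != y.shape:
        raise ValueError("annotations differ in length")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    return fisher_or_table(a, b, c, d, conditional=conditional)


def or_matrix(
    row_annots: pd.DataFrame, col_annots: pd.DataFrame, conditional: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log(OR) and p matrices between two annotation sets on one panel.

    Rows/columns follow the input column order (e.g. Cas annotations as
    rows, functional annotations as columns).
    """
    if len(row_annots) != len(col_annots):
        raise ValueError("annotation sets are aligned to different panels")
    log_or = pd.DataFrame(
        index=row_annots.columns, columns=col_annots.columns, dtype=float
    )
    pvals = log_or.copy()
    for rc in row_annots.columns:
        for cc in col_annots.columns:
            res = fisher_or(row_annots[rc].to_numpy(), col_annots[cc].to_numpy(),
                            conditional=conditional)
            log_or.loc[rc, cc] = res.log_or
            pvals.loc[rc, cc] = res.p
    return log_or, pvals


def pearson_fisher_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided Fisher-Z p-value.

    Requires n >= 4 and non-constant vectors.  At |r| = 1 the Z
    statistic diverges and p is reported as 0.0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    n = len(x)
    if n < 4:
        raise ValueError("Fisher-Z test requires n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    z = math.atanh(r) * math.sqrt(n - 3)
    return r, float(2.0 * stats.norm.sf(abs(z)))


def read_offtargets(path: str | Path) -> pd.DataFrame:
    """Read an off-target site table: chrom, pos (1-based), frequency[, study]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "frequency") if c not in df.columns]
    if missing:
        raise ValueError(f"off-target table lacks columns: {missing}")
    bad = (df["frequency"] < 0) | (df["frequency"] > 1)
    if bad.any():
        raise ValueError(f"{bad.sum()} cleavage frequencies outside [0, 1]")
    return df


def offtargets_to_segments(
    sites: pd.DataFrame, concat: GenomeConcat, plan: np.ndarray
) -> tuple[pd.DataFrame, int]:
    """Match off-target sites to segments by half-open interval membership.

    Returns a per-segment DataFrame (``n_sites``, ``mean_frequency``,
    NaN where no site maps) plus the number of sites dropped because
    their coordinates fall outside the segmentation.
    """
    plan = np.asarray(plan)
    offs = concat.offsets
    lengths = dict(zip(concat.chromosomes, concat.lengths))
    n_seg = len(plan)
    counts = np.zeros(n_seg, dtype=np.int64)
    freq_sum = np.zeros(n_seg)
    dropped = 0
    for chrom, pos, freq in zip(
        sites["chrom"].astype(str), sites["pos"].astype(int), sites["frequency"]
    ):
        if chrom not in offs or not 1 <= pos <= lengths[chrom]:
            dropped += 1
            continue
        cpos = offs[chrom] + pos - 1
        idx = int(np.searchsorted(plan[:, 0], cpos, side="right")) - 1
        if idx < 0 or cpos >= plan[idx, 1]:
            dropped += 1
            continue
        counts[idx] += 1
        freq_sum[idx] += freq
    if dropped:
        warnings.warn(f"{dropped} off-target sites outside the segmentation dropped",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        mean_freq = np.where(counts > 0, freq_sum / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame({"n_sites": counts, "mean_frequency": mean_freq})
    out.index.name = "segment"
    return out, dropped
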