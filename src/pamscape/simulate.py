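"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its spec plus a seed, so reruns
are byte-identical.  The generators emulate the features the analysis
actually exercises:

* a genome with spatially structured GC content, N-runs, and motifs
  planted at controlled density (so PAM-enriched and GC-rich segments
  exist and partly coincide);
* LD-structured diploid genotypes: haplotypes drawn from a Gaussian
  threshold model with equicorrelated latent variables inside fixed-size
  LD blocks, giving tunable within-block r2 and independence between
  blocks, plus a uniform-rate genetic map (default 1 cM/Mb);
* GWAS summary statistics following E[chi2_j] = 1 + N sum_c tau_c l(j,c),
  either drawn directly at the model level (fast) or produced by an
  actual phenotype regression on the genotype panel (slower, validates
  the whole chain);
* functional annotations whose SNP membership probability is logistic
  in segment GC content, and off-target sites sampled proportionally to
  a power of per-segment PAM counts.

None of this reproduces human demography, real recombination maps, or
real functional genomics; it reproduces the moments the estimators
consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import expand_iupac
from .segmentation import GenomeConcat

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Genome

@dataclass(frozen=True)
class GenomeSpec:
    """Layout of a synthetic genome.

    ``gc_blocks`` override the background GC inside (chrom, start, end)
    intervals (0-based half-open).  ``n_runs`` are hard-masked intervals
    (applied last: N wins over planted motifs, with a warning).
    ``motif_blocks`` plant a motif at an expected per-base density
    inside an interval; degenerate motifs are concretized per instance.
    """

    chrom_lengths: Mapping[str, int]
    background_gc: float = 0.41
    gc_blocks: tuple[tuple[str, int, int, float], ...] = ()
    n_runs: tuple[tuple[str, int, int], ...] = ()
    motif_blocks: tuple[tuple[str, str, int, int, float], ...] = ()  # motif, chrom, start, end, density
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, start, end, gc in self.gc_blocks:
            self._check_interval(chrom, start, end)
            if not 0.0 <= gc <= 1.0:
                raise ValueError(f"target GC {gc} outside [0, 1]")
        for chrom, start, end in self.n_runs:
            self._check_interval(chrom, start, end)
        for _, chrom, start, end, dens in self.motif_blocks:
            self._check_interval(chrom, start, end)
            if dens < 0:
                raise ValueError("motif density must be non-negative")

    def _check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_lengths:
            raise ValueError(f"interval on unknown chromosome {chrom!r}")
        if not 0 <= start < end <= self.chrom_lengths[chrom]:
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")


def _draw_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def generate_genome(spec: GenomeSpec) -> dict[str, str]:
    """Generate chromosome sequences according to a :class:`GenomeSpec`."""
    rng = np.random.default_rng(spec.seed)
    out: dict[str, str] = {}
    for chrom in spec.chrom_lengths:
        length = spec.chrom_lengths[chrom]
        seq = _draw_bases(rng, length, spec.background_gc)
        for c, start, end, gc in spec.gc_blocks:
            if c == chrom:
                seq[start:end] = _draw_bases(rng, end - start, gc)
        motif_positions: list[tuple[int, int]] = []
        for motif, c, start, end, density in spec.motif_blocks:
            if c != chrom:
                continue
            k = len(motif)
            n_sites = rng.poisson(density * (end - start))
            concrete = sorted(expand_iupac(motif))
            for pos in rng.integers(start, max(start + 1, end - k + 1), size=n_sites):
                inst = concrete[rng.integers(len(concrete))]
                seq[pos : pos + k] = np.frombuffer(inst.encode(), dtype="S1")
                motif_positions.append((int(pos), int(pos) + k))
        for c, start, end in spec.n_runs:
            if c == chrom:
                if any(s < end and start < e for s, e in motif_positions):
                    warnings.warn(
                        f"N-run {chrom}:{start}-{end} overwrites planted motifs",
                        stacklevel=2,
                    )
                seq[start:end] = np.frombuffer(b"N", dtype="S1")
        out[chrom] = seq.tobytes().decode()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write chromosome sequences as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Genotypes

@dataclass(frozen=True)
class SimSpec:
    """Genotype-panel simulation parameters.

    ``rho`` is the latent equicorrelation within LD blocks of
    ``block_size`` consecutive SNPs (blocks are mutually independent).
    SNP positions are uniform over [1, ``length``] on one chromosome and
    the genetic map is uniform at ``cm_per_mb``.
    """

    n: int
    m: int
    block_size: int = 50
    rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"
    length: int | None = None
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n < 2 or self.m < 1 or self.block_size < 1:
            raise ValueError("n >= 2, m >= 1, block_size >= 1 required")


def generate_genotypes(spec: SimSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Blockwise-correlated diploid genotypes plus a SNP panel table.

    Haplotype alleles arise from thresholding equicorrelated Gaussian
    latents at the normal quantile of each SNP's allele frequency, so
    each SNP has its target MAF in expectation and within-block LD
    increases with ``rho``.  Returns (genotypes (n, m) int8 dosages,
    panel DataFrame with snp/chrom/pos/a1/a2/maf/cm).
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.length if spec.length is not None else spec.m * 150
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=spec.m, replace=False))
    maf = rng.uniform(*spec.maf_range, size=spec.m)
    thresh = stats.norm.ppf(maf)

    n_hap = 2 * spec.n
    hap = np.empty((n_hap, spec.m), dtype=np.int8)
    for start in range(0, spec.m, spec.block_size):
        s = min(spec.block_size, spec.m - start)
        shared = rng.standard_normal((n_hap, 1))
        latent = np.sqrt(spec.rho) * shared + np.sqrt(1 - spec.rho) * rng.standard_normal(
            (n_hap, s)
        )
        hap[:, start : start + s] = latent < thresh[start : start + s]
    X = hap[: spec.n] + hap[spec.n :]

    panel = pd.DataFrame(
        {
            "snp": [f"snp{i:07d}" for i in range(spec.m)],
            "chrom": spec.chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "maf": maf,
            "cm": pos / 1e6 * spec.cm_per_mb,
        }
    )
    return X, panel


# ---------------------------------------------------------------------------
# Summary statistics

def tau_from_enrichment(
    annotations: pd.DataFrame,
    target_enrichment: Mapping[str, float],
    h2: float,
    base: str = "base",
) -> pd.Series:
    """Per-annotation variance coefficients realizing target enrichments.

    Targeted annotations must be mutually disjoint.  With SNP share p
    and target enrichment E, annotated SNPs get per-SNP variance
    E*h2/M; the remaining SNPs share the rest uniformly, so the
    realized h2 share is exactly E*p.
    """
    A = annotations.to_numpy(dtype=np.float64)
    m = A.shape[0]
    cols = list(annotations.columns)
    if base not in cols:
        raise ValueError(f"annotations must include the all-SNPs column {base!r}")
    targeted = [c for c in target_enrichment if c != base]
    for c in targeted:
        if c not in cols:
            raise ValueError(f"unknown annotation {c!r} in target_enrichment")
    T = annotations[targeted].to_numpy(dtype=np.float64) if targeted else np.zeros((m, 0))
    if targeted and (T.sum(axis=1) > 1).any():
        raise ValueError("target_enrichment requires disjoint annotations")
    shares = T.sum(axis=0) / m
    evals = np.array([target_enrichment[c] for c in targeted])
    committed = float((evals * shares).sum())
    if committed > 1.0:
        raise ValueError("target enrichments commit more than 100% of h2")
    m_rest = m - T.sum()
    tau = pd.Series(0.0, index=cols)
    tau[base] = (1.0 - committed) * h2 / m_rest if m_rest > 0 else 0.0
    for c, e in zip(targeted, evals):
        tau[c] = e * h2 / m - tau[base]
    return tau


def simulate_sumstats(
    panel: pd.DataFrame,
    annotations: pd.DataFrame,
    n_gwas: int,
    tau: pd.Series | Mapping[str, float] | None = None,
    target_enrichment: Mapping[str, float] | None = None,
    h2: float = 0.5,
    mode: str = "model",
    ldscores: pd.DataFrame | None = None,
    genotypes: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate GWAS summary statistics under the stratified model.

    Exactly one of ``tau`` / ``target_enrichment`` may be given (neither
    means a fully null trait).  ``mode='model'`` draws
    Z_j ~ Normal(0, sqrt(1 + N sum_c tau_c l(j,c))) from supplied LD
    scores — fast and exactly calibrated to the regression model.
    ``mode='genotype'`` draws causal effects per SNP, builds phenotypes
    on the genotype panel, and computes marginal association Z scores;
    the panel size then caps the effective GWAS N.

    Returns (sumstats DataFrame with SNP A1 A2 N Z, realized tau).
    """
    if tau is not None and target_enrichment is not None:
        raise ValueError("give either tau or target_enrichment, not both")
    cols = list(annotations.columns)
    if target_enrichment is not None:
        tau_v = tau_from_enrichment(annotations, target_enrichment, h2)
    elif tau is not None:
        tau_v = pd.Series(tau).reindex(cols).fillna(0.0)
    else:
        tau_v = pd.Series(0.0, index=cols)
    if mode == "genotype" and (tau_v < 0).any():
        raise ValueError("genotype-level simulation requires non-negative tau")

    rng = np.random.default_rng(seed)
    m = len(panel)
    if mode == "model":
        if ldscores is None:
            raise ValueError("model-level simulation needs LD scores")
        ell = ldscores[cols].to_numpy(dtype=np.float64)
        var = 1.0 + n_gwas * ell @ tau_v.to_numpy()
        if (var <= 0).any():
            raise ValueError("negative chi2 expectation; tau too negative")
        z = rng.standard_normal(m) * np.sqrt(var)
        n_out = np.full(m, n_gwas)
    elif mode == "genotype":
        if genotypes is None:
            raise ValueError("genotype-level simulation needs a genotype panel")
        X = np.asarray(genotypes, dtype=np.float64)
        n = X.shape[0]
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
        per_snp = annotations.to_numpy(dtype=np.float64) @ tau_v.to_numpy()
        beta = rng.standard_normal(m) * np.sqrt(per_snp)
        g = Xs @ beta
        e = rng.standard_normal(n) * np.sqrt(max(1.0 - per_snp.sum(), 1e-12))
        y = g + e
        ys = (y - y.mean()) / y.std()
        z = (Xs.T @ ys) / np.sqrt(n)
        n_out = np.full(m, n)
    else:
        raise ValueError("mode must be 'model' or 'genotype'")

    sumstats = pd.DataFrame(
        {"SNP": panel["snp"].values, "A1": panel["a1"].values, "A2": panel["a2"].values,
         "N": n_out, "Z": z}
    )
    return sumstats, tau_v


# ---------------------------------------------------------------------------
# Functional annotations and off-target sites

def generate_functional_annotations(
    snp_gc: np.ndarray,
    slopes: Mapping[str, float],
    prevalence: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary annotations whose membership is logistic in segment GC.

    ``snp_gc`` is the GC content of each SNP's segment.  For slope b,
    P(member) = sigmoid(logit(prevalence) + b * zscore(gc)); slope 0
    gives GC-independent membership at the target prevalence.
    """
    gc = np.asarray(snp_gc, dtype=np.float64)
    sd = gc.std()
    zgc = (gc - gc.mean()) / sd if sd > 0 else np.zeros_like(gc)
    alpha = np.log(prevalence / (1 - prevalence))
    rng = np.random.default_rng(seed)
    out = {}
    for name, slope in slopes.items():
        if not np.isfinite(slope):
            raise ValueError(f"slope for {name!r} must be finite")
        p = 1.0 / (1.0 + np.exp(-(alpha + slope * zgc)))
        out[name] = (rng.random(len(gc)) < p).astype(np.int8)
    return pd.DataFrame(out)


def generate_offtarget_sites(
    concat: GenomeConcat,
    plan: np.ndarray,
    pam_counts: np.ndarray,
    coupling: float = 1.0,
    n_sites: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Off-target sites sampled across segments with PAM-count coupling.

    Each site's segment is drawn with probability proportional to
    (count)^coupling (coupling 0 = uniform); its position is uniform
    within the segment and its cleavage frequency is drawn independently
    of PAM content (Beta(1.5, 20), small values typical of measured
    cleavage rates).  All-zero counts with positive coupling fall back
    to uniform sampling with a warning.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    plan = np.asarray(plan)
    counts = np.asarray(pam_counts, dtype=np.float64)
    if len(counts) != len(plan):
        raise ValueError("pam_counts and segment plan differ in length")
    if coupling == 0.0:
        weights = np.ones(len(counts))
    else:
        weights = np.power(counts, coupling, where=counts > 0,
                           out=np.zeros_like(counts))
    if weights.sum() == 0:
        warnings.warn("all segment weights zero; sampling uniformly", stacklevel=2)
        weights = np.ones(len(counts))
    rng = np.random.default_rng(seed)
    seg = rng.choice(len(plan), size=n_sites, p=weights / weights.sum())
    cpos = plan[seg, 0] + rng.integers(0, plan[seg, 1] - plan[seg, 0])
    rows = []
    for s, cp in zip(seg, cpos):
        chrom, p0 = concat.to_chrom(int(cp))
        rows.append(
            {"chrom": chrom, "pos": p0 + 1, "frequency": float(rng.beta(1.5, 20.0)),
             "study": "synthetic", "segment": int(s)}
        )
    return pd.DataFrame(rows)
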