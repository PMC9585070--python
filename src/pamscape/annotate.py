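"""SNP panels, region-membership annotations, and annotation I/O.

A binary annotation marks each SNP of a panel 1 if its position falls
inside a selected genome segment (half-open interval in concatenated
coordinates) and 0 otherwise.  Panels are read from PLINK BIM files,
sites-only VCF, or plain TSV; annotations are written in the LDSC
``.annot`` dialect (CHR, BP, SNP, CM, one 0/1 column per annotation),
BED, or TSV.

Standard filters for LD score regression are provided: MAF strictly
above a threshold, exclusion of the MHC region (whose long-range LD
distorts heritability partitioning), and restriction to a keep-list
such as the HapMap3 SNPs.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .landscape import RegionSet
from .segmentation import GenomeConcat

#: GRCh37 MHC interval conventionally excluded from LDSC analyses
#: (chr6:25-34 Mb, 1-based inclusive).
MHC_GRCH37 = ("6", 25_000_000, 34_000_000)

PANEL_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf", "cm"]


def read_bim(path: str | Path) -> pd.DataFrame:
    """Read a PLINK BIM file into a panel DataFrame (MAF column is NaN)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    df["maf"] = np.nan
    return df[PANEL_COLUMNS]


def read_vcf_sites(path: str | Path) -> pd.DataFrame:
    """Read SNP positions from a (sites-only) VCF.

    MAF is taken from the INFO AF field when present (folded to the
    minor allele), else NaN; the cM column is NaN.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if af is not None:
                af = af[0] if isinstance(af, (tuple, list)) else float(af)
                maf = min(af, 1.0 - af)
            else:
                maf = np.nan
            rows.append(
                {
                    "snp": rec.id or f"{rec.chrom}:{rec.pos}",
                    "chrom": str(rec.chrom),
                    "pos": rec.pos,  # pysam exposes 1-based position
                    "a1": rec.alts[0] if rec.alts else ".",
                    "a2": rec.ref,
                    "maf": maf,
                    "cm": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def read_panel_tsv(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated panel with a header naming the standard columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("snp", "chrom", "pos") if c not in df.columns]
    if missing:
        raise ValueError(f"panel file lacks required columns: {missing}")
    for col in PANEL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[PANEL_COLUMNS]


def map_to_segments(
    panel: pd.DataFrame, concat: GenomeConcat, plan: np.ndarray
) -> np.ndarray:
    """Segment index of each SNP; -1 for SNPs off the segmentation.

    SNP positions are 1-based (VCF/BIM convention) and are converted to
    0-based concatenated coordinates; segment intervals are half-open,
    so a SNP at a segment's end coordinate belongs to the next segment.
    """
    plan = np.asarray(plan)
    offs = concat.offsets
    lengths = dict(zip(concat.chromosomes, concat.lengths))
    seg = np.full(len(panel), -1, dtype=np.int64)
    cpos = np.full(len(panel), -1, dtype=np.int64)
    chroms = panel["chrom"].astype(str).to_numpy()
    pos0 = panel["pos"].to_numpy(dtype=np.int64) - 1
    for i, (chrom, p) in enumerate(zip(chroms, pos0)):
        if chrom in offs and 0 <= p < lengths[chrom]:
            cpos[i] = offs[chrom] + p
    ok = cpos >= 0
    idx = np.searchsorted(plan[:, 0], cpos[ok], side="right") - 1
    inside = (idx >= 0) & (cpos[ok] < plan[idx.clip(0), 1])
    seg_ok = np.where(inside, idx, -1)
    seg[ok] = seg_ok
    return seg


def annotate_snps(
    panel: pd.DataFrame,
    regions: RegionSet,
    concat: GenomeConcat,
    plan: np.ndarray,
    on_unmapped: str = "error",
) -> pd.Series:
    """Binary membership of each SNP in a region set.

    A SNP is annotated 1 iff its position falls inside the half-open
    interval of a selected segment.  SNPs on chromosomes absent from the
    segmentation either raise (``on_unmapped='error'``, default) or get
    0 with a warning (``'zero'``).
    """
    seg = map_to_segments(panel, concat, plan)
    unmapped = seg < 0
    if unmapped.any():
        if on_unmapped == "error":
            bad = panel.loc[unmapped, "snp"].head(5).tolist()
            raise ValueError(
                f"{unmapped.sum()} SNPs not mappable to the segmentation (e.g. {bad})"
            )
        warnings.warn(f"{unmapped.sum()} unmappable SNPs annotated 0", stacklevel=2)
    member = np.isin(seg, np.fromiter(regions.as_set(), dtype=np.int64, count=len(regions.indices)))
    name = regions.label or "annot"
    return pd.Series(member.astype(np.int8), index=panel.index, name=name)


def apply_snp_filters(
    panel: pd.DataFrame,
    maf_min: float = 0.05,
    exclude: Sequence[tuple[str, int, int]] = (MHC_GRCH37,),
    keep_list: set[str] | None = None,
) -> pd.DataFrame:
    """Filter a panel for LD score regression.

    Keeps SNPs with MAF strictly above ``maf_min`` (a SNP at exactly the
    threshold is removed), drops SNPs inside any excluded region
    (1-based inclusive intervals; default the GRCh37 MHC), and
    intersects with ``keep_list`` identifiers when given.
    """
    keep = panel["maf"].to_numpy() > maf_min
    pos = panel["pos"].to_numpy()
    chrom = panel["chrom"].astype(str).to_numpy()
    for ex_chrom, start, end in exclude:
        keep &= ~((chrom == str(ex_chrom)) & (pos >= start) & (pos <= end))
    if keep_list is not None:
        if len(keep_list) == 0:
            warnings.warn("empty keep_list: all SNPs removed", stacklevel=2)
        keep &= panel["snp"].isin(keep_list).to_numpy()
    return panel.loc[keep].reset_index(drop=True)


def write_annotation(
    panel: pd.DataFrame,
    annotations: pd.DataFrame | pd.Series,
    path: str | Path,
    fmt: str = "ldsc-annot",
) -> None:
    """Write binary annotations aligned to a panel.

    ``ldsc-annot``: CHR BP SNP CM plus one 0/1 column per annotation,
    tab-separated, gzip-compressed when the path ends in ``.gz``.
    ``tsv``: same including MAF.  ``bed``: one single-base interval per
    annotated SNP per annotation (column ``name`` holds the annotation).
    """
    annots = annotations.to_frame() if isinstance(annotations, pd.Series) else annotations
    if len(annots) != len(panel):
        raise ValueError("annotation length does not match panel size")
    if fmt == "ldsc-annot":
        out = pd.DataFrame(
            {"CHR": panel["chrom"].values, "BP": panel["pos"].values,
             "SNP": panel["snp"].values, "CM": panel["cm"].values}
        )
        for col in annots.columns:
            out[col] = annots[col].to_numpy(dtype=np.int8)
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "tsv":
        out = panel.copy()
        for col in annots.columns:
            out[col] = annots[col].to_numpy(dtype=np.int8)
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        rows = []
        for col in annots.columns:
            hit = annots[col].to_numpy().astype(bool)
            for chrom, pos in zip(panel.loc[hit, "chrom"], panel.loc[hit, "pos"]):
                rows.append((chrom, pos - 1, pos, col))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
            path, sep="\t", index=False, header=False
        )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


def read_annotation(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an ``ldsc-annot`` file back into (panel, annotations)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    meta = ["CHR", "BP", "SNP", "CM"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"not an annot file, missing columns: {missing}")
    panel = pd.DataFrame(
        {"snp": df["SNP"], "chrom": df["CHR"], "pos": df["BP"],
         "a1": ".", "a2": ".", "maf": np.nan, "cm": df["CM"]}
    )
    return panel, df.drop(columns=meta)
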