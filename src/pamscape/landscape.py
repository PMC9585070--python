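"""Per-segment PAM counting, Cas-enriched region selection, GC concordance.

Motifs are counted on both strands: a reverse-strand occurrence of a
pattern is a forward-strand occurrence of its reverse complement (NGG
sites are counted as NGG plus CCN).  Overlapping occurrences all count;
windows containing N never match.  Occurrences must lie fully within a
segment — sites straddling a segment boundary are not counted, which at
144-kb segment scale loses at most |pattern|-1 sites per boundary.

For one Cas enzyme the segment score is the number of distinct
(position, strand) windows matched by any of its ranking PAMs, so a
window matched by two PAMs of the same enzyme counts once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .registry import CasEnzyme, CasRegistry, PAMPattern, PatternLike, _as_str, \
    pam_gc_content, reverse_complement_pattern


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported; classes
    # contain only concrete bases, so sequence N never matches
    body = "".join(
        ch if len(ambiguous_dna_values[ch]) == 1 else f"[{ambiguous_dna_values[ch]}]"
        for ch in pattern
    )
    return re.compile(f"(?=(?:{body}))")


def match_positions(
    sequence: str, pattern: PatternLike, strands: str = "both"
) -> set[tuple[int, str]]:
    """All (offset, strand) windows where ``pattern`` occurs.

    Offsets are 0-based window starts on the forward strand for both
    strand labels; a '-' hit at offset i means the reverse complement of
    the pattern occurs at sequence[i:i+len].  Matching is
    case-insensitive.
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    p = _as_str(pattern)
    seq = sequence.upper()
    hits = {(m.start(), "+") for m in _pattern_regex(p).finditer(seq)}
    if strands == "both":
        rc = reverse_complement_pattern(p).pattern
        hits |= {(m.start(), "-") for m in _pattern_regex(rc).finditer(seq)}
    return hits


def count_pam_per_segment(
    sequences: Iterable[str], pattern: PatternLike, strands: str = "both"
) -> np.ndarray:
    """Occurrences of one PAM in each segment sequence (both strands)."""
    return np.array(
        [len(match_positions(seq, pattern, strands)) for seq in sequences],
        dtype=np.int64,
    )


def cas_segment_counts(
    sequences: Iterable[str], cas: CasEnzyme, strands: str = "both"
) -> np.ndarray:
    """Distinct PAM windows of one Cas enzyme per segment.

    Uses the enzyme's ranking PAMs and deduplicates by (offset, strand):
    the same window matched by several PAMs counts once.
    """
    counts = []
    for seq in sequences:
        windows: set[tuple[int, str]] = set()
        for pam in cas.ranking_pams:
            windows |= match_positions(seq, pam, strands)
        counts.append(len(windows))
    return np.array(counts, dtype=np.int64)


def scan_segments(
    sequences: Iterable[str],
    patterns: Sequence[PatternLike] = (),
    enzymes: Sequence[CasEnzyme] = (),
    strands: str = "both",
) -> pd.DataFrame:
    """Single-pass count matrix: one column per PAM and per Cas enzyme.

    Each segment sequence is scanned once per unique pattern (ranking
    PAMs of the enzymes included); enzyme columns are window-set unions
    of their ranking PAMs.  Suitable for streaming over large genomes.
    """
    pam_names = [_as_str(p) for p in patterns]
    needed = dict.fromkeys(pam_names)
    for cas in enzymes:
        for pam in cas.ranking_pams:
            needed.setdefault(pam.pattern)
    rows = []
    for seq in sequences:
        sets = {p: match_positions(seq, p, strands) for p in needed}
        row = {p: len(sets[p]) for p in pam_names}
        for cas in enzymes:
            union: set[tuple[int, str]] = set()
            for pam in cas.ranking_pams:
                union |= sets[pam.pattern]
            row[cas.name] = len(union)
        rows.append(row)
    df = pd.DataFrame(rows, dtype=np.int64)
    df.index.name = "segment"
    return df


def adjust_counts(counts: np.ndarray, lengths: np.ndarray, n_bases: np.ndarray) -> np.ndarray:
    """Counts per non-N base: count / (length - N); NaN for all-N segments."""
    non_n = np.asarray(lengths, float) - np.asarray(n_bases, float)
    out = np.full(len(non_n), np.nan)
    ok = non_n > 0
    out[ok] = np.asarray(counts, float)[ok] / non_n[ok]
    return out


@dataclass(frozen=True)
class RegionSet:
    """Top-ranked segments for one annotation (e.g. one Cas enzyme)."""

    indices: tuple[int, ...]
    label: str
    k: int
    n_segments: int

    def __post_init__(self) -> None:
        if len(self.indices) > self.k:
            raise ValueError("RegionSet larger than its target size k")
        if any(i < 0 or i >= self.n_segments for i in self.indices):
            raise ValueError("segment index out of range")

    def as_set(self) -> frozenset[int]:
        return frozenset(self.indices)


def top_k_segments(
    counts: np.ndarray,
    k: int,
    eligible: np.ndarray | None = None,
    label: str = "",
) -> RegionSet:
    """The k segments with the highest counts.

    ``eligible`` masks out segments excluded from ranking (all-N
    segments).  Boundary ties are broken by ascending segment index, so
    the selection is deterministic.
    """
    counts = np.asarray(counts)
    n = len(counts)
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    idx = np.flatnonzero(np.asarray(eligible, bool))
    if k > len(idx):
        raise ValueError(f"k={k} exceeds number of eligible segments ({len(idx)})")
    # sort by (-count, index): stable deterministic tie-break
    order = idx[np.lexsort((idx, -counts[idx]))]
    return RegionSet(tuple(sorted(int(i) for i in order[:k])), label, k, n)


def gc_overlap_analysis(pam_top: RegionSet, gc_top: RegionSet) -> tuple[int, int]:
    """(overlap, non-overlap) of a PAM region set against a GC-rich set.

    Non-overlap is the number of top PAM segments absent from the top
    GC-rich segments.  Both sets must come from the same segmentation.
    """
    if pam_top.n_segments != gc_top.n_segments:
        raise ValueError("region sets come from different segmentations")
    a, b = pam_top.as_set(), gc_top.as_set()
    return len(a & b), len(a - b)


def qq_pam_vs_gc(gc: np.ndarray, pam_counts: np.ndarray) -> pd.DataFrame:
    """Paired sorted quantiles of GC and PAM content, min-max normalized.

    Both vectors are mapped to [0, 1] by min-max normalization and
    sorted independently; row i pairs the i-th quantile of each.  A
    constant vector has no normalization and raises ValueError.
    """
    gc = np.asarray(gc, float)
    pam = np.asarray(pam_counts, float)
    if gc.shape != pam.shape:
        raise ValueError("vectors differ in length")

    def _norm(v: np.ndarray, name: str) -> np.ndarray:
        lo, hi = np.nanmin(v), np.nanmax(v)
        if hi == lo:
            raise ValueError(f"{name} vector is constant; normalization degenerate")
        return (v - lo) / (hi - lo)

    return pd.DataFrame(
        {"gc_q": np.sort(_norm(gc, "gc")), "pam_q": np.sort(_norm(pam, "pam"))}
    )


def pam_gc_concordance(
    count_matrix: pd.DataFrame,
    gc: np.ndarray,
    k: int,
    eligible: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-PAM overlap of top-k PAM segments with the top-k GC-rich segments.

    ``count_matrix`` holds one column per PAM.  Returns one row per PAM
    with its GC content, overlap and non-overlap counts against the
    GC-rich top-k.  Correlating ``pam_gc`` with ``overlap`` (see
    :func:`pamscape.overlap.pearson_fisher_z`) quantifies how strongly
    GC-rich PAMs concentrate in GC-rich genome segments.
    """
    gc = np.asarray(gc, float)
    if eligible is None:
        eligible = ~np.isnan(gc)
    gc_top = top_k_segments(np.nan_to_num(gc, nan=-1.0), k, eligible, label="GC")
    rows = []
    for pam in count_matrix.columns:
        pam_top = top_k_segments(count_matrix[pam].to_numpy(), k, eligible, label=pam)
        ov, non = gc_overlap_analysis(pam_top, gc_top)
        rows.append(
            {"pam": pam, "pam_gc": pam_gc_content(pam), "overlap": ov, "non_overlap": non}
        )
    return pd.DataFrame(rows).set_index("pam")
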