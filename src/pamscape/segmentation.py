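"""Genome concatenation and fixed-count segmentation.

The analysis treats the autosomes as a single concatenated sequence and
cuts it into a fixed number of equal-length segments (the last one may
be shorter).  For GRCh37 the 22 autosomes total 2,881,033,286 bases;
cut into 20,000 segments this gives ceil-length segments of 144,052 bp.
Per-segment base composition is computed with an N-adjustment: GC
content is (G+C)/(length - N), and segments consisting entirely of N
are flagged and excluded downstream.

Coordinates are 0-based half-open throughout; 1-based positions appear
only at VCF/BIM-facing I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class GenomeConcat:
    """Map between per-chromosome and concatenated coordinates."""

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("cannot concatenate an empty chromosome list")
        if len(self.chromosomes) != len(self.lengths):
            raise ValueError("chromosomes and lengths differ in length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def offsets(self) -> dict[str, int]:
        """Start offset of each chromosome in the concatenated coordinate."""
        out, pos = {}, 0
        for chrom, length in zip(self.chromosomes, self.lengths):
            out[chrom] = pos
            pos += length
        return out

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def to_concat(self, chrom: str, pos0: int) -> int:
        """Concatenated coordinate of a 0-based per-chromosome position."""
        offs = self.offsets
        if chrom not in offs:
            raise KeyError(f"chromosome {chrom!r} not in concatenation")
        length = self.lengths[self.chromosomes.index(chrom)]
        if not 0 <= pos0 < length:
            raise ValueError(f"position {pos0} out of range for {chrom} (length {length})")
        return offs[chrom] + pos0

    def to_chrom(self, cpos: int) -> tuple[str, int]:
        """Invert :meth:`to_concat`."""
        if not 0 <= cpos < self.total_length:
            raise ValueError(f"concatenated position {cpos} out of range")
        pos = cpos
        for chrom, length in zip(self.chromosomes, self.lengths):
            if pos < length:
                return chrom, pos
            pos -= length
        raise AssertionError("unreachable")


def _default_autosomes(names: Iterable[str]) -> list[str]:
    """Pick chr1..chr22 (or 1..22) in numeric order when present.

    Falls back to all sequences in file order for non-human genomes.
    """
    names = list(names)
    available = set(names)
    for prefix in ("chr", ""):
        wanted = [f"{prefix}{i}" for i in range(1, 23)]
        if all(w in available for w in wanted):
            return wanted
    return names


def concatenate_autosomes(
    fasta: str | Path | Fasta, chromosomes: Sequence[str] | None = None
) -> GenomeConcat:
    """Build the end-to-end concatenation map for a FASTA file.

    ``chromosomes`` defaults to the 22 human autosomes in numeric order
    (accepting either ``chr1`` or ``1`` naming).  A requested chromosome
    missing from the FASTA raises KeyError naming it.
    """
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    if chromosomes is None:
        chromosomes = _default_autosomes(fa.keys())
    elif len(chromosomes) == 0:
        raise ValueError("cannot concatenate an empty chromosome list")
    missing = [c for c in chromosomes if c not in fa]
    if missing:
        raise KeyError(f"chromosomes missing from FASTA: {missing}")
    lengths = tuple(len(fa[c]) for c in chromosomes)
    name = fa.filename if hasattr(fa, "filename") else str(fasta)
    return GenomeConcat(tuple(chromosomes), lengths, source=str(name))


def plan_segments(total_length: int, n_segments: int) -> np.ndarray:
    """Half-open (start, end) bounds of ``n_segments`` consecutive segments.

    Segment length is ceil(total/n); the final segment absorbs the
    remainder and may be shorter.  Returns an (n, 2) int array.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > total_length:
        raise ValueError(
            f"n_segments ({n_segments}) exceeds total length ({total_length})"
        )
    seg_len = math.ceil(total_length / n_segments)
    starts = np.arange(n_segments, dtype=np.int64) * seg_len
    ends = np.minimum(starts + seg_len, total_length)
    return np.stack([starts, ends], axis=1)


def plan_segments_by_chrom(concat: GenomeConcat, n_segments: int) -> np.ndarray:
    """Segment plan that never crosses a chromosome junction.

    The segment length is the global ceil(total/n); each chromosome is
    cut independently into pieces of that length, so the total number of
    segments may exceed ``n_segments``.
    """
    seg_len = math.ceil(concat.total_length / n_segments)
    bounds = []
    offset = 0
    for length in concat.lengths:
        start = offset
        while start < offset + length:
            bounds.append((start, min(start + seg_len, offset + length)))
            start += seg_len
        offset += length
    return np.asarray(bounds, dtype=np.int64)


def segment_composition(sequence: str, strict: bool = True) -> dict:
    """Base counts and N-adjusted GC content of one segment.

    Lowercase (soft-masked) bases count as their base.  Characters other
    than A/C/G/T/N raise ValueError when ``strict`` (default) or are
    counted as N otherwise.  Returns counts plus ``gc_adjusted`` =
    (G+C)/(len-N), which is None for an all-N segment (flagged
    ``all_n``).
    """
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    other = len(seq) - sum(counts.values())
    if other:
        if strict:
            bad = sorted(set(seq) - _VALID_BASES)
            raise ValueError(f"non-ACGTN characters in sequence: {bad}")
        counts["N"] += other
    non_n = len(seq) - counts["N"]
    all_n = non_n == 0
    gc = None if all_n else (counts["G"] + counts["C"]) / non_n
    return {**counts, "length": len(seq), "gc_adjusted": gc, "all_n": all_n}


def segment_sequences(
    fasta: str | Path | Fasta, concat: GenomeConcat, plan: np.ndarray
) -> Iterator[str]:
    """Yield the sequence of each planned segment, spanning junctions."""
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    # precompute chromosome interval bounds in concatenated coordinates
    offs = concat.offsets
    for start, end in np.asarray(plan):
        pieces = []
        pos = int(start)
        while pos < end:
            chrom, cpos = concat.to_chrom(pos)
            chrom_end = offs[chrom] + concat.lengths[concat.chromosomes.index(chrom)]
            take = min(int(end), chrom_end) - pos
            pieces.append(str(fa[chrom][cpos : cpos + take]))
            pos += take
        yield "".join(pieces)


def segment_table(
    fasta: str | Path | Fasta,
    concat: GenomeConcat,
    n_segments: int,
    break_at_chrom: bool = False,
    strict: bool = True,
) -> pd.DataFrame:
    """Segment the concatenated genome and tabulate base composition.

    Returns a DataFrame indexed by segment with columns
    ``start, end, A, C, G, T, N, length, gc_adjusted, all_n``.
    ``gc_adjusted`` is NaN for all-N segments.
    """
    plan = (
        plan_segments_by_chrom(concat, n_segments)
        if break_at_chrom
        else plan_segments(concat.total_length, n_segments)
    )
    rows = []
    for (start, end), seq in zip(plan, segment_sequences(fasta, concat, plan)):
        comp = segment_composition(seq, strict=strict)
        rows.append(
            {
                "start": int(start),
                "end": int(end),
                **{b: comp[b] for b in "ACGTN"},
                "length": comp["length"],
                "gc_adjusted": np.nan if comp["all_n"] else comp["gc_adjusted"],
                "all_n": comp["all_n"],
            }
        )
    df = pd.DataFrame(rows)
    df.index.name = "segment"
    return df


def segments_to_bed(concat: GenomeConcat, plan: np.ndarray) -> pd.DataFrame:
    """Project a segment plan onto per-chromosome BED intervals.

    Segments spanning a junction are split; the ``name`` column keeps
    the segment index so split pieces can be re-associated.
    """
    offs = concat.offsets
    rows = []
    for idx, (start, end) in enumerate(np.asarray(plan)):
        pos = int(start)
        while pos < end:
            chrom, cpos = concat.to_chrom(pos)
            chrom_end = offs[chrom] + concat.lengths[concat.chromosomes.index(chrom)]
            take = min(int(end), chrom_end) - pos
            rows.append({"chrom": chrom, "start": cpos, "end": cpos + take, "name": f"seg{idx}"})
            pos += take
    return pd.DataFrame(rows)
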