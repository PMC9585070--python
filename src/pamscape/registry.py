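"""Cas enzymes and their protospacer-adjacent motifs (PAMs).

A PAM is the short sequence a Cas nuclease must find next to the
protospacer before it can bind and cleave: Cas9-family enzymes read a
PAM downstream of the target (e.g. NGG for SpCas9), Cas12a-family
enzymes read one upstream (e.g. TTTV for AsCas12a).  PAMs are written
in IUPAC degenerate nucleotide code; ``N`` matches any base, ``V``
matches A/C/G, and so on.

This module models PAM patterns and Cas enzymes, expands degenerate
patterns, reverse-complements them, and computes their GC content.  GC
content of a PAM is defined over its informative (non-N) positions: N
positions are dropped from both numerator and denominator, and a
partially degenerate code contributes the fraction of G/C among the
bases it allows (V -> 2/3, S -> 1, W -> 0, ...), which equals the
expected GC under a uniform choice among the allowed bases.

A curated registry of 21 widely used Cas9/Cas12a enzymes (natural
orthologs plus engineered PAM-relaxed variants) ships with the package
as an editable TSV; see :func:`default_registry`.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement as _bio_revcomp

#: IUPAC single-letter codes accepted in PAM patterns.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

PatternLike = Union[str, "PAMPattern"]


def _validate_pattern(pattern: str) -> None:
    if not pattern:
        raise ValueError("PAM pattern must be non-empty")
    for i, ch in enumerate(pattern):
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC code {ch!r} at position {i} of pattern {pattern!r}"
            )


@dataclass(frozen=True)
class PAMPattern:
    """A degenerate PAM motif.

    Parameters
    ----------
    pattern
        IUPAC string, e.g. ``"NGG"`` or ``"TTTV"``.  Stored upper-case.
    orientation
        ``"downstream"`` (Cas9 convention) or ``"upstream"`` (Cas12a
        convention), relative to the protospacer.  Orientation does not
        affect motif counting, which scans both genomic strands anyway;
        it is retained as enzyme metadata.
    """

    pattern: str
    orientation: str = "downstream"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        _validate_pattern(self.pattern)
        if self.orientation not in ("upstream", "downstream"):
            raise ValueError(f"orientation must be upstream/downstream, got {self.orientation!r}")

    def __str__(self) -> str:
        return self.pattern

    def __len__(self) -> int:
        return len(self.pattern)


def _as_str(pattern: PatternLike) -> str:
    if isinstance(pattern, PAMPattern):
        return pattern.pattern
    p = str(pattern).upper()
    _validate_pattern(p)
    return p


def expand_iupac(pattern: PatternLike) -> frozenset[str]:
    """Expand a degenerate pattern into the set of concrete DNA strings.

    >>> sorted(expand_iupac("NGG"))
    ['AGG', 'CGG', 'GGG', 'TGG']
    """
    p = _as_str(pattern)
    choices = [ambiguous_dna_values[ch] for ch in p]
    return frozenset("".join(t) for t in product(*choices))


def reverse_complement_pattern(pattern: PatternLike) -> PAMPattern:
    """Reverse-complement a degenerate pattern (N<->N, V<->B, R<->Y, ...).

    >>> str(reverse_complement_pattern("NGG"))
    'CCN'
    """
    orientation = pattern.orientation if isinstance(pattern, PAMPattern) else "downstream"
    p = _as_str(pattern)
    return PAMPattern(_bio_revcomp(p), orientation=orientation)


def _gc_weight(code: str) -> float:
    """Fraction of G/C among the concrete bases an IUPAC code allows."""
    bases = ambiguous_dna_values[code]
    return sum(b in "GC" for b in bases) / len(bases)


def pam_gc_content(pattern: PatternLike) -> float:
    """GC content of a PAM over its non-N positions, in [0, 1].

    N positions carry no base preference and are excluded entirely.
    Partially degenerate codes contribute their expected GC fraction.
    An all-N pattern has no defined GC content and raises ValueError.

    >>> pam_gc_content("NGG")
    1.0
    """
    p = _as_str(pattern)
    informative = [ch for ch in p if ch != "N"]
    if not informative:
        raise ValueError(f"GC content undefined for all-N pattern {p!r}")
    return sum(_gc_weight(ch) for ch in informative) / len(informative)


@dataclass(frozen=True)
class CasEnzyme:
    """A Cas nuclease with its recognized PAM set.

    ``ranking_pams`` is the subset of PAMs used when ranking genome
    segments for this enzyme.  It usually equals ``pams``; the one
    standard exception is xCas9, whose GAA/GAT sites are subsumed by
    its NG sites (every GAA or GAT occurrence sits one base downstream
    of an NG occurrence), so only NG enters the ranking.
    """

    name: str
    cas_type: str  # "Cas9" or "Cas12a"
    pams: tuple[PAMPattern, ...]
    ranking_pams: tuple[PAMPattern, ...] = ()

    def __post_init__(self) -> None:
        if self.cas_type not in ("Cas9", "Cas12a"):
            raise ValueError(f"cas_type must be Cas9 or Cas12a, got {self.cas_type!r}")
        if not self.pams:
            raise ValueError(f"enzyme {self.name} has no PAMs")
        if not self.ranking_pams:
            object.__setattr__(self, "ranking_pams", self.pams)
        pam_set = {p.pattern for p in self.pams}
        for rp in self.ranking_pams:
            if rp.pattern not in pam_set:
                raise ValueError(
                    f"ranking PAM {rp.pattern} of {self.name} is not among its PAMs"
                )

    @property
    def overall_gc(self) -> float:
        """Pooled GC content over all non-N positions of all PAMs."""
        return cas_overall_gc(self)


def cas_overall_gc(cas: CasEnzyme) -> float:
    """GC content of an enzyme, pooled over every non-N position of every PAM.

    This is a position-pooled average, not a mean of per-PAM values:
    a longer PAM contributes proportionally more positions.
    """
    num = 0.0
    den = 0
    for pam in cas.pams:
        for ch in pam.pattern:
            if ch != "N":
                num += _gc_weight(ch)
                den += 1
    if den == 0:
        raise ValueError(f"GC content undefined: all PAMs of {cas.name} are all-N")
    return num / den


@dataclass(frozen=True)
class CasRegistry:
    """An ordered collection of Cas enzymes with unique names."""

    enzymes: tuple[CasEnzyme, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.enzymes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate enzyme names in registry: {dupes}")

    def __iter__(self) -> Iterator[CasEnzyme]:
        return iter(self.enzymes)

    def __len__(self) -> int:
        return len(self.enzymes)

    def get(self, name: str) -> CasEnzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(f"no enzyme named {name!r} in registry")

    @property
    def unique_pams(self) -> tuple[PAMPattern, ...]:
        """Deduplicated PAM patterns across all enzymes, in first-seen order."""
        seen: dict[str, PAMPattern] = {}
        for e in self.enzymes:
            for p in e.pams:
                seen.setdefault(p.pattern, p)
        return tuple(seen.values())


def _split_pams(cell: str, orientation: str) -> tuple[PAMPattern, ...]:
    cell = cell.strip()
    if not cell or cell == "-":
        return ()
    return tuple(PAMPattern(tok.strip(), orientation=orientation) for tok in cell.split(","))


def load_registry(path: str | Path) -> CasRegistry:
    """Load a registry from a TSV file.

    Columns: ``name  cas_type  orientation  pams  ranking_pams  reference``.
    PAM lists are comma-separated; an empty or ``-`` ranking list means
    "all PAMs".  Lines starting with ``#`` are comments.
    """
    enzymes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed registry line: {raw!r}")
            name, cas_type, orientation, pams = parts[:4]
            ranking = parts[4] if len(parts) > 4 else ""
            enzymes.append(
                CasEnzyme(
                    name=name.strip(),
                    cas_type=cas_type.strip(),
                    pams=_split_pams(pams, orientation.strip()),
                    ranking_pams=_split_pams(ranking, orientation.strip()),
                )
            )
    return CasRegistry(tuple(enzymes))


@functools.lru_cache(maxsize=1)
def default_registry() -> CasRegistry:
    """The curated registry shipped with the package (21 enzymes)."""
    with resources.as_file(
        resources.files("pamscape.data") / "cas_registry.tsv"
    ) as path:
        return load_registry(path)
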