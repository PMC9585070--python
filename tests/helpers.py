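"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: motif matching is
done by concrete k-mer expansion and window scanning (or positionwise
allowed-base lookup) instead of regex; the Fisher p-value by full
hypergeometric enumeration; BH by a literal step-up loop.
"""

from __future__ import annotations

from math import comb

import numpy as np

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement
from pamscape.registry import expand_iupac


def brute_force_matches(sequence: str, pattern: str, strands: str = "both"):
    """Expand the pattern to concrete k-mers and scan every window."""
    seq = sequence.upper()
    k = len(pattern)
    fwd = expand_iupac(pattern)
    hits = set()
    for i in range(len(seq) - k + 1):
        if seq[i : i + k] in fwd:
            hits.add((i, "+"))
    if strands == "both":
        rev = {reverse_complement(s) for s in fwd}
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in rev:
                hits.add((i, "-"))
    return hits


def positionwise_matches(codes: np.ndarray, pattern: str, strands: str = "both"):
    """Vectorized oracle: per-position allowed-base table lookup.

    ``codes`` encodes the sequence as ints (A=0, C=1, G=2, T=3, other=4).
    Returns the same (offset, strand) set as brute_force_matches.
    """
    hits = set()
    variants = [(pattern, "+")]
    if strands == "both":
        variants.append((reverse_complement(pattern), "-"))
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for pat, strand in variants:
        k = len(pat)
        n_win = len(codes) - k + 1
        if n_win <= 0:
            continue
        ok = np.ones(n_win, dtype=bool)
        for p, ch in enumerate(pat):
            allowed = np.zeros(5, dtype=bool)
            for b in ambiguous_dna_values[ch]:
                allowed[base_index[b]] = True
            ok &= allowed[codes[p : p + n_win]]
        hits.update((int(i), strand) for i in np.flatnonzero(ok))
    return hits


def encode_sequence(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def hypergeom_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumerating all tables with the
    observed margins and summing probabilities <= the observed one."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x: int) -> float:
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


def bh_stepup(pvalues, q: float = 0.05) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: find the largest i with
    p_(i) <= i*q/m and reject everything at or below it."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    cutoff = -1
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            cutoff = rank
    flags = np.zeros(m, dtype=bool)
    if cutoff > 0:
        flags[order[:cutoff]] = True
    return flags


def permutation_corr_p(x, y, n_perm: int = 2000, seed: int = 0) -> float:
    """Two-sided permutation p-value for Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    hits = 0
    for _ in range(n_perm):
        r = abs(np.corrcoef(x, rng.permutation(y))[0, 1])
        if r >= r_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
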