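"""Independent brute-force oracles used by the test suite.

These deliberately favour clarity over speed: full-matrix dynamic
programming, exhaustive enumeration, per-base scans.  They share no code
with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def translate_codons(dna: str) -> str:
    """Codon-by-codon translation (codons with N become X)."""
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        out.append(_CODON_TABLE.get(dna[i : i + 3], "X"))
    return "".join(out)


def sw_affine(q: str, s: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2) -> int:
    """Full-matrix Smith-Waterman with affine gaps (gap k costs open+k*ext)."""
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            sub = match if (qi == s[j - 1] and qi != "N") else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            if H[i, j] > best:
                best = int(H[i, j])
    return best


def sw_affine_protein(q: str, s: str, submat, gap_open=-11, gap_extend=-1) -> int:
    """Protein-space Smith-Waterman against a Biopython substitution matrix."""
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            sub = int(submat[q[i - 1]][s[j - 1]])
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            if H[i, j] > best:
                best = int(H[i, j])
    return best


def tsd_scan(locus: str, a: int, b: int, lmin: int, lmax: int, jitter: int):
    """Exhaustive (L, shift-left, shift-right) enumeration of exact direct
    repeats flanking the candidate body; returns set of placements."""
    found = set()
    for L in range(lmin, lmax + 1):
        for ds in range(-jitter, jitter + 1):
            for de in range(-jitter, jitter + 1):
                s0, e0 = a + ds, b + de
                if s0 - L < 0 or e0 + L > len(locus) or e0 <= s0:
                    continue
                left = locus[s0 - L : s0]
                if "N" in left:
                    continue
                if left == locus[e0 : e0 + L]:
                    found.add((left, s0, e0))
    return found


def tir_scan(seq: str, min_len: int, max_mismatch: int):
    """Longest terminal inverted repeat by direct enumeration."""
    best = None
    r = rc(seq)
    for L in range(min_len, len(seq) // 2 + 1):
        mm = sum(1 for x, y in zip(seq[:L], r[:L]) if x != y or x == "N")
        if mm <= max_mismatch:
            best = (L, mm)
    return best


def polya_scan(seq: str, window: int, min_frac: float):
    """Poly(A) call by direct suffix enumeration."""
    if len(seq) < window:
        return None
    tail_window = seq[-window:]
    if tail_window.count("A") / window < min_frac:
        return None
    tail = 0
    for L in range(1, len(seq) + 1):
        suf = seq[-L:]
        if suf.count("A") / L >= min_frac:
            tail = L
    return tail


def ltr_scan(seq: str, min_len: int, min_identity: float, jitter: int):
    """Exhaustive anchored direct-repeat pair scan (ungapped).

    Tries every (left offset, right end offset, length) combination with
    the repeats anchored within the jitter of the two sequence ends and
    returns the best (length, identity) pair or None.
    """
    n = len(seq)
    best = None
    for off_l in range(0, jitter + 1):
        for off_r in range(0, jitter + 1):
            max_len = min(n // 2 - off_l, n // 2 - off_r)
            for L in range(min_len, max_len + 1):
                left = seq[off_l : off_l + L]
                right = seq[n - off_r - L : n - off_r]
                ident = 100.0 * sum(
                    1 for x, y in zip(left, right) if x == y and x != "N"
                ) / L
                if ident >= min_identity:
                    key = (L, ident)
                    if best is None or key > (best[0], best[1]):
                        best = (L, ident, off_l, off_r)
    return best


def overlap_components(intervals: list[tuple[str, int, int]], frac: float = 0.8):
    """Connected components under reciprocal-overlap >= frac (brute force).

    ``intervals`` maps index -> (subject, start, end); returns a list of
    frozensets of indices.
    """
    n = len(intervals)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            si, ai, bi = intervals[i]
            sj, aj, bj = intervals[j]
            if si != sj:
                continue
            ov = min(bi, bj) - max(ai, aj)
            if ov > 0 and ov >= frac * (bi - ai) and ov >= frac * (bj - aj):
                adj[i].add(j)
                adj[j].add(i)
    seen = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps
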