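"""Defining intact transposons: TSD, LTR, TIR and poly(A) detection.

An intact element is gated on two independent lines of evidence: an exact
target-site duplication (TSD) flanking the body, and the superfamily's
terminal hallmark inside the body (an LTR pair, terminal inverted
repeats, or a 3' poly(A) tail).  Boundary candidates come from anchored
homology hits refined by all-vs-all copy alignment; the TSD scan then
jitters each boundary within a small window, and among the TSD
candidates whose body carries a terminal feature the one with the most
exactly-anchored feature (then the longest TSD) wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import HomologyHit, encode_dna, filter_significant, search_dna_vs_dna
from .core import Interval, PipelineParams, SequenceRecord, revcomp


@dataclass(frozen=True)
class CandidateLocus:
    """An anchored hit with its flanking window of genomic context."""

    source_hit: HomologyHit
    window: Interval
    window_seq: str


@dataclass(frozen=True)
class TsdCandidate:
    """A possible body placement with exact direct repeats outside it."""

    seq: str
    body_start: int  # window-relative
    body_end: int
    jitter: int  # |shift_left| + |shift_right| from the initial boundary

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class StructuralFeatures:
    tsd: Optional[TsdCandidate]
    terminal_type: str  # LTR | TIR | POLYA | NONE
    terminal_detail: dict = field(default_factory=dict)


@dataclass
class IntactElement:
    name: str
    family: str
    location: Interval  # element body, TSDs excluded
    superfamily: str
    features: StructuralFeatures
    element_seq: str


# -- locus extraction ---------------------------------------------------------


def extract_locus(
    genome: Sequence[SequenceRecord], hit: HomologyHit, params: Optional[PipelineParams] = None
) -> CandidateLocus:
    """Cut the hit plus ``locus_flank`` bp of context on each side."""
    params = params or PipelineParams()
    seqs = {r.id: r for r in genome}
    if hit.subject_id not in seqs:
        raise ValueError(f"hit subject {hit.subject_id!r} not in genome")
    chrom = seqs[hit.subject_id]
    if hit.s_end > len(chrom.seq) or hit.s_start < 0:
        raise ValueError("hit lies off its chromosome")
    start = max(0, hit.s_start - params.locus_flank)
    end = min(len(chrom.seq), hit.s_end + params.locus_flank)
    return CandidateLocus(
        source_hit=hit,
        window=Interval(hit.subject_id, start, end),
        window_seq=chrom.seq[start:end],
    )


# -- feature finders ----------------------------------------------------------


def find_tsd(
    locus_seq: str, cand_start: int, cand_end: int, params: Optional[PipelineParams] = None
) -> list[TsdCandidate]:
    """Exact direct repeats flanking a (jittered) candidate body.

    For every TSD length L in [tsd_len_min, tsd_len_max] and every pair
    of boundary shifts within ±boundary_jitter, report candidates where
    the L bases left of the body equal the L bases right of it.  Ranked
    by length (desc) then jitter (asc).
    """
    params = params or PipelineParams()
    if not (0 <= cand_start < cand_end <= len(locus_seq)):
        raise ValueError("candidate interval outside locus")
    j = params.boundary_jitter
    out = []
    for L in range(params.tsd_len_max, params.tsd_len_min - 1, -1):
        for ds in range(-j, j + 1):
            a = cand_start + ds
            if a - L < 0:
                continue
            left = locus_seq[a - L : a]
            if "N" in left:
                continue
            for de in range(-j, j + 1):
                b = cand_end + de
                if b + L > len(locus_seq) or b <= a:
                    continue
                if locus_seq[b : b + L] == left:
                    out.append(TsdCandidate(left, a, b, abs(ds) + abs(de)))
    out.sort(key=lambda c: (-c.length, c.jitter, c.body_start, c.body_end))
    return out


@dataclass(frozen=True)
class LtrCall:
    left: tuple[int, int]  # region-relative half-open
    right: tuple[int, int]
    length: int
    identity: float


def find_ltr_pair(
    locus_seq: str,
    region: tuple[int, int],
    params: Optional[PipelineParams] = None,
) -> Optional[LtrCall]:
    """Best pair of long direct repeats near the two ends of a region.

    The first half of the region is aligned to the second half on the
    plus strand; a qualifying repeat pair is >= ltr_min_len long at
    >= ltr_min_identity percent identity, with the left copy anchored at
    the region start and the right copy at the region end (within the
    boundary jitter).  Pairs starting TG and ending CA are preferred.
    """
    params = params or PipelineParams()
    a, b = region
    seq = locus_seq[a:b]
    n = len(seq)
    if n <= 2 * params.ltr_min_len:
        return None
    half = n // 2
    prefix = SequenceRecord("prefix", seq[:half])
    suffix = SequenceRecord("suffix", seq[half:])
    hits = search_dna_vs_dna(prefix, suffix, params)
    cands = []
    for h in hits:
        if h.strand != "+" or h.aln_len < params.ltr_min_len:
            continue
        if h.percent_identity < params.ltr_min_identity:
            continue
        left = (h.q_start, h.q_end)
        right = (half + h.s_start, half + h.s_end)
        if left[0] > params.boundary_jitter or n - right[1] > params.boundary_jitter:
            continue
        canonical = seq[left[0] : left[0] + 2] == "TG" and seq[right[1] - 2 : right[1]] == "CA"
        cands.append((not canonical, -h.aln_len, h.e_value, LtrCall(left, right, h.aln_len, h.percent_identity)))
    if not cands:
        return None
    cands.sort(key=lambda t: t[:3])
    return cands[0][3]


@dataclass(frozen=True)
class TirCall:
    length: int
    mismatches: int


def find_tir(
    locus_seq: str, region: tuple[int, int], params: Optional[PipelineParams] = None
) -> Optional[TirCall]:
    """Longest terminal inverted repeat with few mismatches.

    Compares the region prefix with the reverse complement of its suffix
    base by base; returns the longest length >= tir_min_len whose
    cumulative mismatch count is <= tir_max_mismatch.
    """
    params = params or PipelineParams()
    a, b = region
    seq = locus_seq[a:b]
    n = len(seq)
    if n <= 2 * params.tir_min_len:
        return None
    fwd = encode_dna(seq)
    rc = encode_dna(revcomp(seq))
    lim = n // 2
    mism = np.cumsum((fwd[:lim] != rc[:lim]) | (fwd[:lim] >= 4))
    ok = np.nonzero(mism <= params.tir_max_mismatch)[0]
    if len(ok) == 0:
        return None
    L = int(ok[-1]) + 1
    if L < params.tir_min_len:
        return None
    return TirCall(length=L, mismatches=int(mism[L - 1]))


@dataclass(frozen=True)
class PolyaCall:
    tail_len: int
    a_frac: float


def find_polya(
    element_3prime: str, params: Optional[PipelineParams] = None
) -> Optional[PolyaCall]:
    """Call a 3' poly(A) tract from the terminal window.

    A call requires the A fraction over the last ``polya_window`` bases to
    reach ``polya_min_frac``; the tail length is the longest suffix whose
    running A fraction stays at or above the threshold.
    """
    params = params or PipelineParams()
    s = element_3prime
    if len(s) < params.polya_window:
        raise ValueError("too few bases for a poly(A) call")
    window = s[-params.polya_window :]
    frac = window.count("A") / params.polya_window
    if frac < params.polya_min_frac:
        return None
    n_a = 0
    tail = 0
    for l, ch in enumerate(reversed(s), start=1):
        if ch == "A":
            n_a += 1
        if n_a / l >= params.polya_min_frac:
            tail = l
    return PolyaCall(tail_len=tail, a_frac=round(frac, 3))


# -- element definition -------------------------------------------------------


def _terminal_features(
    body: str, params: PipelineParams
) -> Optional[tuple[str, dict, int]]:
    """Detect the terminal hallmark of a body; returns (type, detail,
    anchor_distance) or None.  TIR and poly(A) are inherently anchored at
    the body ends; for an LTR pair the anchor distance is how far the
    detected repeats sit from the body termini."""
    n = len(body)
    tir = find_tir(body, (0, n), params) if n > 2 * params.tir_min_len else None
    if tir is not None:
        return "TIR", {"tir_len": tir.length, "mismatches": tir.mismatches,
                       "motif_cacta": body.startswith("CACTA")}, 0
    ltr = find_ltr_pair(body, (0, n), params) if n > 2 * params.ltr_min_len else None
    if ltr is not None:
        dist = ltr.left[0] + (n - ltr.right[1])
        return "LTR", {"ltr_len": ltr.length, "ltr_identity": ltr.identity,
                       "left": ltr.left, "right": ltr.right}, dist
    if n >= params.polya_window:
        polya = find_polya(body, params)
        if polya is not None:
            return "POLYA", {"tail_len": polya.tail_len, "a_frac": polya.a_frac}, 0
    return None


def classify_superfamily(features: StructuralFeatures, tsd_seq: str) -> str:
    """Superfamily from terminal feature and TSD, by standard conventions."""
    t = features.terminal_type
    detail = features.terminal_detail
    if t == "LTR":
        return "LTR_retrotransposon"
    if t == "TIR":
        if tsd_seq == "TA":
            return "Tc1/mariner"
        if detail.get("motif_cacta") and len(tsd_seq) == 3:
            return "CACTA"
        if 8 <= len(tsd_seq) <= 10:
            return "Mutator"
        return "UNCLASSIFIED"
    if t == "POLYA":
        return "LINE"
    return "UNCLASSIFIED"


def refine_with_copies(
    primary: CandidateLocus,
    others: Sequence[CandidateLocus],
    params: PipelineParams,
    max_others: int = 2,
    margin: int = 1000,
) -> tuple[int, int]:
    """Estimate the element extent on the primary window by aligning it
    against sibling copy windows: copies share the element and differ in
    their flanks, so the union of significant alignment intervals
    overlapping the anchor marks where multi-copy homology drops off.

    Pairwise local alignments can overrun a true boundary by a base or
    two when adjacent flank bases coincide, so the anchor extent is only
    widened when the homology union extends clearly (more than the
    boundary jitter) beyond it; otherwise the anchor boundary stands.
    """
    hit = primary.source_hit
    a0 = hit.s_start - primary.window.start
    b0 = hit.s_end - primary.window.start
    qa = max(0, a0 - margin)
    qb = min(len(primary.window_seq), b0 + margin)
    qrec = SequenceRecord("primary", primary.window_seq[qa:qb])
    a, b = a0, b0
    for other in others[:max_others]:
        for h in filter_significant(
            search_dna_vs_dna(qrec, SequenceRecord("other", other.window_seq), params),
            params,
        ):
            hq0, hq1 = h.q_start + qa, h.q_end + qa
            if other.window.chrom == primary.window.chrom:
                # nearby loci have physically overlapping windows: a hit
                # that maps a region onto itself is not copy evidence
                gq0 = primary.window.start + hq0
                gq1 = primary.window.start + hq1
                gs0 = other.window.start + h.s_start
                gs1 = other.window.start + h.s_end
                if gq0 < gs1 and gs0 < gq1:
                    continue
            if hq0 < b and a < hq1:  # overlaps current estimate
                a = min(a, hq0)
                b = max(b, hq1)
    if a0 - a <= params.boundary_jitter:
        a = a0
    if b - b0 <= params.boundary_jitter:
        b = b0
    return a, b


def define_element(
    loci: Sequence[CandidateLocus],
    family_name: str,
    params: Optional[PipelineParams] = None,
    max_tsd_candidates: int = 30,
) -> Optional[IntactElement]:
    """Define one intact element for a family from its candidate loci.

    Loci are tried best-hit-first; a locus yields an element only when an
    exact TSD and a terminal feature coincide (the strict gate: both
    lines of evidence, or nothing).  Returns None when no locus qualifies
    — the "no complete element" outcome for truncated copies.
    """
    params = params or PipelineParams()
    if not loci:
        raise ValueError("no candidate loci supplied")
    ordered = sorted(loci, key=lambda l: (-l.source_hit.bit_score, l.window.chrom, l.window.start))
    for idx, locus in enumerate(ordered):
        a0 = locus.source_hit.s_start - locus.window.start
        b0 = locus.source_hit.s_end - locus.window.start
        # The anchor extent is bounded by the query and cannot overrun the
        # element, so it is tried first; the multi-copy union widens the
        # proposal only when the anchor covered the element partially.
        extents = [(a0, b0)]
        others = [l for k, l in enumerate(ordered) if k != idx]
        if others:
            ar, br = refine_with_copies(locus, others, params)
            if (ar, br) != (a0, b0):
                extents.append((ar, br))
        for a, b in extents:
            element = _element_at(locus, a, b, family_name, params, max_tsd_candidates)
            if element is not None:
                return element
    return None


def _element_at(
    locus: CandidateLocus,
    a: int,
    b: int,
    family_name: str,
    params: PipelineParams,
    max_tsd_candidates: int = 30,
) -> Optional[IntactElement]:
    """Try to place an intact element near window-relative extent [a, b)."""
    strand = locus.source_hit.strand
    # Smallest jitter first (the boundary proposal is trusted), longest
    # TSD within a jitter class; the first candidate whose body carries a
    # terminal feature wins.  Ranking by TSD length across jitter classes
    # would let microhomology between element termini and flanking bases
    # fabricate longer pseudo-TSDs at shifted boundaries.
    cands = sorted(
        find_tsd(locus.window_seq, a, b, params),
        key=lambda c: (c.jitter, -c.length, c.body_start, c.body_end),
    )[:max_tsd_candidates]
    found = None
    for cand in cands:
        body = locus.window_seq[cand.body_start : cand.body_end]
        if strand == "-":
            body = revcomp(body)
        feat = _terminal_features(body, params)
        if feat is not None:
            found = (cand, feat[0], feat[1])
            break
    if found is None:
        return None
    cand, ttype, detail = found
    features = StructuralFeatures(tsd=cand, terminal_type=ttype, terminal_detail=detail)
    location = Interval(
        locus.window.chrom,
        locus.window.start + cand.body_start,
        locus.window.start + cand.body_end,
        strand,
    )
    body = locus.window_seq[cand.body_start : cand.body_end]
    if strand == "-":
        body = revcomp(body)
    return IntactElement(
        name=family_name,
        family=family_name,
        location=location,
        superfamily=classify_superfamily(features, cand.seq),
        features=features,
        element_seq=body,
    )
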