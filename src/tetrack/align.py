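"""Seed-and-extend local alignment with E-values.

Two search modes cover what the pipeline needs: nucleotide query vs
nucleotide subject (exact k-mer seeds on both strands, default word 11)
and protein query vs six-frame-translated subject (word 3 with BLOSUM62
neighborhood seeding).  Seeds are clustered by diagonal and each cluster
is resolved by a banded affine-gap (Gotoh) dynamic program whose rows are
vectorized with numpy; on small problems the band covers the full matrix,
so the reported optimum equals full Smith–Waterman.  E-values follow the
Karlin–Altschul formula E = K·m·n·exp(−λ·S).

A gap of length k costs ``gap_open + k·gap_extend`` (both negative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core import PipelineParams, ProteinQuery, SequenceRecord, revcomp

# Karlin–Altschul parameters (lambda, K): nucleotide values for +2/-3
# scoring, protein values for BLOSUM62 with 11/1 gaps.
KA_NT = (0.625, 0.41)
KA_AA = (0.267, 0.041)

AA_GAP_OPEN = -11
AA_GAP_EXTEND = -1

_NT_CODE = {c: i for i, c in enumerate("ACGTN")}
_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_CODE = {c: i for i, c in enumerate(_AA_ORDER)}

# problems with m*n at or below this get a full-band (exact) DP
SMALL_PROBLEM_CELLS = 250_000
_SEED_QGAP = 100  # max along-query gap when chaining seeds on one diagonal
_DIAG_MERGE = 16  # diagonals closer than this join one cluster
_UNGAPPED_GATE = 40  # raw score an isolated seed must reach to earn a DP


@dataclass(frozen=True)
class HomologyHit:
    """A scored local alignment between a query and a subject.

    Query coordinates are in query units (nt, or aa for translated
    searches) on the forward query; subject coordinates are nucleotide
    positions on the forward subject strand.  ``frame`` is None for
    nucleotide searches.  ``aln_len`` counts alignment columns.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    frame: Optional[int]
    aln_len: int
    percent_identity: float
    raw_score: int
    bit_score: float
    e_value: float

    def matched_nt(self) -> int:
        """Matched-region length in subject nucleotides."""
        return self.aln_len * (3 if self.frame is not None else 1)


def encode_dna(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    ).copy()


def encode_aa(seq: str) -> np.ndarray:
    out = np.array([_AA_CODE.get(c, _AA_CODE["X"]) for c in seq], dtype=np.uint8)
    return out


def _dna_submat(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N never matches, not even N
    m[:, 4] = mismatch
    return m


_B62 = substitution_matrices.load("BLOSUM62")


def _aa_submat() -> np.ndarray:
    n = len(_AA_ORDER)
    m = np.full((n, n), -4, dtype=np.int32)
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            try:
                m[i, j] = int(_B62[a][b])
            except (KeyError, IndexError):
                pass
    return m


_AA_SUBMAT = _aa_submat()


# -- banded Gotoh local alignment --------------------------------------------


def banded_local_align(
    q: np.ndarray,
    s: np.ndarray,
    submat: np.ndarray,
    gap_open: int,
    gap_extend: int,
    dlo: int,
    dhi: int,
    exclude_code: int | None = None,
):
    """Best local alignment restricted to diagonals d = j - i in [dlo, dhi].

    Returns (raw_score, q_start, q_end, s_start, s_end, n_ident, n_cols)
    or None if no positive-scoring cell exists.  With the band spanning
    the whole matrix this is exact Smith–Waterman with affine gaps.
    """
    m, n = len(q), len(s)
    dlo = max(dlo, -(m - 1))
    dhi = min(dhi, n - 1)
    if dlo > dhi:
        return None
    W = dhi - dlo + 1
    NEG = np.int32(-(10**8))
    open_ext = gap_open + gap_extend

    H = np.zeros((m + 1, W), dtype=np.int32)
    F_prev = np.full(W, NEG, dtype=np.int32)
    F_cur = np.full(W, NEG, dtype=np.int32)
    ramp = np.arange(W, dtype=np.int32) * gap_extend  # for the prefix trick

    best = 0
    best_cell = None
    for i in range(1, m + 1):
        # cell (i, j) scores q[i-1] vs s[j-1]; band offset b has j = i+dlo+b
        j0 = i + dlo
        b_lo = max(0, 1 - j0)
        b_hi = min(W - 1, n - j0)
        if b_lo > b_hi:
            F_prev.fill(NEG)
            continue
        sl = slice(b_lo, b_hi + 1)
        sub = submat[q[i - 1]][s[j0 + b_lo - 1 : j0 + b_hi]]

        Hp = H[i - 1]
        # diagonal predecessor (i-1, j-1) sits at the same band offset;
        # vertical-gap predecessor (i-1, j) sits at offset b+1
        P = Hp[sl] + sub
        F_cur.fill(NEG)
        if b_lo < W - 1:
            up = slice(b_lo + 1, min(b_hi + 2, W))
            upd = slice(b_lo, b_lo + (up.stop - up.start))
            F_cur[upd] = np.maximum(F_prev[up] + gap_extend, Hp[up] + open_ext)
            np.maximum(P, F_cur[sl], out=P)
        np.maximum(P, 0, out=P)

        # horizontal gap via prefix-max: E[b] = open + max_{k<b}(P[k]+(b-k)ext)
        G = np.maximum.accumulate(P - ramp[sl])
        Hrow = P
        if b_hi > b_lo:
            E = G[:-1] + ramp[sl][1:] + gap_open
            np.maximum(Hrow[1:], E, out=Hrow[1:])
        H[i, sl] = Hrow

        F_prev, F_cur = F_cur, F_prev
        rb = int(np.argmax(Hrow))
        if Hrow[rb] > best:
            best = int(Hrow[rb])
            best_cell = (i, rb + b_lo)

    if best <= 0 or best_cell is None:
        return None
    return _traceback(q, s, submat, gap_open, gap_extend, dlo, H, best_cell, exclude_code)


def _traceback(q, s, submat, gap_open, gap_extend, dlo, H, cell, exclude_code):
    m, n = len(q), len(s)
    W = H.shape[1]
    i, b = cell
    score = int(H[i, b])
    n_ident = 0
    n_cols = 0
    q_end = i
    s_end = i + dlo + b
    open_ext = gap_open + gap_extend
    while True:
        h = int(H[i, b])
        if h == 0:
            break
        j = i + dlo + b
        sub = int(submat[q[i - 1], s[j - 1]])
        if i >= 1 and j >= 1 and h == int(H[i - 1, b]) + sub:
            if q[i - 1] == s[j - 1] and (exclude_code is None or q[i - 1] != exclude_code):
                n_ident += 1
            n_cols += 1
            i -= 1
            continue
        # horizontal gap (consumes subject): jump to (i, k) with k < b
        done = False
        for k in range(b - 1, -1, -1):
            if h == int(H[i, k]) + gap_open + (b - k) * gap_extend:
                n_cols += b - k
                b = k
                done = True
                break
        if done:
            continue
        # vertical gap (consumes query): jump to (i - l, b + l)
        for l in range(1, min(i, W - 1 - b) + 1):
            if h == int(H[i - l, b + l]) + gap_open + l * gap_extend:
                n_cols += l
                i -= l
                b += l
                done = True
                break
        if not done:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed")
    q_start = i
    s_start = i + dlo + b
    return score, q_start, q_end, s_start, s_end, n_ident, n_cols


# -- k-mer indexing -----------------------------------------------------------


class SubjectIndex:
    """Sorted exact k-mer index over one or more nucleotide subjects."""

    def __init__(self, subjects: Sequence[SequenceRecord], word_size: int):
        self.word_size = word_size
        self.subjects = list(subjects)
        self.codes = {r.id: encode_dna(r.seq) for r in self.subjects}
        self.total_length = sum(len(r.seq) for r in self.subjects)
        self._kmers = {}
        for r in self.subjects:
            self._kmers[r.id] = _build_kmer_index(self.codes[r.id], word_size)

    def lookup(self, subject_id: str, kcodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Match query k-mer codes; returns (query_pos, subject_pos) arrays."""
        sorted_codes, positions = self._kmers[subject_id]
        lo = np.searchsorted(sorted_codes, kcodes, side="left")
        hi = np.searchsorted(sorted_codes, kcodes, side="right")
        counts = hi - lo
        qpos = np.repeat(np.arange(len(kcodes)), counts)
        spos = np.concatenate(
            [positions[a:b] for a, b in zip(lo, hi) if b > a]
        ) if counts.sum() else np.empty(0, dtype=np.int64)
        return qpos, spos


def _kmer_codes(codes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Encode every w-mer as an integer; second array flags windows with N."""
    n = len(codes)
    if n < w:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    powers = (4 ** np.arange(w - 1, -1, -1)).astype(np.int64)
    vals = windows.astype(np.int64) @ powers
    has_n = np.convolve((codes >= 4).astype(np.int64), np.ones(w, dtype=np.int64))[
        w - 1 : n
    ] > 0
    return vals, has_n


def _build_kmer_index(codes: np.ndarray, w: int):
    vals, has_n = _kmer_codes(codes, w)
    keep = ~has_n
    vals = vals[keep]
    positions = np.nonzero(keep)[0]
    order = np.argsort(vals, kind="stable")
    return vals[order], positions[order].astype(np.int64)


def _cluster_seeds(qpos: np.ndarray, spos: np.ndarray, w: int):
    """Group seeds into diagonal clusters; yields (dmin, dmax, seeds)."""
    if len(qpos) == 0:
        return []
    d = spos - qpos
    order = np.lexsort((spos, d))
    d, qp, sp = d[order], qpos[order], spos[order]
    clusters = []
    cur = [0]
    for t in range(1, len(d)):
        if d[t] - d[cur[-1]] <= _DIAG_MERGE and sp[t] - sp[cur[-1]] <= _SEED_QGAP + _DIAG_MERGE:
            cur.append(t)
        else:
            clusters.append(cur)
            cur = [t]
    clusters.append(cur)
    out = []
    for idx in clusters:
        ii = np.array(idx)
        out.append((int(d[ii].min()), int(d[ii].max()), qp[ii], sp[ii]))
    return out


def _ungapped_extend(q, s, qpos, spos, w, match, mismatch, xdrop=20):
    """X-drop ungapped extension around an exact seed; returns raw score."""
    score = w * match
    best = score
    i, j = qpos + w, spos + w
    while i < len(q) and j < len(s):
        score += match if (q[i] == s[j] and q[i] < 4) else mismatch
        if score > best:
            best = score
        if best - score > xdrop:
            break
        i += 1
        j += 1
    score = best
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        score += match if (q[i] == s[j] and q[i] < 4) else mismatch
        if score > best:
            best = score
        if best - score > xdrop:
            break
        i -= 1
        j -= 1
    return best


# -- nucleotide search --------------------------------------------------------


def _ka_stats(raw: int, m: int, n: int, ka) -> tuple[float, float]:
    lam, K = ka
    bits = (lam * raw - np.log(K)) / np.log(2)
    evalue = float(m) * float(n) * 2.0 ** (-bits)
    return float(bits), float(evalue)


def search_dna_vs_dna(
    query: SequenceRecord,
    subject: Union[SequenceRecord, Sequence[SequenceRecord], SubjectIndex],
    params: Optional[PipelineParams] = None,
) -> list[HomologyHit]:
    """All significant-looking local alignments of query vs subject(s).

    Both strands of the query are seeded with exact ``word_size``-mers;
    seed clusters are extended by banded DP.  Hits are sorted by
    (e_value, -bit_score, subject_id, s_start) for determinism.
    """
    params = params or PipelineParams()
    index = subject if isinstance(subject, SubjectIndex) else SubjectIndex(
        [subject] if isinstance(subject, SequenceRecord) else list(subject),
        params.word_size,
    )
    if index.word_size != params.word_size:
        raise ValueError("index word size does not match params")
    submat = _dna_submat(params.match_score, params.mismatch_score)
    m = len(query.seq)
    hits: list[HomologyHit] = []
    oriented = {"+": encode_dna(query.seq), "-": encode_dna(revcomp(query.seq))}
    for strand, qcodes in oriented.items():
        kq, has_n = _kmer_codes(qcodes, params.word_size)
        valid = np.nonzero(~has_n)[0]
        kq = kq[valid]
        for rec in index.subjects:
            scodes = index.codes[rec.id]
            qpos_raw, spos = index.lookup(rec.id, kq)
            qpos = valid[qpos_raw] if len(qpos_raw) else qpos_raw
            small = m * len(scodes) <= SMALL_PROBLEM_CELLS
            if small:
                if len(qpos) == 0:
                    continue
                regions = [(-(m - 1), len(scodes) - 1)]
            else:
                regions = []
                for dmin, dmax, qp, sp in _cluster_seeds(qpos, spos, params.word_size):
                    span = qp.max() - qp.min() + params.word_size
                    if span < 2 * params.word_size:
                        ug = _ungapped_extend(
                            qcodes, scodes, int(qp[0]), int(sp[0]),
                            params.word_size, params.match_score, params.mismatch_score,
                        )
                        if ug < _UNGAPPED_GATE:
                            continue
                    regions.append((dmin - params.band_pad, dmax + params.band_pad))
            for dlo, dhi in regions:
                res = banded_local_align(
                    qcodes, scodes, submat, params.gap_open, params.gap_extend,
                    dlo, dhi, exclude_code=4,
                )
                if res is None:
                    continue
                raw, qs, qe, ss, se, nid, ncols = res
                if strand == "-":
                    qs, qe = m - qe, m - qs
                bits, ev = _ka_stats(raw, m, index.total_length, KA_NT)
                hits.append(
                    HomologyHit(
                        query_id=query.id, subject_id=rec.id,
                        q_start=qs, q_end=qe, s_start=ss, s_end=se,
                        strand=strand, frame=None, aln_len=ncols,
                        percent_identity=round(100.0 * nid / ncols, 2),
                        raw_score=raw, bit_score=round(bits, 2), e_value=ev,
                    )
                )
    return _finalize(hits)


def _finalize(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Suppress near-duplicate hits and sort deterministically."""
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.subject_id, h.s_start, h.strand))
    kept: list[HomologyHit] = []
    for h in hits:
        dup = False
        for k in kept:
            if k.subject_id != h.subject_id or k.strand != h.strand or k.frame != h.frame:
                continue
            so = min(k.s_end, h.s_end) - max(k.s_start, h.s_start)
            qo = min(k.q_end, h.q_end) - max(k.q_start, h.q_start)
            if so > 0.8 * (h.s_end - h.s_start) and qo > 0.8 * (h.q_end - h.q_start):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


# -- translated search --------------------------------------------------------


def translate_six_frames(dna: str) -> list[tuple[int, str]]:
    """Translate all six reading frames; stops rendered as ``*``.

    Returns (frame, aaseq) pairs with frame in {1,2,3,-1,-2,-3}; negative
    frames read the reverse complement.
    """
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    fwd = dna.upper().replace("N", "N")
    rev = revcomp(fwd)
    out = []
    for f in (1, 2, 3):
        for strand_seq, sign in ((fwd, 1), (rev, -1)):
            sub = strand_seq[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate()) if sub else ""
            out.append((sign * f, aa))
    out.sort(key=lambda t: (t[0] < 0, abs(t[0])))
    return out


_TWO_HIT_WINDOW = 64  # aa distance within which two same-diagonal seeds count
_MIN_AA_CLUSTER_SEEDS = 4  # surviving seeds a cluster needs to earn a DP


def _two_hit_filter(qp: np.ndarray, sp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep only seeds supported by a second seed on the same diagonal
    within the two-hit window (the classic neighborhood-seeding gate)."""
    if len(qp) < 2:
        return qp[:0], sp[:0]
    d = sp - qp
    order = np.lexsort((qp, d))
    ds, qs = d[order], qp[order]
    same = ds[1:] == ds[:-1]
    close = (qs[1:] - qs[:-1]) <= _TWO_HIT_WINDOW
    pair = same & close
    keep = np.zeros(len(qp), dtype=bool)
    keep[:-1] |= pair
    keep[1:] |= pair
    idx = order[keep]
    return qp[idx], sp[idx]


def _aa_neighbors(qcodes: np.ndarray, threshold: int = 12):
    """BLOSUM62 neighborhood words for every query 3-mer position.

    Returns dict word-code -> list of query positions.  Word codes are
    base-24 integers over the BLOSUM alphabet.
    """
    n20 = 20  # seed neighborhood restricted to the 20 standard residues
    S = _AA_SUBMAT[:n20, :n20]
    base = len(_AA_ORDER)
    table: dict[int, list[int]] = {}
    for pos in range(len(qcodes) - 2):
        a, b, c = int(qcodes[pos]), int(qcodes[pos + 1]), int(qcodes[pos + 2])
        if a >= n20 or b >= n20 or c >= n20:
            continue
        tot = (
            S[a][:, None, None] + S[b][None, :, None] + S[c][None, None, :]
        )
        for x, y, z in np.argwhere(tot >= threshold):
            code = (int(x) * base + int(y)) * base + int(z)
            table.setdefault(code, []).append(pos)
    return table


def search_protein_vs_dna(
    query: ProteinQuery,
    subject: Union[SequenceRecord, Sequence[SequenceRecord]],
    params: Optional[PipelineParams] = None,
) -> list[HomologyHit]:
    """Protein query vs six-frame translated nucleotide subject(s).

    Seeds are 3-mer BLOSUM62 neighborhood words; extension runs in
    protein space within each frame and coordinates are mapped back to
    the forward DNA strand of the subject.
    """
    params = params or PipelineParams()
    subjects = [subject] if isinstance(subject, SequenceRecord) else list(subject)
    qcodes = encode_aa(query.aaseq)
    m = len(qcodes)
    neigh = _aa_neighbors(qcodes)
    base = len(_AA_ORDER)
    total_aa = sum(len(r.seq) // 3 for r in subjects) or 1
    hits: list[HomologyHit] = []
    for rec in subjects:
        n = len(rec.seq)
        for frame, aaseq in translate_six_frames(rec.seq):
            if len(aaseq) < 3:
                continue
            scodes = encode_aa(aaseq)
            wcodes = (
                scodes[:-2].astype(np.int64) * base + scodes[1:-1]
            ) * base + scodes[2:]
            qpos_list, spos_list = [], []
            for sp, code in enumerate(wcodes):
                ql = neigh.get(int(code))
                if ql:
                    qpos_list.extend(ql)
                    spos_list.extend([sp] * len(ql))
            if not qpos_list:
                continue
            # neighborhood seeding is dense, so a DP is only spent where a
            # second seed supports the same diagonal (two-hit rule)
            qpos, spos = _two_hit_filter(np.array(qpos_list), np.array(spos_list))
            if len(qpos) == 0:
                continue
            clusters = [
                c for c in _cluster_seeds(qpos, spos, 3) if len(c[2]) >= _MIN_AA_CLUSTER_SEEDS
            ]
            if not clusters:
                continue
            if m * len(scodes) <= 4 * SMALL_PROBLEM_CELLS:
                regions = [(-(m - 1), len(scodes) - 1)]
            else:
                regions = [
                    (dmin - params.band_pad, dmax + params.band_pad)
                    for dmin, dmax, _, _ in clusters
                ]
            for dlo, dhi in regions:
                res = banded_local_align(
                    qcodes, scodes, _AA_SUBMAT, AA_GAP_OPEN, AA_GAP_EXTEND,
                    dlo, dhi, exclude_code=_AA_CODE["X"],
                )
                if res is None:
                    continue
                raw, qs, qe, aas, aae, nid, ncols = res
                off = abs(frame) - 1
                if frame > 0:
                    s_start = off + 3 * aas
                    s_end = off + 3 * aae
                    strand = "+"
                else:
                    s_end = n - off - 3 * aas
                    s_start = n - off - 3 * aae
                    strand = "-"
                bits, ev = _ka_stats(raw, m, total_aa, KA_AA)
                hits.append(
                    HomologyHit(
                        query_id=query.id, subject_id=rec.id,
                        q_start=qs, q_end=qe, s_start=s_start, s_end=s_end,
                        strand=strand, frame=frame, aln_len=ncols,
                        percent_identity=round(100.0 * nid / ncols, 2),
                        raw_score=raw, bit_score=round(bits, 2), e_value=ev,
                    )
                )
    return _finalize(hits)


# -- significance filter & query deduplication --------------------------------


def filter_significant(
    hits: Iterable[HomologyHit], params: Optional[PipelineParams] = None
) -> list[HomologyHit]:
    """Keep hits with E-value below threshold and matched region over the
    minimum length (strictly greater; translated hits count 3 nt per
    column)."""
    params = params or PipelineParams()
    return [
        h
        for h in hits
        if h.e_value < params.evalue_max and h.matched_nt() > params.min_match_len
    ]


def deduplicate_queries(hits: Sequence[HomologyHit]) -> list[HomologyHit]:
    """Collapse queries whose best subject loci reciprocally overlap >=80%.

    Queries are clustered by single-linkage on the overlap relation of
    their best hits; the representative of each cluster is the hit with
    the smallest E-value (ties by bit score then query id).
    """
    best: dict[str, HomologyHit] = {}
    for h in sorted(hits, key=lambda h: (h.e_value, -h.bit_score, h.query_id)):
        best.setdefault(h.query_id, h)
    ids = sorted(best)
    parent = {q: q for q in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ha, hb = best[a], best[b]
            if ha.subject_id != hb.subject_id:
                continue
            ov = min(ha.s_end, hb.s_end) - max(ha.s_start, hb.s_start)
            if ov <= 0:
                continue
            if ov >= 0.8 * (ha.s_end - ha.s_start) and ov >= 0.8 * (hb.s_end - hb.s_start):
                parent[find(a)] = find(b)
    clusters: dict[str, list[str]] = {}
    for q in ids:
        clusters.setdefault(find(q), []).append(q)
    reps = []
    for members in clusters.values():
        reps.append(
            min(
                (best[q] for q in members),
                key=lambda h: (h.e_value, -h.bit_score, h.query_id),
            )
        )
    reps.sort(key=lambda h: (h.e_value, -h.bit_score, h.query_id))
    return reps
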