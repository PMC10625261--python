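"""Cross-genome presence/absence classification of transposon insertions.

For each well-defined element, 350 bp of flanking sequence is taken on
each side (the TSD copies fall inside the flanks) and each flank is
mapped to the target genome independently.  The joint outcome of the two
flank searches is one of six categories:

=============  ===========================================================
A_SHARED       both flanks map uniquely, collinear, with an element-length
               gap that masks to the element's family — insertion present
B_ABSENT       both flanks map uniquely with (nearly) no gap: the empty,
               pre-insertion site — insertion absent
C_MULTI_BOTH   both flanks hit multiple places at the same identity
D_MULTI_ONE    one flank unique, the other multi-mapping (or a unique
               pair whose geometry fits neither A nor B)
E_MISSING_ONE  one flank not found at all
F_MISSING_BOTH neither flank found
=============  ===========================================================

The categories partition the probed set: every element receives exactly
one call per target genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .align import HomologyHit, SubjectIndex, filter_significant, search_dna_vs_dna
from .boundaries import IntactElement
from .core import PipelineParams, SequenceRecord

CATEGORIES = (
    "A_SHARED",
    "B_ABSENT",
    "C_MULTI_BOTH",
    "D_MULTI_ONE",
    "E_MISSING_ONE",
    "F_MISSING_BOTH",
)


@dataclass(frozen=True)
class FlankProbe:
    element_id: str
    left_flank: str
    right_flank: str
    clipped: bool

    @property
    def probe(self) -> str:
        """The merged 700-bp probe (left + right concatenated)."""
        return self.left_flank + self.right_flank


@dataclass
class FlankMapping:
    label: str  # UNIQUE | MULTI | NONE
    hits: list[HomologyHit] = field(default_factory=list)

    @property
    def best(self) -> Optional[HomologyHit]:
        return self.hits[0] if self.hits else None


@dataclass
class OrthologyCall:
    element_id: str
    family: str
    target_genome_id: str
    category: str
    reason: str = ""
    left_hit: Optional[HomologyHit] = None
    right_hit: Optional[HomologyHit] = None
    gap: Optional[int] = None


def make_flank_probe(
    genome: Sequence[SequenceRecord],
    element: IntactElement,
    params: Optional[PipelineParams] = None,
) -> FlankProbe:
    """Extract probe_flank bp immediately outside the element body.

    Flanks clipped at a chromosome end are flagged; an element whose
    flanks are both empty (spanning the whole chromosome) is an error.
    """
    params = params or PipelineParams()
    seqs = {r.id: r.seq for r in genome}
    iv = element.location
    chrom = seqs[iv.chrom]
    left = chrom[max(0, iv.start - params.probe_flank) : iv.start]
    right = chrom[iv.end : iv.end + params.probe_flank]
    if not left and not right:
        raise ValueError(f"element {element.name} spans its whole chromosome")
    clipped = len(left) < params.probe_flank or len(right) < params.probe_flank
    return FlankProbe(
        element_id=element.name, left_flank=left, right_flank=right, clipped=clipped
    )


def map_flanks(
    probe: FlankProbe,
    target: SubjectIndex | Sequence[SequenceRecord],
    params: Optional[PipelineParams] = None,
) -> tuple[FlankMapping, FlankMapping]:
    """Search each flank independently and label its mapping uniqueness.

    UNIQUE: the best hit's identity exceeds the runner-up by at least
    ``unique_margin`` percentage points (or there is no runner-up);
    MULTI: two or more significant hits within the margin; NONE: no
    significant hit.
    """
    params = params or PipelineParams()
    index = target if isinstance(target, SubjectIndex) else SubjectIndex(list(target), params.word_size)
    out = []
    for side, flank in (("L", probe.left_flank), ("R", probe.right_flank)):
        if not flank:
            out.append(FlankMapping("NONE", []))
            continue
        rec = SequenceRecord(f"{probe.element_id}_{side}", flank)
        hits = filter_significant(search_dna_vs_dna(rec, index, params), params)
        hits.sort(key=lambda h: (-h.percent_identity, -h.bit_score, h.subject_id, h.s_start))
        if not hits:
            out.append(FlankMapping("NONE", []))
        elif len(hits) == 1 or hits[0].percent_identity - hits[1].percent_identity >= params.unique_margin:
            out.append(FlankMapping("UNIQUE", hits))
        else:
            out.append(FlankMapping("MULTI", hits))
    return out[0], out[1]


def classify_orthology(
    left: FlankMapping,
    right: FlankMapping,
    element: IntactElement,
    target: SubjectIndex | Sequence[SequenceRecord],
    target_genome_id: str,
    params: Optional[PipelineParams] = None,
) -> OrthologyCall:
    """Combine the two flank mappings into one of the six categories."""
    params = params or PipelineParams()
    index = target if isinstance(target, SubjectIndex) else SubjectIndex(list(target), params.word_size)
    call = OrthologyCall(
        element_id=element.name,
        family=element.family,
        target_genome_id=target_genome_id,
        category="",
        left_hit=left.best,
        right_hit=right.best,
    )
    labels = (left.label, right.label)
    if labels == ("NONE", "NONE"):
        call.category, call.reason = "F_MISSING_BOTH", "no hit for either flank"
        return call
    if "NONE" in labels:
        call.category, call.reason = "E_MISSING_ONE", "one flank not found"
        return call
    if labels == ("MULTI", "MULTI"):
        call.category, call.reason = "C_MULTI_BOTH", "both flanks multi-mapping"
        return call
    if "MULTI" in labels:
        call.category, call.reason = "D_MULTI_ONE", "one flank multi-mapping"
        return call

    lh, rh = left.best, right.best
    assert lh is not None and rh is not None
    if lh.subject_id != rh.subject_id or lh.strand != rh.strand:
        call.category = "D_MULTI_ONE"
        call.reason = "unique flanks on different chromosomes or strands"
        return call
    if lh.strand == "+":
        gap = rh.s_start - lh.s_end
        lo, hi = lh.s_end, rh.s_start
    else:
        gap = lh.s_start - rh.s_end
        lo, hi = rh.s_end, lh.s_start
    call.gap = gap
    tsd_slack = params.tsd_len_max + params.boundary_jitter
    if -tsd_slack <= gap <= params.empty_site_gap_max:
        call.category, call.reason = "B_ABSENT", "flanks abut: empty site"
        return call
    elen = len(element.element_seq)
    if (1 - params.shared_len_tol) * elen <= gap <= (1 + params.shared_len_tol) * elen:
        if _interval_masks_to_family(index, lh.subject_id, lo, hi, element, params):
            call.category = "A_SHARED"
            call.reason = "element-length gap matching the family"
            return call
        call.category = "D_MULTI_ONE"
        call.reason = "element-length gap but no family homology"
        return call
    call.category = "D_MULTI_ONE"
    call.reason = f"unique pair with incompatible gap {gap}"
    return call


def _interval_masks_to_family(
    index: SubjectIndex,
    chrom: str,
    lo: int,
    hi: int,
    element: IntactElement,
    params: PipelineParams,
    min_cover: float = 0.5,
) -> bool:
    """Does the inter-flank interval align to the element family?"""
    if hi - lo <= 0:
        return False
    seqs = {r.id: r.seq for r in index.subjects}
    segment = SequenceRecord("segment", seqs[chrom][lo:hi])
    ref = SequenceRecord(element.family, element.element_seq)
    hits = [
        h
        for h in search_dna_vs_dna(ref, segment, params)
        if h.e_value < params.evalue_max and h.percent_identity >= params.mask_min_identity
    ]
    covered = sum(h.s_end - h.s_start for h in hits)
    return covered >= min_cover * (hi - lo)


def classify_element(
    genome: Sequence[SequenceRecord],
    element: IntactElement,
    target: SubjectIndex | Sequence[SequenceRecord],
    target_genome_id: str,
    params: Optional[PipelineParams] = None,
) -> OrthologyCall:
    """Probe one element against one target genome end to end."""
    params = params or PipelineParams()
    probe = make_flank_probe(genome, element, params)
    left, right = map_flanks(probe, target, params)
    return classify_orthology(left, right, element, target, target_genome_id, params)


def summarize_comparison(calls: Sequence[OrthologyCall]) -> pd.DataFrame:
    """Per-family x category counts with row/column totals.

    The six categories partition the probed elements, so every row sums
    to the family's probed count and the grand total to the number of
    calls.
    """
    df = pd.DataFrame(
        [(c.family, c.category) for c in calls], columns=["family", "category"]
    )
    if df.empty:
        return pd.DataFrame(columns=["family", *CATEGORIES, "total"])
    pivot = (
        df.groupby(["family", "category"]).size().unstack(fill_value=0)
    )
    for cat in CATEGORIES:
        if cat not in pivot.columns:
            pivot[cat] = 0
    pivot = pivot[list(CATEGORIES)]
    pivot["total"] = pivot.sum(axis=1)
    pivot.loc["all"] = pivot.sum(axis=0)
    return pivot.reset_index().rename(columns={"index": "family"})


def calls_to_table(calls: Sequence[OrthologyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": c.element_id,
                "family": c.family,
                "target_genome": c.target_genome_id,
                "category": c.category,
                "gap": c.gap if c.gap is not None else ".",
                "reason": c.reason,
            }
            for c in calls
        ],
        columns=["element_id", "family", "target_genome", "category", "gap", "reason"],
    )
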