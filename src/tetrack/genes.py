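"""TE recruitment into gene transcripts: CDS vs UTR classification.

A gene model is a transcript with exon and CDS segmentation in genomic
coordinates; projecting it to transcript space partitions the transcript
into 5' UTR | CDS | 3' UTR.  Transcripts are scanned against the intact
element library and each TE-derived segment is assigned to the region
that contains at least 80% of it (otherwise MIXED).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core import Interval, PipelineParams, SequenceRecord
from .align import HomologyHit, filter_significant, search_dna_vs_dna

CONTAINMENT_FRAC = 0.8


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    strand: str
    exons: list[Interval]
    cds_segments: list[Interval]
    annotation_label: str = ""

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds_segments = sorted(self.cds_segments, key=lambda iv: iv.start)
        for cds in self.cds_segments:
            if not any(
                e.chrom == cds.chrom and e.start <= cds.start and cds.end <= e.end
                for e in self.exons
            ):
                raise ValueError(
                    f"{self.transcript_id}: CDS {cds} outside exons"
                )

    @property
    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)


def _genomic_to_transcript(gene: GeneModel, gpos: int) -> int:
    """Map a genomic position inside an exon to plus-orientation offset."""
    off = 0
    for e in gene.exons:
        if e.start <= gpos <= e.end:
            return off + (gpos - e.start)
        off += len(e)
    raise ValueError(f"position {gpos} not exonic in {gene.transcript_id}")


def transcript_to_regions(gene: GeneModel) -> dict[str, tuple[int, int]]:
    """Partition the transcript into UTR5 | CDS | UTR3 (transcript coords).

    Returns half-open intervals; UTRs may be empty.  Minus-strand models
    are flipped so coordinates run 5'→3' along the transcript.
    """
    L = gene.transcript_length
    if not gene.cds_segments:
        raise ValueError(f"{gene.transcript_id}: no CDS segments")
    lo = min(_genomic_to_transcript(gene, c.start) for c in gene.cds_segments)
    hi = max(_genomic_to_transcript(gene, c.end) for c in gene.cds_segments)
    if gene.strand == "-":
        lo, hi = L - hi, L - lo
    return {"UTR5": (0, lo), "CDS": (lo, hi), "UTR3": (hi, L)}


def classify_overlap(
    hit_start: int, hit_end: int, regions: dict[str, tuple[int, int]]
) -> str:
    """Region containing >=80% of the hit, else MIXED."""
    if hit_end <= hit_start:
        raise ValueError("empty hit interval")
    span = hit_end - hit_start
    for name, (a, b) in regions.items():
        ov = min(hit_end, b) - max(hit_start, a)
        if ov >= CONTAINMENT_FRAC * span:
            return name
    return "MIXED"


@dataclass(frozen=True)
class TEGeneOverlap:
    gene_id: str
    transcript_id: str
    family: str
    t_start: int
    t_end: int
    region_class: str
    percent_identity: float


def scan_transcripts(
    transcripts: Sequence[SequenceRecord],
    te_library: Sequence[SequenceRecord],
    params: Optional[PipelineParams] = None,
) -> list[HomologyHit]:
    """Significant element-vs-transcript hits, best region per pair.

    Each library element is the query and each transcript the subject;
    only the best-scoring significant hit per (transcript, family) pair
    is kept.
    """
    params = params or PipelineParams()
    best: dict[tuple[str, str], HomologyHit] = {}
    for element in te_library:
        for hit in filter_significant(
            search_dna_vs_dna(element, list(transcripts), params), params
        ):
            key = (hit.subject_id, hit.query_id)
            cur = best.get(key)
            if cur is None or (hit.e_value, -hit.bit_score) < (cur.e_value, -cur.bit_score):
                best[key] = hit
    return [best[k] for k in sorted(best)]


def annotate_overlaps(
    hits: Sequence[HomologyHit], models: Sequence[GeneModel]
) -> list[TEGeneOverlap]:
    """Classify transcript hits against their gene models.

    Hits on transcripts without a gene model (e.g. raw element
    transcripts) are skipped — only annotated genes are classified.
    """
    by_tid = {m.transcript_id: m for m in models}
    out = []
    for h in hits:
        model = by_tid.get(h.subject_id)
        if model is None:
            continue
        regions = transcript_to_regions(model)
        cls = classify_overlap(h.s_start, h.s_end, regions)
        out.append(
            TEGeneOverlap(
                gene_id=model.gene_id,
                transcript_id=model.transcript_id,
                family=h.query_id,
                t_start=h.s_start,
                t_end=h.s_end,
                region_class=cls,
                percent_identity=h.percent_identity,
            )
        )
    return out


def summarize_gene_overlap(overlaps: Sequence[TEGeneOverlap]) -> dict:
    """Per-class gene counts and the CDS-recruitment percentage.

    Genes (not segments) are counted; a gene's class is the class of its
    best-identity overlap.  The CDS percentage is reported both over all
    classified genes and excluding MIXED calls.
    """
    if not overlaps:
        return {"n_genes": 0, "counts": {}, "cds_pct": None, "cds_pct_excl_mixed": None}
    per_gene: dict[str, TEGeneOverlap] = {}
    for ov in overlaps:
        cur = per_gene.get(ov.gene_id)
        if cur is None or ov.percent_identity > cur.percent_identity:
            per_gene[ov.gene_id] = ov
    counts: dict[str, int] = {}
    for ov in per_gene.values():
        counts[ov.region_class] = counts.get(ov.region_class, 0) + 1
    n = len(per_gene)
    n_cds = counts.get("CDS", 0)
    n_excl = n - counts.get("MIXED", 0)
    return {
        "n_genes": n,
        "counts": dict(sorted(counts.items())),
        "cds_pct": round(100.0 * n_cds / n, 1),
        "cds_pct_excl_mixed": round(100.0 * n_cds / n_excl, 1) if n_excl else None,
    }


def overlaps_to_table(overlaps: Sequence[TEGeneOverlap]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": o.gene_id,
                "transcript_id": o.transcript_id,
                "family": o.family,
                "t_start": o.t_start,
                "t_end": o.t_end,
                "region_class": o.region_class,
                "percent_identity": o.percent_identity,
            }
            for o in overlaps
        ],
        columns=[
            "gene_id", "transcript_id", "family", "t_start", "t_end",
            "region_class", "percent_identity",
        ],
    )
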