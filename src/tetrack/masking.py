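"""Genome-wide family masking and copy curation.

Intact elements serve as a repeat library: every genomic copy above the
identity floor is annotated (no low-complexity pre-filter), overlapping
same-family fragments are merged, and each merged copy is curated as
well_defined or fragmental.  A copy is well defined only when (a) its
alignment reaches both reference termini within 10 bp, (b) the family's
terminal feature is detectable on the copy itself, and (c) an exact TSD
flanks it; curation refines the copy boundaries to the TSD-consistent
placement.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .align import SubjectIndex, search_dna_vs_dna
from .boundaries import IntactElement, _element_at, CandidateLocus
from .core import Interval, PipelineParams, SequenceRecord
from .io import MaskTableRow

TERMINUS_TOL = 10  # bp of slack when checking reference-terminus coverage


def mask_genome(
    genome: Sequence[SequenceRecord] | SubjectIndex,
    library: Sequence[SequenceRecord],
    params: Optional[PipelineParams] = None,
) -> list[MaskTableRow]:
    """Annotate all genomic copies of the library families.

    Each library sequence is searched against the genome; hits passing
    the E-value threshold and the identity floor are kept, and
    same-family hits that overlap or sit closer than ``mask_merge_gap``
    are merged into one interval annotated with the best identity and
    the union of reference coverage.
    """
    params = params or PipelineParams()
    index = genome if isinstance(genome, SubjectIndex) else SubjectIndex(list(genome), params.word_size)
    if not library:
        return []
    rows: list[MaskTableRow] = []
    for element in library:
        hits = [
            h
            for h in search_dna_vs_dna(element, index, params)
            if h.e_value < params.evalue_max
            and h.percent_identity >= params.mask_min_identity
        ]
        by_chrom: dict[str, list] = {}
        for h in hits:
            by_chrom.setdefault(h.subject_id, []).append(h)
        for chrom, hs in sorted(by_chrom.items()):
            hs.sort(key=lambda h: (h.s_start, h.s_end))
            group = [hs[0]]
            for h in hs[1:]:
                if h.s_start < group[-1].s_end + params.mask_merge_gap:
                    group.append(h)
                else:
                    rows.append(_merge_group(chrom, element.id, group))
                    group = [h]
            rows.append(_merge_group(chrom, element.id, group))
    rows.sort(key=lambda r: (r.chrom, r.start, r.family_name))
    return rows


def _merge_group(chrom: str, family: str, group: list) -> MaskTableRow:
    best = max(group, key=lambda h: h.bit_score)
    return MaskTableRow(
        chrom=chrom,
        start=min(h.s_start for h in group),
        end=max(h.s_end for h in group),
        strand=best.strand,
        family_name=family,
        percent_identity=best.percent_identity,
        ref_start=min(h.q_start for h in group),
        ref_end=max(h.q_end for h in group),
        boundary_status="unset",
    )


def curate_boundaries(
    masked: Sequence[MaskTableRow],
    genome: Sequence[SequenceRecord],
    library: Sequence[IntactElement],
    params: Optional[PipelineParams] = None,
) -> list[MaskTableRow]:
    """Set boundary_status for every masked copy (and refine coordinates).

    A copy is well_defined when its alignment covers both reference
    termini (within 10 bp), the family's terminal feature is present at
    the copy, and an exact TSD flanks the TSD-consistent placement; the
    returned row then carries the refined boundaries.  Everything else is
    fragmental.
    """
    params = params or PipelineParams()
    seqs = {r.id: r.seq for r in genome}
    lib = {el.family: el for el in library}
    pad = params.tsd_len_max + params.boundary_jitter + 5
    out: list[MaskTableRow] = []
    for row in masked:
        el = lib.get(row.family_name)
        status = "fragmental"
        refined = row
        if el is not None:
            ref_len = len(el.element_seq)
            covers = row.ref_start <= TERMINUS_TOL and row.ref_end >= ref_len - TERMINUS_TOL
            if covers:
                chrom_seq = seqs[row.chrom]
                w0 = max(0, row.start - pad)
                w1 = min(len(chrom_seq), row.end + pad)
                pseudo = CandidateLocus(
                    source_hit=_pseudo_hit(row),
                    window=Interval(row.chrom, w0, w1),
                    window_seq=chrom_seq[w0:w1],
                )
                placed = _element_at(pseudo, row.start - w0, row.end - w0, row.family_name, params)
                if placed is not None and placed.features.terminal_type == el.features.terminal_type:
                    status = "well_defined"
                    refined = MaskTableRow(
                        chrom=row.chrom,
                        start=placed.location.start,
                        end=placed.location.end,
                        strand=row.strand,
                        family_name=row.family_name,
                        percent_identity=row.percent_identity,
                        ref_start=row.ref_start,
                        ref_end=row.ref_end,
                        boundary_status=status,
                    )
        if status != "well_defined":
            refined = MaskTableRow(
                **{**row.__dict__, "boundary_status": "fragmental"}
            )
        out.append(refined)
    return out


def _pseudo_hit(row: MaskTableRow):
    from .align import HomologyHit

    return HomologyHit(
        query_id=row.family_name,
        subject_id=row.chrom,
        q_start=row.ref_start,
        q_end=row.ref_end,
        s_start=row.start,
        s_end=row.end,
        strand=row.strand,
        frame=None,
        aln_len=row.end - row.start,
        percent_identity=row.percent_identity,
        raw_score=0,
        bit_score=0.0,
        e_value=0.0,
    )


def copy_number_summary(masked: Sequence[MaskTableRow]) -> pd.DataFrame:
    """Per-family, per-chromosome copy counts."""
    if not masked:
        return pd.DataFrame(columns=["family", "chrom", "count"])
    df = pd.DataFrame(
        [(r.family_name, r.chrom) for r in masked], columns=["family", "chrom"]
    )
    out = df.groupby(["family", "chrom"]).size().reset_index(name="count")
    return out.sort_values(["family", "chrom"]).reset_index(drop=True)


def distribution_bins(
    masked: Sequence[MaskTableRow],
    bin_size: int,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Binned per-chromosome repeat density (interval -> bin of its start).

    With ``chrom_lengths`` supplied, all bins are materialized (zeros
    included); otherwise only populated bins appear.  Bin counts always
    sum to the number of masked intervals.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts: dict[tuple[str, int], int] = {}
    if chrom_lengths:
        for chrom, ln in sorted(chrom_lengths.items()):
            for b in range(ln // bin_size + 1):
                counts[(chrom, b)] = 0
    for r in masked:
        key = (r.chrom, r.start // bin_size)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"chrom": c, "bin_index": b, "bin_start": b * bin_size, "count": n}
        for (c, b), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "bin_index", "bin_start", "count"])


def plot_distribution(bins: pd.DataFrame, path: str) -> None:
    """Render a per-chromosome density plot (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(bins["chrom"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2 * max(1, len(chroms))), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = bins[bins["chrom"] == chrom]
        ax.bar(sub["bin_start"], sub["count"], width=0.9 * (sub["bin_start"].diff().median() or 1))
        ax.set_ylabel(chrom)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
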