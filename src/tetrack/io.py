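"""Readers and writers for the formats the pipeline touches.

FASTA goes through Bio.SeqIO; GFF3 is written directly (the attribute
vocabulary is fixed: ID, Name, family, superfamily, tsd, terminal, status)
and gene models are read back with gffutils.  Tabular reports are TSV via
pandas so every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import Interval, SequenceRecord, to_gff3_coords

MASK_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "family_name",
    "percent_identity",
    "ref_start",
    "ref_end",
    "boundary_status",
]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Raises on empty files, duplicate ids, and non-{A,C,G,T,N} characters.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _gff3_escape(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def write_gff3(features: Sequence[dict], path: str | Path, source: str = "tetrack") -> None:
    """Write generic features to GFF3.

    Each feature dict needs ``interval`` (Interval), ``ftype``; optional
    ``attributes`` mapping and ``score``/``phase``/``parent``.
    """
    lines = ["##gff-version 3"]
    for feat in features:
        iv: Interval = feat["interval"]
        start1, end1 = to_gff3_coords(iv)
        attrs = dict(feat.get("attributes", {}))
        if "parent" in feat:
            attrs["Parent"] = feat["parent"]
        attr_str = ";".join(f"{k}={_gff3_escape(v)}" for k, v in attrs.items()) or "."
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    source,
                    feat["ftype"],
                    str(start1),
                    str(end1),
                    str(feat.get("score", ".")),
                    iv.strand,
                    str(feat.get("phase", ".")),
                    attr_str,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def elements_to_gff3(elements, path: str | Path) -> None:
    """Write intact elements (see boundaries.IntactElement) to GFF3."""
    feats = []
    for el in elements:
        attrs = {
            "ID": el.name,
            "Name": el.name,
            "family": el.family,
            "superfamily": el.superfamily,
            "terminal": el.features.terminal_type,
        }
        if el.features.tsd is not None:
            attrs["tsd"] = el.features.tsd.seq
        feats.append(
            {"interval": el.location, "ftype": "transposable_element", "attributes": attrs}
        )
    write_gff3(feats, path)


def read_gff3_elements(path: str | Path) -> list[dict]:
    """Read transposable_element features back as plain dicts."""
    out = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        chrom, _src, ftype, start1, end1, _score, strand, _phase, attr_str = raw.split("\t")
        if ftype != "transposable_element":
            continue
        attrs = dict(kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv)
        out.append(
            {
                "interval": Interval(chrom, int(start1) - 1, int(end1), strand),
                "attributes": attrs,
            }
        )
    return out


def load_gene_models(path: str | Path):
    """Load gene models from GFF3 via gffutils (in-memory db).

    Returns a list of genes.GeneModel; import is deferred to avoid a cycle.
    """
    from .genes import GeneModel

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = [
            Interval(f.seqid, f.start - 1, f.end, mrna.strand)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        ]
        cds = [
            Interval(f.seqid, f.start - 1, f.end, mrna.strand)
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        label = mrna.attributes.get("annotation_label", [""])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
                annotation_label=label,
            )
        )
    return models


# -- mask table ---------------------------------------------------------------


@dataclass(frozen=True)
class MaskTableRow:
    """One masked repeat interval, analogous to a repeat-annotation row."""

    chrom: str
    start: int
    end: int
    strand: str
    family_name: str
    percent_identity: float
    ref_start: int
    ref_end: int
    boundary_status: str = "unset"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid mask interval [{self.start},{self.end})")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0,100]")


def write_mask_table(rows: Sequence[MaskTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [[getattr(r, c) for c in MASK_TABLE_COLUMNS] for r in rows],
        columns=MASK_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_mask_table(path: str | Path) -> list[MaskTableRow]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty mask table {path}") from exc
    if list(df.columns) != MASK_TABLE_COLUMNS:
        raise ValueError(f"{path}: unexpected header {list(df.columns)}")
    rows = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            rows.append(
                MaskTableRow(
                    chrom=rec.chrom,
                    start=int(rec.start),
                    end=int(rec.end),
                    strand=rec.strand,
                    family_name=rec.family_name,
                    percent_identity=float(rec.percent_identity),
                    ref_start=int(rec.ref_start),
                    ref_end=int(rec.ref_end),
                    boundary_status=rec.boundary_status,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return rows
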