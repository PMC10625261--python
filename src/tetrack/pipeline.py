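"""End-to-end orchestration: simulate -> scan -> anchor -> define ->
mask -> compare -> gene-overlap -> report.

Stage outputs are plain files (FASTA / GFF3 / TSV) under one output
directory; a JSON manifest records the parameter snapshot, input
digests, per-stage timings and the seed.  Re-running with the same
inputs and seed reproduces identical outputs; partial runs resume from
whatever stage outputs already exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import report as report_mod
from .align import (
    SubjectIndex,
    deduplicate_queries,
    filter_significant,
    search_dna_vs_dna,
    search_protein_vs_dna,
)
from .boundaries import IntactElement, StructuralFeatures, TsdCandidate, define_element, extract_locus
from .core import Interval, PipelineParams, SequenceRecord
from .genes import annotate_overlaps, overlaps_to_table, scan_transcripts, summarize_gene_overlap
from .io import (
    elements_to_gff3,
    load_gene_models,
    read_fasta,
    read_gff3_elements,
    read_mask_table,
    write_fasta,
    write_gff3,
    write_mask_table,
)
from .masking import copy_number_summary, curate_boundaries, distribution_bins, mask_genome
from .polymorphism import calls_to_table, classify_element, summarize_comparison
from .simulate import (
    default_family_specs,
    derive_accession,
    simulate_genome,
    simulate_transcripts,
    transposase_queries,
    write_truth,
)

log = logging.getLogger("tetrack")

STAGES = (
    "simulate",
    "scan-cdna",
    "anchor",
    "define-elements",
    "mask",
    "compare",
    "gene-overlap",
    "report",
)

#: files each stage must find (produced by earlier stages)
_REQUIRES = {
    "simulate": (),
    "scan-cdna": ("transcripts.fasta", "transposases.fasta"),
    "anchor": ("ref.fasta", "te_transcripts.fasta"),
    "define-elements": ("ref.fasta", "anchored_hits.tsv"),
    "mask": ("ref.fasta", "elements.fasta", "elements.gff3"),
    "compare": ("ref.fasta", "elements.fasta", "mask_table.tsv"),
    "gene-overlap": ("transcripts.fasta", "genes.gff3", "elements.fasta"),
    "report": ("scan_hits.tsv", "mask_table.tsv", "comparison_calls.tsv", "gene_overlaps.tsv"),
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _hits_to_table(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id, "subject_id": h.subject_id,
                "q_start": h.q_start, "q_end": h.q_end,
                "s_start": h.s_start, "s_end": h.s_end,
                "strand": h.strand, "frame": h.frame if h.frame is not None else ".",
                "aln_len": h.aln_len, "percent_identity": h.percent_identity,
                "raw_score": h.raw_score, "bit_score": h.bit_score, "e_value": h.e_value,
            }
            for h in hits
        ],
        columns=[
            "query_id", "subject_id", "q_start", "q_end", "s_start", "s_end",
            "strand", "frame", "aln_len", "percent_identity", "raw_score",
            "bit_score", "e_value",
        ],
    )


class PipelineRun:
    """One pipeline invocation bound to an output directory."""

    def __init__(
        self,
        outdir: str | Path,
        params: Optional[PipelineParams] = None,
        seed: int = 0,
        sim_options: Optional[dict] = None,
    ):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.params = params or PipelineParams()
        self.seed = seed
        self.sim_options = dict(sim_options or {})
        self.manifest: dict = {
            "seed": seed,
            "params": {k: getattr(self.params, k) for k in vars(self.params)},
            "stages": {},
        }

    # -- helpers -------------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _check_requirements(self, stage: str) -> None:
        missing = [f for f in _REQUIRES[stage] if not self._path(f).exists()]
        if missing:
            raise FileNotFoundError(
                f"stage {stage!r} requires {missing} — run the producing stage first"
            )

    def _record(self, stage: str, t0: float, outputs: Sequence[str]) -> None:
        self.manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "outputs": {name: _digest(self._path(name)) for name in outputs},
        }

    # -- stages --------------------------------------------------------------

    def stage_simulate(self) -> None:
        t0 = time.time()
        opts = self.sim_options
        chrom_lengths = opts.get("chrom_lengths", {"chr1": 1_000_000, "chr2": 1_000_000})
        specs = opts.get("specs") or default_family_specs(
            divergence=opts.get("divergence", 0.0),
            fragmentation_rate=opts.get("fragmentation_rate", 0.3),
        )
        genome, truth = simulate_genome(
            chrom_lengths, specs, seed=self.seed,
            n_duplicated_flanks=opts.get("n_duplicated_flanks", 0),
        )
        write_fasta(genome, self._path("ref.fasta"))
        n_acc = opts.get("n_accessions", 3)
        absence_prob = opts.get("absence_prob", 0.1)
        for k in range(n_acc):
            acc = derive_accession(truth, absence_prob, seed=self.seed + 1 + k, genome_id=f"acc{k + 1}")
            write_fasta(acc, self._path(f"acc{k + 1}.fasta"))
        transcripts, models, _labels = simulate_transcripts(
            genome, truth,
            n_clean_genes=opts.get("n_clean_genes", 10),
            n_te_genes=opts.get("n_te_genes", 9),
            n_full_te=opts.get("n_full_te", 5),
            seed=self.seed + 100,
        )
        write_fasta(transcripts, self._path("transcripts.fasta"))
        _write_gene_models(models, self._path("genes.gff3"))
        write_fasta(
            [SequenceRecord(fam.name, fam.record.seq) for fam in truth.families.values()],
            self._path("family_refs.fasta"),
        )
        proteins = transposase_queries(list(truth.families.values()))
        with open(self._path("transposases.fasta"), "w") as fh:
            for p in proteins:
                fh.write(f">{p.id} {p.superfamily}\n{p.aaseq}\n")
        write_truth(truth, self.outdir)
        self.truth = truth
        self._record("simulate", t0, ["ref.fasta", "transcripts.fasta", "genes.gff3"])

    def stage_scan_cdna(self) -> None:
        self._check_requirements("scan-cdna")
        t0 = time.time()
        transcripts = read_fasta(self._path("transcripts.fasta"))
        proteins = _read_protein_fasta(self._path("transposases.fasta"))
        hits = []
        for prot in proteins:
            hits.extend(
                filter_significant(search_protein_vs_dna(prot, transcripts, self.params), self.params)
            )
        _hits_to_table(hits).to_csv(self._path("scan_hits.tsv"), sep="\t", index=False)
        te_ids = sorted({h.subject_id for h in hits})
        by_id = {r.id: r for r in transcripts}
        write_fasta([by_id[t] for t in te_ids], self._path("te_transcripts.fasta"))
        log.info("scan-cdna: %d TE-related transcripts", len(te_ids))
        self._record("scan-cdna", t0, ["scan_hits.tsv", "te_transcripts.fasta"])

    def stage_anchor(self) -> None:
        self._check_requirements("anchor")
        t0 = time.time()
        genome = read_fasta(self._path("ref.fasta"))
        index = SubjectIndex(genome, self.params.word_size)
        queries = read_fasta(self._path("te_transcripts.fasta"))
        all_hits = []
        for q in queries:
            all_hits.extend(filter_significant(search_dna_vs_dna(q, index, self.params), self.params))
        reps = deduplicate_queries(all_hits)
        rep_ids = {h.query_id for h in reps}
        kept = [h for h in all_hits if h.query_id in rep_ids]
        _hits_to_table(kept).to_csv(self._path("anchored_hits.tsv"), sep="\t", index=False)
        log.info("anchor: %d hits for %d unique transcripts", len(kept), len(rep_ids))
        self._record("anchor", t0, ["anchored_hits.tsv"])

    def stage_define_elements(self) -> None:
        self._check_requirements("define-elements")
        t0 = time.time()
        genome = read_fasta(self._path("ref.fasta"))
        df = pd.read_csv(self._path("anchored_hits.tsv"), sep="\t")
        from .align import HomologyHit

        elements: list[IntactElement] = []
        for qid, sub in df.groupby("query_id"):
            sub = sub.sort_values("bit_score", ascending=False).head(12)
            loci = []
            for rec in sub.itertuples(index=False):
                hit = HomologyHit(
                    query_id=rec.query_id, subject_id=rec.subject_id,
                    q_start=int(rec.q_start), q_end=int(rec.q_end),
                    s_start=int(rec.s_start), s_end=int(rec.s_end),
                    strand=rec.strand, frame=None, aln_len=int(rec.aln_len),
                    percent_identity=float(rec.percent_identity),
                    raw_score=int(rec.raw_score), bit_score=float(rec.bit_score),
                    e_value=float(rec.e_value),
                )
                loci.append(extract_locus(genome, hit, self.params))
            el = define_element(loci, family_name=str(qid), params=self.params)
            if el is not None:
                elements.append(el)
        # distinct transcripts can define the same genomic element
        elements = _dedupe_elements(elements)
        for i, el in enumerate(elements, 1):
            el.name = f"el{i:03d}_{el.family}"
        elements_to_gff3(elements, self._path("elements.gff3"))
        write_fasta(
            [SequenceRecord(el.name, el.element_seq) for el in elements],
            self._path("elements.fasta"),
        )
        log.info("define-elements: %d intact elements", len(elements))
        self._record("define-elements", t0, ["elements.gff3", "elements.fasta"])

    def _load_elements(self) -> list[IntactElement]:
        recs = {r.id: r for r in read_fasta(self._path("elements.fasta"))}
        out = []
        for feat in read_gff3_elements(self._path("elements.gff3")):
            attrs = feat["attributes"]
            name = attrs["ID"]
            tsd = attrs.get("tsd")
            features = StructuralFeatures(
                tsd=TsdCandidate(tsd, 0, 0, 0) if tsd else None,
                terminal_type=attrs.get("terminal", "NONE"),
            )
            out.append(
                IntactElement(
                    name=name,
                    family=attrs.get("family", name),
                    location=feat["interval"],
                    superfamily=attrs.get("superfamily", "UNCLASSIFIED"),
                    features=features,
                    element_seq=recs[name].seq,
                )
            )
        return out

    def stage_mask(self) -> None:
        self._check_requirements("mask")
        t0 = time.time()
        genome = read_fasta(self._path("ref.fasta"))
        elements = self._load_elements()
        library = [SequenceRecord(el.name, el.element_seq) for el in elements]
        masked = mask_genome(genome, library, self.params)
        curated = curate_boundaries(
            masked, genome,
            [_rename_family(el) for el in elements],
            self.params,
        )
        write_mask_table(curated, self._path("mask_table.tsv"))
        copy_number_summary(curated).to_csv(self._path("copy_numbers.tsv"), sep="\t", index=False)
        chrom_lengths = {r.id: len(r.seq) for r in genome}
        distribution_bins(curated, bin_size=100_000, chrom_lengths=chrom_lengths).to_csv(
            self._path("distribution_bins.tsv"), sep="\t", index=False
        )
        n_wd = sum(1 for r in curated if r.boundary_status == "well_defined")
        log.info("mask: %d copies, %d well-defined", len(curated), n_wd)
        self._record("mask", t0, ["mask_table.tsv", "copy_numbers.tsv", "distribution_bins.tsv"])

    def stage_compare(self) -> None:
        self._check_requirements("compare")
        t0 = time.time()
        genome = read_fasta(self._path("ref.fasta"))
        elements = self._load_elements()
        rows = [r for r in read_mask_table(self._path("mask_table.tsv")) if r.boundary_status == "well_defined"]
        by_family = {el.name: el for el in elements}
        probed: list[IntactElement] = []
        for i, row in enumerate(rows, 1):
            tmpl = by_family[row.family_name]
            probed.append(
                IntactElement(
                    name=f"{row.family_name}_c{i:03d}",
                    family=row.family_name,
                    location=Interval(row.chrom, row.start, row.end, row.strand),
                    superfamily=tmpl.superfamily,
                    features=tmpl.features,
                    element_seq=genome_slice(genome, row),
                )
            )
        calls = []
        targets = sorted(self.outdir.glob("acc*.fasta"))
        for tpath in targets:
            target = read_fasta(tpath)
            index = SubjectIndex(target, self.params.word_size)
            gid = tpath.stem
            for el in probed:
                calls.append(classify_element(genome, el, index, gid, self.params))
        calls_to_table(calls).to_csv(self._path("comparison_calls.tsv"), sep="\t", index=False)
        summarize_comparison(calls).to_csv(self._path("comparison_summary.tsv"), sep="\t", index=False)
        log.info("compare: %d calls over %d targets", len(calls), len(targets))
        self._record("compare", t0, ["comparison_calls.tsv", "comparison_summary.tsv"])

    def stage_gene_overlap(self) -> None:
        self._check_requirements("gene-overlap")
        t0 = time.time()
        transcripts = read_fasta(self._path("transcripts.fasta"))
        library = read_fasta(self._path("elements.fasta"))
        models = load_gene_models(self._path("genes.gff3"))
        hits = scan_transcripts(transcripts, library, self.params)
        overlaps = annotate_overlaps(hits, models)
        overlaps_to_table(overlaps).to_csv(self._path("gene_overlaps.tsv"), sep="\t", index=False)
        summary = summarize_gene_overlap(overlaps)
        (self._path("gene_overlap_summary.json")).write_text(json.dumps(summary, indent=2))
        log.info("gene-overlap: %s", summary)
        self._record("gene-overlap", t0, ["gene_overlaps.tsv", "gene_overlap_summary.json"])

    def stage_report(self) -> dict:
        self._check_requirements("report")
        t0 = time.time()
        rep = report_from_outputs(self.outdir)
        (self._path("report.json")).write_text(json.dumps(rep, indent=2))
        self._record("report", t0, ["report.json"])
        return rep

    # -- driver --------------------------------------------------------------

    def run(self, stages: Optional[Sequence[str]] = None, resume: bool = True) -> dict:
        todo = list(stages or STAGES)
        unknown = set(todo) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        fn = {
            "simulate": self.stage_simulate,
            "scan-cdna": self.stage_scan_cdna,
            "anchor": self.stage_anchor,
            "define-elements": self.stage_define_elements,
            "mask": self.stage_mask,
            "compare": self.stage_compare,
            "gene-overlap": self.stage_gene_overlap,
            "report": self.stage_report,
        }
        for stage in STAGES:
            if stage not in todo:
                continue
            marker = self.manifest["stages"].get(stage)
            if resume and marker is None and _stage_done(self.outdir, stage):
                log.info("stage %s: outputs exist, skipping", stage)
                continue
            log.info("stage %s: running", stage)
            fn[stage]()
        (self.outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return self.manifest


_STAGE_SENTINELS = {
    "simulate": "ref.fasta",
    "scan-cdna": "te_transcripts.fasta",
    "anchor": "anchored_hits.tsv",
    "define-elements": "elements.gff3",
    "mask": "mask_table.tsv",
    "compare": "comparison_calls.tsv",
    "gene-overlap": "gene_overlaps.tsv",
    "report": "report.json",
}


def _stage_done(outdir: Path, stage: str) -> bool:
    return (outdir / _STAGE_SENTINELS[stage]).exists()


def genome_slice(genome: Sequence[SequenceRecord], row) -> str:
    seqs = {r.id: r.seq for r in genome}
    return seqs[row.chrom][row.start : row.end]


def _rename_family(el: IntactElement) -> IntactElement:
    """Masking labels copies by library id, so curate under that id too."""
    out = IntactElement(
        name=el.name, family=el.name, location=el.location,
        superfamily=el.superfamily, features=el.features, element_seq=el.element_seq,
    )
    return out


def _dedupe_elements(elements: list[IntactElement]) -> list[IntactElement]:
    kept: list[IntactElement] = []
    for el in sorted(elements, key=lambda e: (e.location.chrom, e.location.start)):
        if any(
            el.location.overlaps(k.location)
            for k in kept
        ):
            continue
        kept.append(el)
    return kept


def _write_gene_models(models, path: Path) -> None:
    feats = []
    for m in models:
        span = Interval(m.exons[0].chrom, m.exons[0].start, m.exons[-1].end, m.strand)
        feats.append({"interval": span, "ftype": "gene", "attributes": {"ID": m.gene_id}})
        feats.append(
            {
                "interval": span, "ftype": "mRNA",
                "attributes": {
                    "ID": m.transcript_id, "Parent": m.gene_id,
                    "annotation_label": m.annotation_label,
                },
            }
        )
        for k, e in enumerate(m.exons, 1):
            feats.append(
                {"interval": e, "ftype": "exon",
                 "attributes": {"ID": f"{m.transcript_id}.exon{k}", "Parent": m.transcript_id}}
            )
        for k, c in enumerate(m.cds_segments, 1):
            feats.append(
                {"interval": c, "ftype": "CDS", "phase": 0,
                 "attributes": {"ID": f"{m.transcript_id}.cds{k}", "Parent": m.transcript_id}}
            )
    write_gff3(feats, path)


def _read_protein_fasta(path: Path):
    from .core import ProteinQuery

    out = []
    pid = None
    desc = ""
    buf: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if pid is not None:
                out.append(ProteinQuery(pid, "".join(buf), desc))
            head = line[1:].split(None, 1)
            pid = head[0]
            desc = head[1] if len(head) > 1 else ""
            buf = []
        else:
            buf.append(line.strip())
    if pid is not None:
        out.append(ProteinQuery(pid, "".join(buf), desc))
    return out


def report_from_outputs(outdir: str | Path) -> dict:
    """Re-derive every summary count from the stage TSVs (a pure view)."""
    outdir = Path(outdir)
    scan = pd.read_csv(outdir / "scan_hits.tsv", sep="\t")
    n_tx_total = len(read_fasta(outdir / "transcripts.fasta"))
    te_tx = sorted(scan["subject_id"].unique())
    mask_rows = read_mask_table(outdir / "mask_table.tsv")
    calls = pd.read_csv(outdir / "comparison_calls.tsv", sep="\t")
    overlaps = pd.read_csv(outdir / "gene_overlaps.tsv", sep="\t")
    per_family = {}
    for r in mask_rows:
        per_family.setdefault(r.family_name, [0, 0])
        per_family[r.family_name][0] += 1
        if r.boundary_status == "well_defined":
            per_family[r.family_name][1] += 1
    partitions = {}
    if not calls.empty:
        for gid, sub in calls.groupby("target_genome"):
            counts = sub["category"].value_counts().to_dict()
            partitions[gid] = {
                "shared": counts.get("A_SHARED", 0),
                "absent": counts.get("B_ABSENT", 0),
                "undetermined": int(len(sub)) - counts.get("A_SHARED", 0) - counts.get("B_ABSENT", 0),
                "total": int(len(sub)),
            }
    gene_classes = (
        overlaps.groupby("gene_id")["region_class"].first().value_counts().to_dict()
        if not overlaps.empty
        else {}
    )
    n_classified = sum(gene_classes.values())
    return {
        "n_transcripts": n_tx_total,
        "n_te_transcripts": len(te_tx),
        "te_transcript_rate_pct": report_mod.transcript_te_rate(len(te_tx), n_tx_total),
        "masked_copies": {k: v[0] for k, v in sorted(per_family.items())},
        "well_defined": {k: v[1] for k, v in sorted(per_family.items())},
        "comparison_partitions": partitions,
        "gene_overlap_classes": gene_classes,
        "cds_recruitment_pct": (
            report_mod.cds_recruitment_pct(gene_classes.get("CDS", 0), n_classified)
            if n_classified
            else None
        ),
    }
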