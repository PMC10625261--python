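"""Synthetic genomes, derived accessions, and transcript sets with ground truth.

The generator emulates the statistical structure the analysis assumes:
multi-copy transposon families of five structural archetypes planted into
an i.i.d. uniform background, flanked by exact target-site duplications
(TSDs); derived accessions in which each insertion is independently absent
(the empty site keeps a single TSD copy, the pre-insertion state); and a
transcript set mixing full-element transcripts, genes that recruited a TE
fragment into their CDS or UTR, and TE-free genes.

Archetypes and their terminal hallmarks:

========  =======================================================
LTR       identical direct terminal repeats, starting TG, ending CA
LINE      3' poly(A) tail, no terminal repeats
CACTA     terminal inverted repeats beginning with the CACTA motif
MARINER   terminal inverted repeats, fixed TA target site
MUTATOR   long terminal inverted repeats, 8-10 bp TSD
========  =======================================================

Divergence is applied as independent per-base substitution on element
bodies only (no indels), so TSD arithmetic stays exact.  All operations
are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import Interval, ProteinQuery, SequenceRecord, revcomp
from .genes import GeneModel

ARCHETYPES = ("LTR", "LINE", "CACTA", "MARINER", "MUTATOR")

#: protein superfamily label used for the transposase probe of each archetype
ARCHETYPE_SUPERFAMILY = {
    "LTR": "Ty3-Gypsy",
    "LINE": "LINE",
    "CACTA": "CACTA",
    "MARINER": "Tc1/mariner",
    "MUTATOR": "Mutator",
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]

POLYA_TAIL_LEN = 15
ORF_LEN_CODONS = 320  # ~1 kb ORF embedded in every reference element


@dataclass
class FamilySpec:
    """Parameters of one simulated transposon family."""

    name: str
    archetype: str
    element_len: int
    ltr_len: int = 0
    tir_len: int = 0
    tsd_len: int = 5
    copy_number: int = 10
    divergence: float = 0.02
    fragmentation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "MARINER":
            self.tsd_len = 2  # mariner target site is fixed TA
        term = self.ltr_len if self.archetype == "LTR" else self.tir_len
        if self.archetype != "LINE" and self.element_len <= 2 * term:
            raise ValueError("element_len must exceed twice the terminal length")
        if not (0.0 <= self.divergence <= 0.3):
            raise ValueError("divergence must be in [0, 0.3]")


def default_family_specs(
    divergence: float = 0.02, fragmentation_rate: float = 0.0, copy_number: int = 10
) -> list[FamilySpec]:
    """The five study families, one per archetype.

    Lengths are scaled-down but realistic: retroelements of a few kb with
    a ~1-kb internal ORF, a short mariner with 26-bp TIRs, long-TIR
    mutator-like element.
    """
    common = dict(
        copy_number=copy_number, divergence=divergence, fragmentation_rate=fragmentation_rate
    )
    return [
        FamilySpec("simGypsy1", "LTR", 5000, ltr_len=200, tsd_len=5, **common),
        FamilySpec("simLINE1", "LINE", 3000, tsd_len=12, **common),
        FamilySpec("simCACTA1", "CACTA", 4000, tir_len=20, tsd_len=3, **common),
        FamilySpec("simMariner1", "MARINER", 1300, tir_len=26, **common),
        FamilySpec("simMutator1", "MUTATOR", 3500, tir_len=60, tsd_len=9, **common),
    ]


@dataclass
class ReferenceElement:
    """A family's reference sequence plus its structural layout."""

    spec: FamilySpec
    record: SequenceRecord
    orf: tuple[int, int]  # ORF interval within the element, half-open

    @property
    def name(self) -> str:
        return self.spec.name


@dataclass
class PlantedInsertion:
    """One planted copy; site identity is shared across accession genomes."""

    insertion_id: str
    family: str
    archetype: str
    chrom: str
    bg_pos: int  # target-site position in background coordinates
    tsd_seq: str
    body: str  # copy sequence after mutation/truncation
    intact: bool
    truncated_end: Optional[str] = None  # "5p" or "3p" for fragmental copies
    mutated: bool = False


@dataclass
class SimulationTruth:
    """Planted-insertion registry grounding every downstream test."""

    families: dict[str, ReferenceElement]
    insertions: list[PlantedInsertion]
    background: dict[str, str]
    presence: dict[str, dict[str, bool]] = field(default_factory=dict)
    coords: dict[str, dict[str, Interval]] = field(default_factory=dict)
    duplicated_flank_ids: list[str] = field(default_factory=list)
    transcript_labels: dict[str, str] = field(default_factory=dict)

    def genome_ids(self) -> list[str]:
        return list(self.presence)

    def insertion(self, insertion_id: str) -> PlantedInsertion:
        for ins in self.insertions:
            if ins.insertion_id == insertion_id:
                return ins
        raise KeyError(insertion_id)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in codons) + "TAA"


def build_reference_element(spec: FamilySpec, seed: int) -> ReferenceElement:
    """Construct the family reference sequence with its terminal features."""
    rng = np.random.default_rng(seed)
    orf = _random_orf(rng, ORF_LEN_CODONS)
    if spec.archetype == "LTR":
        ltr = "TG" + _random_dna(rng, spec.ltr_len - 4) + "CA"
        internal_len = spec.element_len - 2 * spec.ltr_len
        pad = internal_len - len(orf)
        if pad < 2:
            raise ValueError(f"{spec.name}: element too short for internal ORF")
        left = _random_dna(rng, pad // 2)
        right = _random_dna(rng, pad - pad // 2)
        seq = ltr + left + orf + right + ltr
        orf_start = spec.ltr_len + len(left)
    elif spec.archetype == "LINE":
        body_len = spec.element_len - POLYA_TAIL_LEN
        pad = body_len - len(orf)
        if pad < 2:
            raise ValueError(f"{spec.name}: element too short for internal ORF")
        left = _random_dna(rng, pad // 2)
        right = _random_dna(rng, pad - pad // 2)
        seq = left + orf + right + "A" * POLYA_TAIL_LEN
        orf_start = len(left)
    else:  # TIR archetypes
        tir = _random_dna(rng, spec.tir_len)
        if spec.archetype == "CACTA":
            tir = "CACTA" + tir[5:]
        internal_len = spec.element_len - 2 * spec.tir_len
        pad = internal_len - len(orf)
        if pad < 2:
            raise ValueError(f"{spec.name}: element too short for internal ORF")
        left = _random_dna(rng, pad // 2)
        right = _random_dna(rng, pad - pad // 2)
        seq = tir + left + orf + right + revcomp(tir)
        orf_start = spec.tir_len + len(left)
    assert len(seq) == spec.element_len
    rec = SequenceRecord(spec.name, seq, f"reference {spec.archetype} element")
    return ReferenceElement(spec=spec, record=rec, orf=(orf_start, orf_start + len(orf)))


def transposase_queries(families: Sequence[ReferenceElement]) -> list[ProteinQuery]:
    """Translate each family's internal ORF into a transposase-like probe."""
    out = []
    for fam in families:
        a, b = fam.orf
        orf_nt = fam.record.seq[a:b]
        aa = _translate(orf_nt[:-3])  # drop the stop codon
        out.append(
            ProteinQuery(
                id=f"{fam.name}_tpase",
                aaseq=aa,
                superfamily=ARCHETYPE_SUPERFAMILY[fam.spec.archetype],
            )
        )
    return out


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, bool]:
    if rate <= 0:
        return seq, False
    codes = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hit) == 0:
        return seq, False
    for i in hit:
        cur = codes[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != cur]
        codes[i] = choices[int(rng.integers(0, 3))]
    return codes.tobytes().decode(), True


def simulate_genome(
    chrom_lengths: dict[str, int],
    specs: Sequence[FamilySpec],
    seed: int,
    min_gap: int = 1500,
    end_margin: int = 1000,
    n_duplicated_flanks: int = 0,
) -> tuple[list[SequenceRecord], SimulationTruth]:
    """Plant every family's copies into random background chromosomes.

    ``chrom_lengths`` gives background lengths (before insertion).  Each
    copy is flanked by an identical TSD on both sides (the duplicated
    target site); fragmental copies lose one terminus; divergence applies
    per-base substitutions to the copy body.  With ``n_duplicated_flanks``
    > 0, the left-flank segment (including the target site) of that many
    insertions is copied elsewhere into the background — a mappability
    stress that makes those flanks multi-mapping in every accession.
    """
    rng = np.random.default_rng(seed)
    background = {c: _random_dna(rng, n) for c, n in chrom_lengths.items()}
    families = {s.name: build_reference_element(s, int(rng.integers(0, 2**31))) for s in specs}

    total = sum(s.copy_number for s in specs)
    chroms = sorted(chrom_lengths)
    # sample non-overlapping target sites, spread over chromosomes by length
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placements: dict[str, list[int]] = {c: [] for c in chroms}
    site_list: list[tuple[str, int]] = []
    for _ in range(total):
        for _attempt in range(10_000):
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            p = int(rng.integers(end_margin, chrom_lengths[c] - end_margin))
            if all(abs(p - q) >= min_gap for q in placements[c]):
                placements[c].append(p)
                site_list.append((c, p))
                break
        else:
            raise ValueError("chromosomes too small for the requested copy number")

    insertions: list[PlantedInsertion] = []
    i = 0
    for spec in specs:
        fam = families[spec.name]
        for _copy in range(spec.copy_number):
            c, p = site_list[i]
            i += 1
            if spec.archetype == "MARINER":
                tsd = "TA"
                background[c] = background[c][:p] + tsd + background[c][p + 2 :]
            else:
                tsd = background[c][p : p + spec.tsd_len]
            body = fam.record.seq
            truncated_end = None
            intact = True
            if rng.random() < spec.fragmentation_rate:
                intact = False
                cut = int(rng.integers(int(0.1 * len(body)), int(0.6 * len(body))))
                if rng.random() < 0.5:
                    body = body[cut:]
                    truncated_end = "5p"
                else:
                    body = body[: len(body) - cut]
                    truncated_end = "3p"
            body, mutated = _mutate(rng, body, spec.divergence)
            insertions.append(
                PlantedInsertion(
                    insertion_id=f"ins{len(insertions):04d}",
                    family=spec.name,
                    archetype=spec.archetype,
                    chrom=c,
                    bg_pos=p,
                    tsd_seq=tsd,
                    body=body,
                    intact=intact,
                    truncated_end=truncated_end,
                    mutated=mutated,
                )
            )

    truth = SimulationTruth(families=families, insertions=insertions, background=background)

    if n_duplicated_flanks > 0:
        _plant_flank_duplications(truth, rng, n_duplicated_flanks)

    records = _assemble("ref", truth, {ins.insertion_id: True for ins in insertions})
    return records, truth


def _plant_flank_duplications(
    truth: SimulationTruth, rng: np.random.Generator, n: int, seg_len: int = 400
) -> None:
    """Copy the left-flank segment of n insertions elsewhere in background."""
    candidates = [ins for ins in truth.insertions if ins.intact]
    picked = [candidates[int(k)] for k in rng.choice(len(candidates), size=min(n, len(candidates)), replace=False)]
    occupied = [(ins.chrom, ins.bg_pos) for ins in truth.insertions]
    for ins in picked:
        src = truth.background[ins.chrom][
            ins.bg_pos - seg_len : ins.bg_pos + len(ins.tsd_seq)
        ]
        for _attempt in range(10_000):
            c = ins.chrom
            p = int(rng.integers(1000, len(truth.background[c]) - 1000 - len(src)))
            if all(
                abs(p - q) >= 2000 for ch, q in occupied if ch == c
            ):
                break
        else:  # pragma: no cover
            raise ValueError("no room for background duplication")
        bg = truth.background[c]
        truth.background[c] = bg[:p] + src + bg[p + len(src) :]
        occupied.append((c, p))
        truth.duplicated_flank_ids.append(ins.insertion_id)


def _assemble(
    genome_id: str, truth: SimulationTruth, present: dict[str, bool]
) -> list[SequenceRecord]:
    """Build a genome from background plus the present subset of insertions."""
    records = []
    coords: dict[str, Interval] = {}
    for chrom in sorted(truth.background):
        bg = truth.background[chrom]
        here = sorted(
            (ins for ins in truth.insertions if ins.chrom == chrom),
            key=lambda x: x.bg_pos,
        )
        parts = []
        prev = 0
        offset = 0  # running length added by insertions
        for ins in here:
            if not present.get(ins.insertion_id, False):
                continue
            L = len(ins.tsd_seq)
            parts.append(bg[prev : ins.bg_pos + L])
            start = ins.bg_pos + L + offset
            parts.append(ins.body)
            coords[ins.insertion_id] = Interval(chrom, start, start + len(ins.body))
            prev = ins.bg_pos  # right TSD copy re-reads the site
            offset += len(ins.body) + L
        parts.append(bg[prev:])
        records.append(SequenceRecord(chrom, "".join(parts), f"{genome_id} {chrom}"))
    truth.presence[genome_id] = dict(present)
    truth.coords[genome_id] = coords
    return records


def derive_accession(
    truth: SimulationTruth, absence_prob: float, seed: int, genome_id: str
) -> list[SequenceRecord]:
    """Derive an accession in which each insertion is independently absent.

    An absent site is the pre-insertion state: flank + single TSD copy +
    flank.  The background is otherwise identical to the reference.
    """
    rng = np.random.default_rng(seed)
    present = {
        ins.insertion_id: bool(rng.random() >= absence_prob) for ins in truth.insertions
    }
    return _assemble(genome_id, truth, present)


# -- transcripts and gene models ---------------------------------------------


def simulate_transcripts(
    genome: Sequence[SequenceRecord],
    truth: SimulationTruth,
    n_clean_genes: int,
    n_te_genes: int,
    n_full_te: int,
    seed: int,
    te_fragment_len: int = 120,
) -> tuple[list[SequenceRecord], list[GeneModel], dict[str, str]]:
    """Emit a transcript set with known TE content.

    Full-TE transcripts copy intact planted element bodies; TE-bearing
    genes carry a ``te_fragment_len`` slice of a planted element inside
    their CDS, 5' UTR or 3' UTR (cycling); clean genes are background-only
    and share no 20-mer with any family reference.  Gene models are
    single-exon on the plus strand (every third model gains an upstream
    background exon); clean genes alternate strands.
    """
    rng = np.random.default_rng(seed)
    seqs = {r.id: r.seq for r in genome}
    ref_coords = truth.coords["ref"]
    # round-robin across families so small transcript sets cover them all
    by_family: dict[str, list[PlantedInsertion]] = {}
    for ins in truth.insertions:
        if ins.intact and ins.insertion_id in ref_coords:
            by_family.setdefault(ins.family, []).append(ins)
    intact = []
    for depth in range(max((len(v) for v in by_family.values()), default=0)):
        for fam in sorted(by_family):
            if depth < len(by_family[fam]):
                intact.append(by_family[fam][depth])
    if n_full_te > 0 and not intact:
        raise ValueError("no intact insertions available for full-TE transcripts")

    transcripts: list[SequenceRecord] = []
    models: list[GeneModel] = []
    labels: dict[str, str] = {}

    for k in range(n_full_te):
        ins = intact[k % len(intact)]
        iv = ref_coords[ins.insertion_id]
        tid = f"TEtx{k:03d}"
        transcripts.append(
            SequenceRecord(tid, seqs[iv.chrom][iv.start : iv.end], f"full {ins.family}")
        )
        labels[tid] = "full_TE"

    # genomic space already taken by elements (plus margin for gene bodies)
    occupied: list[tuple[str, int, int]] = [
        (iv.chrom, iv.start - 400, iv.end + 400) for iv in ref_coords.values()
    ]

    def free_region(chrom: str, start: int, end: int) -> bool:
        return all(
            not (c == chrom and start < e and s < end) for c, s, e in occupied
        )

    te_regions = ["CDS", "UTR3", "UTR5"]
    gid = 0
    for k in range(n_te_genes):
        region = te_regions[k % 3]
        ins = intact[(k + n_full_te) % len(intact)]
        iv = ref_coords[ins.insertion_id]
        f = te_fragment_len
        bg_len = 600
        gid += 1
        gene_id = f"gene{gid:04d}"
        tid = f"{gene_id}.t1"
        if region in ("CDS", "UTR5"):
            # exon crosses the element 3' boundary: TE fragment leads
            exon = Interval(iv.chrom, iv.end - f, iv.end + bg_len, "+")
            L = len(exon)
            if region == "CDS":
                cds_lo, cds_hi = 0, f + 150
            else:
                cds_lo, cds_hi = f + 50, L - 80
        else:
            # exon crosses the element 5' boundary: TE fragment trails
            exon = Interval(iv.chrom, iv.start - bg_len, iv.start + f, "+")
            L = len(exon)
            cds_lo, cds_hi = 60, bg_len - 50
        cds = Interval(exon.chrom, exon.start + cds_lo, exon.start + cds_hi, "+")
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=tid,
                strand="+",
                exons=[exon],
                cds_segments=[cds],
                annotation_label=f"synthetic TE-{region} gene",
            )
        )
        transcripts.append(
            SequenceRecord(tid, seqs[exon.chrom][exon.start : exon.end], f"TE in {region}")
        )
        labels[tid] = {"CDS": "gene_TE_CDS", "UTR5": "gene_TE_UTR5", "UTR3": "gene_TE_UTR3"}[region]

    ref_kmers: set[str] = set()
    for fam in truth.families.values():
        s = fam.record.seq
        ref_kmers.update(s[i : i + 20] for i in range(len(s) - 19))

    chroms = sorted(seqs)
    for k in range(n_clean_genes):
        gid += 1
        gene_id = f"gene{gid:04d}"
        tid = f"{gene_id}.t1"
        strand = "+" if k % 2 == 0 else "-"
        two_exon = gid % 3 == 0
        for _attempt in range(10_000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            glen = 700 if not two_exon else 950
            start = int(rng.integers(500, len(seqs[chrom]) - 500 - glen))
            if not free_region(chrom, start, start + glen):
                continue
            tx = (
                seqs[chrom][start : start + 150] + seqs[chrom][start + 250 : start + glen]
                if two_exon
                else seqs[chrom][start : start + glen]
            )
            if strand == "-":
                tx = revcomp(tx)
            if any(tx[i : i + 20] in ref_kmers for i in range(0, len(tx) - 19, 10)):
                continue
            break
        else:  # pragma: no cover
            raise ValueError("could not place a clean gene")
        occupied.append((chrom, start - 200, start + glen + 200))
        if two_exon:
            exons = [
                Interval(chrom, start, start + 150, strand),
                Interval(chrom, start + 250, start + glen, strand),
            ]
        else:
            exons = [Interval(chrom, start, start + glen, strand)]
        L = sum(len(e) for e in exons)
        # CDS occupies the middle of the transcript, genomically anchored
        cds = [Interval(chrom, start + 250 if two_exon else start + 120, start + glen - 150, strand)]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=tid,
                strand=strand,
                exons=exons,
                cds_segments=cds,
                annotation_label="synthetic clean gene",
            )
        )
        transcripts.append(SequenceRecord(tid, tx, "clean gene"))
        labels[tid] = "gene_clean"

    truth.transcript_labels.update(labels)
    return transcripts, models, labels


# -- truth serialization ------------------------------------------------------


def write_truth(truth: SimulationTruth, outdir: str | Path) -> None:
    """Write the planted-insertion registry and presence matrix as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_ids = truth.genome_ids()
    lines = [
        "\t".join(
            ["insertion_id", "family", "archetype", "chrom", "tsd_seq", "intact", "body_len"]
            + [f"present_{g}" for g in genome_ids]
            + [f"coords_{g}" for g in genome_ids]
        )
    ]
    for ins in truth.insertions:
        row = [
            ins.insertion_id, ins.family, ins.archetype, ins.chrom, ins.tsd_seq,
            str(int(ins.intact)), str(len(ins.body)),
        ]
        for g in genome_ids:
            row.append(str(int(truth.presence[g].get(ins.insertion_id, False))))
        for g in genome_ids:
            iv = truth.coords[g].get(ins.insertion_id)
            row.append(f"{iv.start}-{iv.end}" if iv else ".")
        lines.append("\t".join(row))
    (outdir / "truth_insertions.tsv").write_text("\n".join(lines) + "\n")
    if truth.transcript_labels:
        tl = ["transcript_id\tlabel"] + [
            f"{t}\t{l}" for t, l in sorted(truth.transcript_labels.items())
        ]
        (outdir / "truth_transcripts.tsv").write_text("\n".join(tl) + "\n")
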