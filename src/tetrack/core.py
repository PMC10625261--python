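"""Shared domain types, coordinate conventions, and pipeline parameters.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
writers convert to 1-based inclusive at the boundary.  Sequences are stored
uppercase over the alphabet {A, C, G, T, N}; ``N`` never counts as a match
in identity computations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: The nine transposase superfamilies used as homology probes.
SUPERFAMILIES = (
    "Ty1-Copia",
    "Ty3-Gypsy",
    "LINE",
    "hAT",
    "Mutator",
    "Helitron",
    "CACTA",
    "Pong",
    "Tc1/mariner",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_dna(seq: str) -> str:
    """Uppercase a nucleotide string and validate its alphabet."""
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"illegal nucleotide character(s): {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"illegal nucleotide character(s): {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (chromosome, transcript, or element)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", normalize_dna(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinQuery:
    """A transposase protein probe labelled with its superfamily."""

    id: str
    aaseq: str
    superfamily: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        aas = self.aaseq.upper()
        bad = set(aas) - AA_ALPHABET
        if bad:
            raise ValueError(f"illegal amino-acid character(s): {sorted(bad)}")
        object.__setattr__(self, "aaseq", aas)
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open, with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def to_gff3_coords(iv: Interval) -> tuple[int, int]:
    """Convert a 0-based half-open interval to a 1-based inclusive pair."""
    return iv.start + 1, iv.end


def from_gff3_coords(chrom: str, start1: int, end1: int, strand: str = "+") -> Interval:
    """Inverse of :func:`to_gff3_coords`."""
    return Interval(chrom, start1 - 1, end1, strand)


@dataclass
class PipelineParams:
    """Every tunable threshold of the pipeline, in one serializable object.

    The four significance/window values (``evalue_max``, ``min_match_len``,
    ``locus_flank``, ``probe_flank``) are the published operating point of
    the screening protocol; the structural-detection thresholds encode
    standard transposon taxonomy conventions and are documented choices.
    Lengths are in base pairs, identities in percent.
    """

    # homology significance filter
    evalue_max: float = 1e-10
    min_match_len: int = 50  # matched region must exceed this (strict >)
    # locus / probe windows
    locus_flank: int = 10_000  # per side around an anchored hit
    probe_flank: int = 350  # per side around an element body
    # structural feature detection
    tsd_len_min: int = 2
    tsd_len_max: int = 20
    boundary_jitter: int = 5
    ltr_min_len: int = 80
    ltr_min_identity: float = 85.0
    tir_min_len: int = 10
    tir_max_mismatch: int = 2
    polya_window: int = 15
    polya_min_frac: float = 0.75
    # presence/absence classification
    unique_margin: float = 2.0  # percent-identity gap defining a unique hit
    empty_site_gap_max: int = 50
    shared_len_tol: float = 0.2
    # masking
    mask_min_identity: float = 60.0
    mask_merge_gap: int = 20
    # alignment engine
    word_size: int = 11
    aa_word_size: int = 3
    match_score: int = 2
    mismatch_score: int = -3
    gap_open: int = -5  # opening a gap of length k costs open + k*extend
    gap_extend: int = -2
    band_pad: int = 64
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        for name in (
            "min_match_len",
            "locus_flank",
            "probe_flank",
            "tsd_len_min",
            "tsd_len_max",
            "ltr_min_len",
            "tir_min_len",
            "polya_window",
            "empty_site_gap_max",
            "word_size",
            "aa_word_size",
            "band_pad",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tsd_len_min > self.tsd_len_max:
            raise ValueError("tsd_len_min must be <= tsd_len_max")
        if not (0.0 < self.polya_min_frac <= 1.0):
            raise ValueError("polya_min_frac must be in (0, 1]")
        if not (0.0 < self.shared_len_tol <= 1.0):
            raise ValueError("shared_len_tol must be in (0, 1]")

    # -- flat key=value config round-trip ------------------------------------

    def to_config(self, path: str | Path) -> None:
        """Write the parameter set as a flat ``key=value`` config file."""
        lines = ["# tetrack pipeline parameters"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)!r}".replace("'", ""))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(
        cls, path: str | Path, overrides: Optional[dict] = None
    ) -> "PipelineParams":
        """Read a flat key=value config; unknown keys are an error."""
        values: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"float": float, "int": int}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            values[key] = casts[types[key]](val)
        if overrides:
            values.update(overrides)
        return cls(**values)


def check_intervals_within(ivs: Iterable[Interval], chrom_lengths: dict) -> None:
    """Assert every interval lies inside its chromosome."""
    for iv in ivs:
        if iv.chrom not in chrom_lengths:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > chrom_lengths[iv.chrom]:
            raise ValueError(
                f"interval [{iv.start},{iv.end}) exceeds {iv.chrom} "
                f"length {chrom_lengths[iv.chrom]}"
            )
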