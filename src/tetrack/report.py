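"""Arithmetic summary views over pipeline counts.

Every function here is a pure view: it re-derives percentages and
partitions from counts, never recomputing the underlying analysis.
Percent shares over superfamily tallies are printed as whole percent;
rates over transcript sets and gene classes carry one decimal.
"""

from __future__ import annotations

from typing import Mapping

from .core import SUPERFAMILIES

LTR_SUPERFAMILIES = frozenset({"Ty1-Copia", "Ty3-Gypsy"})
LINE_SUPERFAMILIES = frozenset({"LINE"})
DNA_SUPERFAMILIES = frozenset(SUPERFAMILIES) - LTR_SUPERFAMILIES - LINE_SUPERFAMILIES


def superfamily_tally(counts: Mapping[str, int]) -> dict:
    """Total and class shares of a per-superfamily transcript tally.

    Returns the total and the whole-percent share of LINE-related,
    DNA-transposon-related and LTR-retrotransposon-related entries.
    """
    unknown = set(counts) - set(SUPERFAMILIES)
    if unknown:
        raise ValueError(f"unknown superfamilies: {sorted(unknown)}")
    total = sum(counts.values())
    if total == 0:
        return {"total": 0, "pct_line": None, "pct_dna": None, "pct_ltr": None}
    n_line = sum(v for k, v in counts.items() if k in LINE_SUPERFAMILIES)
    n_dna = sum(v for k, v in counts.items() if k in DNA_SUPERFAMILIES)
    n_ltr = sum(v for k, v in counts.items() if k in LTR_SUPERFAMILIES)
    return {
        "total": total,
        "n_line": n_line,
        "n_dna": n_dna,
        "n_ltr": n_ltr,
        "pct_line": round(100.0 * n_line / total),
        "pct_dna": round(100.0 * n_dna / total),
        "pct_ltr": round(100.0 * n_ltr / total),
    }


def transcript_te_rate(n_te: int, n_total: int) -> float:
    """Share of a transcript set related to transposons, in percent (0.1)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_te / n_total, 1)


def cds_recruitment_pct(n_cds: int, n_classified: int) -> float:
    """Share of TE-bearing genes whose TE segment sits in the CDS."""
    if n_classified <= 0:
        raise ValueError("n_classified must be positive")
    return round(100.0 * n_cds / n_classified, 1)


def comparison_partition(n_shared: int, n_absent: int, n_undetermined: int) -> dict:
    """Shared / absent / undetermined partition of probed elements."""
    for name, v in (("shared", n_shared), ("absent", n_absent), ("undetermined", n_undetermined)):
        if v < 0:
            raise ValueError(f"negative count for {name}")
    return {
        "shared": n_shared,
        "absent": n_absent,
        "undetermined": n_undetermined,
        "total": n_shared + n_absent + n_undetermined,
    }
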