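"""Base composition and strand-asymmetry (skew) statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), the standard
compositional asymmetry measures for mitochondrial strands.  Both are
scale-invariant, so counts and percentages give identical values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import pandas as pd

from .annotation import (
    MitogenomeAnnotation,
    SequenceRecord,
    extract_feature_sequence,
)

__all__ = [
    "CompositionSummary",
    "base_composition",
    "at_skew",
    "gc_skew",
    "per_feature_composition",
    "composition_report",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (as in typeset tables).

    Python's built-in round uses banker's rounding, which disagrees with
    how published tables round values like -0.2565 -> -0.257.
    """
    factor = 10 ** ndigits
    scaled = x * factor
    # nudge by an epsilon scaled to the value to counter binary representation error
    return math.copysign(math.floor(abs(scaled) + 0.5 + 1e-9), scaled) / factor


def at_skew(a: float, t: float) -> float:
    """(A - T)/(A + T); accepts counts or percentages."""
    if a + t <= 0:
        raise ValueError("AT skew undefined: A + T must be positive")
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G - C)/(G + C); accepts counts or percentages."""
    if g + c <= 0:
        raise ValueError("GC skew undefined: G + C must be positive")
    return (g - c) / (g + c)


@dataclass(frozen=True)
class CompositionSummary:
    """Counts, percentages and skews of one sequence.

    N bases are excluded from all counts and denominators so that draft
    sequences remain usable; percentages are relative to counted bases.
    """

    n_A: int
    n_T: int
    n_G: int
    n_C: int

    @property
    def total(self) -> int:
        return self.n_A + self.n_T + self.n_G + self.n_C

    @property
    def pct_A(self) -> float:
        return 100.0 * self.n_A / self.total

    @property
    def pct_T(self) -> float:
        return 100.0 * self.n_T / self.total

    @property
    def pct_G(self) -> float:
        return 100.0 * self.n_G / self.total

    @property
    def pct_C(self) -> float:
        return 100.0 * self.n_C / self.total

    @property
    def at_pct(self) -> float:
        return 100.0 * (self.n_A + self.n_T) / self.total

    @property
    def gc_pct(self) -> float:
        return 100.0 * (self.n_G + self.n_C) / self.total

    @property
    def at_skew(self) -> float:
        return at_skew(self.n_A, self.n_T)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.n_G, self.n_C)


def base_composition(seq: Union[str, SequenceRecord]) -> CompositionSummary:
    """Tally A/T/G/C of a sequence, ignoring N."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq.upper()
    if not s:
        raise ValueError("empty sequence")
    summary = CompositionSummary(
        n_A=s.count("A"), n_T=s.count("T"), n_G=s.count("G"), n_C=s.count("C")
    )
    if summary.total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return summary


def per_feature_composition(
    genome: Union[SequenceRecord, str],
    annotation: MitogenomeAnnotation,
    *,
    include_trnas: bool = False,
    sense_strand: bool = True,
) -> pd.DataFrame:
    """Composition of each PCG and rRNA feature plus a genome-wide row.

    Computed on each feature's sense (coding) strand by default; with
    ``sense_strand=False`` the plus-strand genomic slice is used
    instead.  Returns a DataFrame indexed by gene name with columns
    T, C, A, G, Total, GC%, AT%, GC Skew, AT Skew (full precision).
    """
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    if len(seq) != annotation.genome_length:
        raise ValueError(
            f"sequence length {len(seq)} != annotation genome_length {annotation.genome_length}"
        )
    wanted = {"PCG", "rRNA"} | ({"tRNA"} if include_trnas else set())
    rows = []
    for feat in annotation.sorted_by_start():
        if feat.gene_type not in wanted:
            continue
        sub = extract_feature_sequence(seq, feat)
        if not sense_strand and feat.strand == "-":
            from .annotation import reverse_complement

            sub = reverse_complement(sub)
        rows.append((feat.name, base_composition(sub)))
    rows.append(("genome", base_composition(seq)))

    frame = pd.DataFrame(
        {
            "T": [c.pct_T for _, c in rows],
            "C": [c.pct_C for _, c in rows],
            "A": [c.pct_A for _, c in rows],
            "G": [c.pct_G for _, c in rows],
            "Total": [c.total for _, c in rows],
            "GC%": [c.gc_pct for _, c in rows],
            "AT%": [c.at_pct for _, c in rows],
            "GC Skew": [c.gc_skew for _, c in rows],
            "AT Skew": [c.at_skew for _, c in rows],
        },
        index=pd.Index([name for name, _ in rows], name="Gene"),
    )
    return frame


def composition_report(frame: pd.DataFrame) -> pd.DataFrame:
    """Round a per-feature composition table to publication precision.

    Percentages to 2 decimals, base fractions to 1, skews to 3, with
    half-away-from-zero ties.
    """
    out = frame.copy()
    for col in ("T", "C", "A", "G"):
        out[col] = [round_half_away(v, 1) for v in out[col]]
    for col in ("GC%", "AT%"):
        out[col] = [round_half_away(v, 2) for v in out[col]]
    for col in ("GC Skew", "AT Skew"):
        out[col] = [round_half_away(v, 3) for v in out[col]]
    return out
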