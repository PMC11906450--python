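"""Codon usage, start/stop classification and RSCU for mitochondrial PCGs.

All statistics are computed on sense-strand coding sequences.  Incomplete
stop codons ("T" or "TA" tails, completed to UAA by post-transcriptional
polyadenylation in animal mitochondria) are classified but excluded from
codon tallies, since they encode no amino acid.

RSCU (relative synonymous codon usage) for codon ``c`` in a synonymous
family ``F`` is ``|F| * n_c / sum_{c' in F} n_{c'}`` — the observed count
relative to expectation under uniform use within the family.  Stop
codons are excluded from RSCU families by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "StartStopReport",
    "CodonUsageTable",
    "INVERTEBRATE_MITO",
    "STANDARD",
    "split_codons",
    "classify_start_stop",
    "codon_usage",
    "rscu",
    "amino_acid_usage",
    "codon_report",
]

_BASES = "TCAG"
#: All 64 DNA codons in the T/C/A/G nesting order used by published
#: codon-usage tables (UUU, UUC, UUA, UUG, CUU, ...).
ALL_CODONS = tuple(b1 + b2 + b3 for b1 in _BASES for b2 in _BASES for b3 in _BASES)

STOP_SYMBOL = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: codon -> amino acid, plus start/stop sets.

    Stop codons map to ``*``.  Built from the NCBI translation tables
    shipped with Biopython; the invertebrate mitochondrial code is
    table 5, the standard code table 1.
    """

    code_id: int
    codon_to_aa: dict[str, str]
    start_codon_set: frozenset[str]
    stop_codon_set: frozenset[str]

    @classmethod
    def from_ncbi_id(cls, code_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[code_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP_SYMBOL
        if len(mapping) != 64:
            raise ValueError(f"translation table {code_id} does not cover 64 codons")
        return cls(
            code_id=code_id,
            codon_to_aa=mapping,
            start_codon_set=frozenset(table.start_codons),
            stop_codon_set=frozenset(table.stop_codons),
        )

    def family(self, codon: str) -> tuple[str, ...]:
        """All codons encoding the same amino acid (the synonymous family)."""
        aa = self.codon_to_aa[codon]
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == aa)


INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)
STANDARD = GeneticCode.from_ncbi_id(1)


def split_codons(cds: str) -> tuple[list[str], str]:
    """Maximal triplet decomposition of a sense-strand CDS.

    Returns (codons, tail) where the tail of length 0-2 is the
    remainder — a truncated terminator on genes with incomplete stops.
    """
    cds = cds.upper().replace("U", "T")
    if not cds:
        raise ValueError("empty coding sequence")
    n_full = len(cds) // 3
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_full)]
    return codons, cds[3 * n_full :]


@dataclass(frozen=True)
class StartStopReport:
    gene: str
    start_codon: str
    start_canonical: bool
    stop_codon: str
    stop_complete: bool


def classify_start_stop(
    codons: Sequence[str], tail: str, code: GeneticCode = INVERTEBRATE_MITO, *, gene: str = ""
) -> StartStopReport:
    """Identify the initiator and terminator of a CDS.

    The start is the first codon, canonical iff in the code's start set.
    With a non-empty tail the stop is the (incomplete) tail; otherwise
    the last full codon, complete iff it is a stop codon of the code.
    Non-canonical codons are flagged, never fatal.
    """
    if not codons:
        raise ValueError("CDS has no full codon")
    start = codons[0].upper()
    if tail:
        stop, complete = tail.upper(), False
    else:
        stop = codons[-1].upper()
        complete = stop in code.stop_codon_set
    return StartStopReport(
        gene=gene,
        start_codon=start,
        start_canonical=start in code.start_codon_set,
        stop_codon=stop,
        stop_complete=complete,
    )


@dataclass
class CodonUsageTable:
    """Pooled per-codon counts with derived per-1000 frequencies and RSCU."""

    counts: dict[str, int]
    code: GeneticCode = field(default_factory=lambda: INVERTEBRATE_MITO)

    @property
    def n_codons_total(self) -> int:
        return sum(self.counts.values())

    def per_1000(self) -> dict[str, float]:
        total = self.n_codons_total
        if total == 0:
            raise ValueError("empty codon table")
        return {c: 1000.0 * n / total for c, n in self.counts.items()}

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        if other.code.code_id != self.code.code_id:
            raise ValueError("cannot merge tables under different genetic codes")
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonUsageTable(counts=merged, code=self.code)


def codon_usage(
    cds_set: Iterable[str], code: GeneticCode = INVERTEBRATE_MITO
) -> CodonUsageTable:
    """Pool codon counts over a set of sense-strand coding sequences.

    Incomplete stop tails are excluded from the tallies.
    """
    counts = {c: 0 for c in ALL_CODONS}
    n_genes = 0
    for cds in cds_set:
        n_genes += 1
        codons, _tail = split_codons(cds)
        for codon in codons:
            if codon in counts:
                counts[codon] += 1
            # codons containing N are skipped
    if n_genes == 0:
        raise ValueError("empty CDS pool")
    return CodonUsageTable(counts=counts, code=code)


def rscu(table: CodonUsageTable, *, include_stop: bool = False) -> dict[str, float]:
    """Relative synonymous codon usage per codon.

    Families with zero total get RSCU 0 for every member.  Stop codons
    (and single-codon families when stops are included) follow the same
    formula; by default stop codons are excluded from the result.
    """
    values: dict[str, float] = {}
    for codon in ALL_CODONS:
        if not include_stop and table.code.codon_to_aa[codon] == STOP_SYMBOL:
            continue
        fam = table.code.family(codon)
        fam_total = sum(table.counts[c] for c in fam)
        if fam_total == 0:
            values[codon] = 0.0
        else:
            values[codon] = len(fam) * table.counts[codon] / fam_total
    return values


def amino_acid_usage(table: CodonUsageTable) -> pd.Series:
    """Per-amino-acid codon totals, ranked descending (ties alphabetical).

    Stop codons are tallied under ``*`` and reported last regardless of
    count, since they encode no amino acid.
    """
    if table.n_codons_total == 0:
        raise ValueError("empty codon table")
    totals: dict[str, int] = {}
    for codon in ALL_CODONS:
        aa = table.code.codon_to_aa[codon]
        totals[aa] = totals.get(aa, 0) + table.counts[codon]
    aas = sorted(totals, key=lambda a: (a == STOP_SYMBOL, -totals[a], a))
    return pd.Series({a: totals[a] for a in aas}, name="count")


def _to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def codon_report(table: CodonUsageTable, *, include_stop_rscu: bool = False) -> pd.DataFrame:
    """Full codon table: codon (RNA), amino acid, count, per-1000, RSCU.

    Rows follow the U/C/A/G nesting order of published codon tables.
    """
    freqs = table.per_1000()
    rscu_vals = rscu(table, include_stop=True)
    rows = []
    for codon in ALL_CODONS:
        aa = table.code.codon_to_aa[codon]
        show_rscu = include_stop_rscu or aa != STOP_SYMBOL
        rows.append(
            {
                "codon": _to_rna(codon),
                "amino_acid": aa,
                "count": table.counts[codon],
                "per_1000": freqs[codon],
                "RSCU": rscu_vals[codon] if show_rscu else float("nan"),
            }
        )
    return pd.DataFrame(rows)
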