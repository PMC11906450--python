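"""Gene architecture from coordinates alone.

Intergenic spacers and gene overlaps are read off the sorted feature
list: for consecutive features the signed gap is
``next_start - current_end - 1``, so abutting genes score 0, a positive
gap is a spacer and a negative gap an overlap.  A terminal record runs
linearly from the last feature to the genome end (the region before the
first feature is reported separately and not counted in spacer totals,
which is the accounting used in published mitogenome summary tables).
The control region of an insect mitogenome is identified as the longest
intergenic spacer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .annotation import MitogenomeAnnotation, gene_length, normalize_gene_name

__all__ = [
    "AdjacencyRecord",
    "AdjacencyTable",
    "ArchitectureSummary",
    "InventoryReport",
    "CANONICAL_TRNAS",
    "compute_adjacencies",
    "architecture_summary",
    "strand_distribution",
    "trna_inventory",
    "control_region_candidate",
    "coverage_accounting",
]

logger = logging.getLogger(__name__)

#: The 22 tRNA genes of the canonical animal mitogenome, with the two
#: leucine and two serine isoacceptors distinguished.
CANONICAL_TRNAS = frozenset(
    {
        "trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG",
        "trnH", "trnI", "trnK", "trnM", "trnF", "trnP", "trnT", "trnY",
        "trnL1", "trnL2", "trnS1", "trnS2", "trnW", "trnV",
    }
)


@dataclass(frozen=True)
class AdjacencyRecord:
    """Signed gap between two consecutive features (or feature -> genome end)."""

    upstream_gene: str
    downstream_gene: str
    gap: int
    terminal: bool = False

    @property
    def kind(self) -> str:
        if self.terminal:
            return "terminal"
        if self.gap > 0:
            return "spacer"
        if self.gap < 0:
            return "overlap"
        return "abutting"


@dataclass(frozen=True)
class AdjacencyTable:
    """Ordered adjacency records plus the region before the first feature."""

    records: tuple[AdjacencyRecord, ...]
    leading_gap: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ArchitectureSummary:
    total_spacer_bp: int
    n_spacers: int
    max_spacer: Optional[AdjacencyRecord]
    total_overlap_bp: int
    n_overlaps: int
    max_overlap: Optional[AdjacencyRecord]
    leading_gap: int


@dataclass(frozen=True)
class InventoryReport:
    present_trnas: frozenset[str]
    missing: frozenset[str]
    duplicated: frozenset[str]
    counts_by_type: dict[str, int] = field(default_factory=dict)


def compute_adjacencies(annotation: MitogenomeAnnotation) -> AdjacencyTable:
    """Gap between every consecutive feature pair, sorted by start.

    Ties on start position are ordered longer-feature-first (logged).
    The final record is the terminal feature -> genome-end gap.
    """
    if not annotation.features:
        raise ValueError("annotation has no features")
    ordered = annotation.sorted_by_start()
    starts = [f.start for f in ordered]
    if len(set(starts)) != len(starts):
        logger.info("duplicate start positions resolved longer-feature-first")

    records: list[AdjacencyRecord] = []
    for up, down in zip(ordered, ordered[1:]):
        records.append(
            AdjacencyRecord(
                upstream_gene=up.name,
                downstream_gene=down.name,
                gap=down.start - up.end - 1,
            )
        )
    last = ordered[-1]
    if last.is_wrap:
        # a wrap-around terminal feature already spans the origin: the
        # closing gap runs from its head end to the first feature
        records.append(
            AdjacencyRecord(
                upstream_gene=last.name,
                downstream_gene=ordered[0].name,
                gap=ordered[0].start - last.end - 1,
                terminal=True,
            )
        )
        leading = 0
    else:
        # a feature ending exactly at genome_length would score -1 under
        # the next_start - end - 1 convention; it abuts the origin, so
        # the linear terminal gap is clamped at 0
        records.append(
            AdjacencyRecord(
                upstream_gene=last.name,
                downstream_gene="(genome end)",
                gap=max(annotation.genome_length - last.end - 1, 0),
                terminal=True,
            )
        )
        leading = ordered[0].start - 1
    return AdjacencyTable(records=tuple(records), leading_gap=leading)


def architecture_summary(
    adjacencies: AdjacencyTable, genome_length: Optional[int] = None
) -> ArchitectureSummary:
    """Spacer/overlap totals, counts and extrema over an adjacency table.

    Extremum ties are broken by earliest genome position (list order).
    """
    spacers = [r for r in adjacencies if r.gap > 0]
    overlaps = [r for r in adjacencies if r.gap < 0]
    return ArchitectureSummary(
        total_spacer_bp=sum(r.gap for r in spacers),
        n_spacers=len(spacers),
        max_spacer=max(spacers, key=lambda r: r.gap, default=None),
        total_overlap_bp=sum(-r.gap for r in overlaps),
        n_overlaps=len(overlaps),
        max_overlap=min(overlaps, key=lambda r: r.gap, default=None),
        leading_gap=adjacencies.leading_gap,
    )


def strand_distribution(annotation: MitogenomeAnnotation) -> tuple[int, int]:
    """(n_plus, n_minus) over all features."""
    n_plus = sum(1 for f in annotation.features if f.strand == "+")
    return n_plus, len(annotation.features) - n_plus


def trna_inventory(annotation: MitogenomeAnnotation) -> InventoryReport:
    """Present / missing / duplicated tRNAs against the canonical 22."""
    observed: list[str] = []
    counts: dict[str, int] = {"PCG": 0, "tRNA": 0, "rRNA": 0, "other": 0}
    for f in annotation.features:
        counts[f.gene_type] = counts.get(f.gene_type, 0) + 1
        if f.gene_type == "tRNA":
            name = normalize_gene_name(f.name)
            if name in CANONICAL_TRNAS:
                observed.append(name)
            else:
                logger.warning("unrecognized tRNA name %r counted under 'other'", f.name)
                counts["other"] += 1
    present = frozenset(observed)
    duplicated = frozenset(n for n in present if observed.count(n) > 1)
    return InventoryReport(
        present_trnas=present,
        missing=frozenset(CANONICAL_TRNAS - present),
        duplicated=duplicated,
        counts_by_type=counts,
    )


def control_region_candidate(adjacencies: AdjacencyTable) -> list[AdjacencyRecord]:
    """The longest positive gap(s) — the putative control region.

    Equal maxima are all returned, in genome order.  Empty list when no
    positive gap exists.
    """
    best = max((r.gap for r in adjacencies), default=0)
    if best <= 0:
        return []
    return [r for r in adjacencies if r.gap == best]


def coverage_accounting(annotation: MitogenomeAnnotation) -> dict[str, int]:
    """Bookkeeping decomposition of the genome into covered/gap classes.

    Returns the leading gap, the summed internal (non-terminal) positive
    gaps, the uncovered run after the last feature, and the count of
    positions covered by at least one feature.  On annotations without
    wrap-around features and without one feature fully contained in
    another, these satisfy
    ``leading + internal_spacers + trailing + covered == genome_length``.
    """
    adj = compute_adjacencies(annotation)
    covered = set()
    for f in annotation.features:
        n = gene_length(f, annotation.genome_length)
        for off in range(n):
            covered.add((f.start - 1 + off) % annotation.genome_length)
    last_end = max(f.end for f in annotation.features)
    return {
        "leading_gap": adj.leading_gap,
        "internal_spacer_bp": sum(r.gap for r in adj if r.gap > 0 and not r.terminal),
        "trailing_bp": max(annotation.genome_length - last_end, 0),
        "covered_bp": len(covered),
    }
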