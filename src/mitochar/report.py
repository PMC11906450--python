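"""Pipeline orchestration: run every characterization stage and bundle
the resulting tables, mirroring the layout of published mitogenome
summary papers (annotation summary, per-gene composition, architecture,
codon usage/RSCU, control-region hits).

Tables are pandas DataFrames serializable to TSV (publication rounding)
and JSON (full precision).  A coordinate-only input (no sequence) still
yields the summary and architecture tables; sequence-dependent tables
are skipped with a logged notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .annotation import (
    MitogenomeAnnotation,
    SequenceRecord,
    extract_feature_sequence,
    gene_length,
    read_fasta,
    read_gene_table,
    read_genbank,
    write_fasta,
)
from .architecture import (
    architecture_summary,
    compute_adjacencies,
    control_region_candidate,
    strand_distribution,
    trna_inventory,
)
from .codon import (
    GeneticCode,
    INVERTEBRATE_MITO,
    classify_start_stop,
    codon_report,
    codon_usage,
    split_codons,
)
from .composition import composition_report, per_feature_composition
from .motifs import find_iupac_motif, find_poly_t, find_stem_loops, find_tandem_repeats
from .phylo import PCG_ORDER, concatenate_pcgs, distance_matrix, neighbor_joining, write_newick

logger = logging.getLogger(__name__)

__all__ = ["ReportBundle", "run_characterize", "run_concat", "load_input"]


@dataclass
class ReportBundle:
    """All tables produced by one characterization run."""

    summary: pd.DataFrame
    adjacency: pd.DataFrame
    architecture: dict
    composition: Optional[pd.DataFrame] = None
    codon: Optional[pd.DataFrame] = None
    control_region_hits: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)

    def write(self, outdir: Union[str, Path]) -> list[str]:
        """Write every table (TSV + JSON summary blocks) and a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def tsv(frame: pd.DataFrame, name: str, **kwargs) -> None:
            path = outdir / name
            frame.to_csv(path, sep="\t", **kwargs)
            written.append(name)

        tsv(self.summary, "summary.tsv", index=False)
        tsv(self.adjacency, "adjacency.tsv", index=False)
        (outdir / "architecture.json").write_text(json.dumps(self.architecture, indent=2))
        written.append("architecture.json")
        if self.composition is not None:
            tsv(composition_report(self.composition), "composition.tsv")
        if self.codon is not None:
            rounded = self.codon.copy()
            rounded["per_1000"] = rounded["per_1000"].round(2)
            rounded["RSCU"] = rounded["RSCU"].round(3)
            tsv(rounded, "codon_usage.tsv", index=False)
        if self.control_region_hits is not None:
            tsv(self.control_region_hits, "control_region_hits.tsv", index=False)
        manifest = {"outputs": written, **self.metadata}
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        written.append("run_manifest.json")
        return written


def load_input(
    genbank: Optional[str] = None,
    fasta: Optional[str] = None,
    gene_table: Optional[str] = None,
) -> tuple[Optional[SequenceRecord], MitogenomeAnnotation]:
    """Resolve the supported input combinations to (sequence?, annotation)."""
    if genbank:
        return read_genbank(genbank)
    if gene_table is None:
        raise ValueError("need either a GenBank file or a gene table (optionally with FASTA)")
    annotation = read_gene_table(gene_table)
    sequence = None
    if fasta:
        records = read_fasta(fasta)
        if len(records) != 1:
            raise ValueError(f"expected a single-record FASTA, found {len(records)} records")
        sequence = records[0]
        if len(sequence) != annotation.genome_length:
            raise ValueError(
                f"sequence length {len(sequence)} does not match "
                f"annotation genome_length {annotation.genome_length}"
            )
    return sequence, annotation


def _summary_table(annotation: MitogenomeAnnotation) -> pd.DataFrame:
    adjacency = compute_adjacencies(annotation)
    gaps = {r.upstream_gene: r.gap for r in adjacency}
    rows = []
    for f in annotation.sorted_by_start():
        rows.append(
            {
                "gene": f.name,
                "type": f.gene_type,
                "start": f.start,
                "end": f.end,
                "length_bp": gene_length(f, annotation.genome_length),
                "strand": f.strand,
                "intergenic_space": gaps.get(f.name, 0),
                "start_codon": f.start_codon or "",
                "stop_codon": f.stop_codon or "",
                "anticodon": f.anticodon or "",
            }
        )
    return pd.DataFrame(rows)


def _adjacency_table(annotation: MitogenomeAnnotation) -> pd.DataFrame:
    adjacency = compute_adjacencies(annotation)
    return pd.DataFrame(
        [
            {"upstream": r.upstream_gene, "downstream": r.downstream_gene,
             "gap": r.gap, "class": r.kind}
            for r in adjacency
        ]
    )


def _control_region_scan(
    sequence: SequenceRecord, annotation: MitogenomeAnnotation, params: dict
) -> Optional[pd.DataFrame]:
    candidates = control_region_candidate(compute_adjacencies(annotation))
    if not candidates:
        logger.info("no positive intergenic gap; control-region scan skipped")
        return None
    record = candidates[0]
    upstream = annotation.get(record.upstream_gene)
    region_start = upstream.end + 1
    region = sequence.sequence[region_start - 1 : region_start - 1 + record.gap]
    rows = []
    for hit in find_poly_t(region, params.get("poly_t_min_run", 5)):
        rows.append(("poly-T", hit.start, hit.end, hit.strand, hit.matched_text))
    for pattern in ("TATA", "GANT", "ATNC"):
        for hit in find_iupac_motif(region, pattern):
            rows.append((pattern, hit.start, hit.end, hit.strand, hit.matched_text))
    for rep in find_tandem_repeats(
        region,
        params.get("tandem_min_unit", 2),
        params.get("tandem_max_unit", 50),
        params.get("tandem_min_copies", 2),
    ):
        rows.append(
            (f"tandem[{rep.unit}x{rep.copies}]", rep.start, rep.end, "+", rep.text)
        )
    for sl in find_stem_loops(
        region,
        params.get("stem_min", 6),
        params.get("stem_max", 20),
        params.get("loop_min", 3),
        params.get("loop_max", 30),
    ):
        rows.append(
            (
                f"stem-loop[{sl.stem_len}/{sl.loop_len}]",
                sl.arm1_start,
                sl.arm2_start + sl.stem_len - 1,
                "+",
                region[sl.arm1_start - 1 : sl.arm2_start + sl.stem_len - 1],
            )
        )
    frame = pd.DataFrame(rows, columns=["motif_label", "start", "end", "strand", "matched_text"])
    frame.attrs["region_start"] = region_start
    frame.attrs["flanks"] = (record.upstream_gene, record.downstream_gene)
    return frame


def run_characterize(
    genbank: Optional[str] = None,
    fasta: Optional[str] = None,
    gene_table: Optional[str] = None,
    *,
    sequence: Optional[SequenceRecord] = None,
    annotation: Optional[MitogenomeAnnotation] = None,
    code: GeneticCode = INVERTEBRATE_MITO,
    params: Optional[dict] = None,
) -> ReportBundle:
    """Run the full characterization pipeline.

    Inputs may be file paths (GenBank, or gene table + optional FASTA)
    or in-memory objects.  Deterministic given its inputs.
    """
    params = params or {}
    if annotation is None:
        sequence, annotation = load_input(genbank, fasta, gene_table)

    adjacency = compute_adjacencies(annotation)
    arch = architecture_summary(adjacency)
    n_plus, n_minus = strand_distribution(annotation)
    inventory = trna_inventory(annotation)
    architecture = {
        "genome_length": annotation.genome_length,
        "taxon": annotation.taxon_label,
        "n_features": len(annotation),
        "strand_distribution": {"plus": n_plus, "minus": n_minus},
        "total_spacer_bp": arch.total_spacer_bp,
        "n_spacers": arch.n_spacers,
        "max_spacer": None
        if arch.max_spacer is None
        else {"upstream": arch.max_spacer.upstream_gene,
              "downstream": arch.max_spacer.downstream_gene, "gap": arch.max_spacer.gap},
        "total_overlap_bp": arch.total_overlap_bp,
        "n_overlaps": arch.n_overlaps,
        "max_overlap": None
        if arch.max_overlap is None
        else {"upstream": arch.max_overlap.upstream_gene,
              "downstream": arch.max_overlap.downstream_gene, "gap": arch.max_overlap.gap},
        "leading_gap": arch.leading_gap,
        "trna_missing": sorted(inventory.missing),
        "trna_duplicated": sorted(inventory.duplicated),
        "counts_by_type": inventory.counts_by_type,
    }

    composition = codon = hits = None
    if sequence is not None:
        composition = per_feature_composition(sequence, annotation)
        pcgs = annotation.of_type("PCG")
        if pcgs:
            cds_set = [extract_feature_sequence(sequence, f) for f in pcgs]
            table = codon_usage(cds_set, code=code)
            codon = codon_report(table)
            start_stops = []
            for f, cds in zip(pcgs, cds_set):
                codons, tail = split_codons(cds)
                rep = classify_start_stop(codons, tail, code, gene=f.name)
                start_stops.append(rep)
            architecture["start_stop"] = {
                r.gene: {"start": r.start_codon, "start_canonical": r.start_canonical,
                         "stop": r.stop_codon, "stop_complete": r.stop_complete}
                for r in start_stops
            }
        hits = _control_region_scan(sequence, annotation, params)
    else:
        logger.info("no sequence provided; sequence-dependent tables skipped")

    metadata = {
        "tool": "mitochar",
        "version": __version__,
        "taxon": annotation.taxon_label,
        "genetic_code": code.code_id,
        "inputs": {"genbank": genbank, "fasta": fasta, "gene_table": gene_table},
        "parameters": params,
    }
    return ReportBundle(
        summary=_summary_table(annotation),
        adjacency=_adjacency_table(annotation),
        architecture=architecture,
        composition=composition,
        codon=codon,
        control_region_hits=hits,
        metadata=metadata,
    )


def run_concat(
    gene_fastas: dict[str, str],
    outdir: Union[str, Path],
    *,
    order: tuple[str, ...] = PCG_ORDER,
    tree: bool = True,
    model: str = "JC69",
) -> dict[str, str]:
    """Build the supermatrix (and optionally an NJ tree) from per-gene FASTAs.

    ``gene_fastas`` maps gene name -> FASTA path with one record per
    taxon.  Writes supermatrix FASTA, partition TSV and, with three or
    more taxa, a Newick tree; returns the written paths.
    """
    per_taxon: dict[str, dict[str, str]] = {}
    for gene, path in gene_fastas.items():
        for rec in read_fasta(path):
            per_taxon.setdefault(rec.identifier, {})[gene] = rec.sequence
    rows = concatenate_pcgs(per_taxon, order=order)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}

    fasta_path = outdir / "supermatrix.fasta"
    write_fasta(
        [SequenceRecord(r.taxon_label, r.sequence) for r in rows], str(fasta_path)
    )
    outputs["supermatrix"] = str(fasta_path)

    part_path = outdir / "partitions.tsv"
    pd.DataFrame(
        [{"gene": g, "start": s, "end": e} for g, s, e in rows[0].partition_map]
    ).to_csv(part_path, sep="\t", index=False)
    outputs["partitions"] = str(part_path)

    if tree and len(rows) >= 3:
        dm = distance_matrix(rows, model=model)
        newick = write_newick(neighbor_joining(dm))
        tree_path = outdir / "nj_tree.nwk"
        tree_path.write_text(newick + "\n")
        outputs["tree"] = str(tree_path)
    return outputs
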