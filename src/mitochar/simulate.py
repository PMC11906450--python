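"""Packaged annotation fixtures and a seeded synthetic-genome generator.

Two kinds of test data back the pipeline:

* **Fixtures** — the published coordinate and composition tables for the
  *Thrips tabaci* and *T. parvispinus* mitogenomes, shipped as
  gene-table TSVs.  They are coordinate-only: no sequence is fabricated
  for the real species, so sequence-dependent stages are exercised on
  generated genomes instead.
* **Generator** — a reproducible simulator of annotated circular
  mitogenomes with planted architecture (gaps, overlaps, strands, a
  wrap-around gene), per-gene base composition, start/stop codons
  (including incomplete stops) and control-region elements (motifs,
  a poly-T stretch, a tandem repeat, a hairpin).  Every planted discrete
  structure is recoverable exactly by the corresponding analysis stage;
  composition targets are recovered within binomial sampling tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
import numpy as np
import pandas as pd

from .annotation import (
    GeneFeature,
    MitogenomeAnnotation,
    SequenceRecord,
    gene_length,
    read_gene_table,
    reverse_complement,
)

__all__ = [
    "SPECIES",
    "fixture_annotation",
    "fixture_table",
    "fixture_composition",
    "Plant",
    "GenomeSpec",
    "generate_genome",
    "default_test_suite_spec",
]

SPECIES = ("tabaci", "parvispinus")

_ANNOTATION_FILES = {
    "tabaci": "tabaci_table1.tsv",
    "parvispinus": "parvispinus_table3.tsv",
}
_COMPOSITION_FILES = {
    "tabaci": "tabaci_table2_composition.tsv",
    "parvispinus": "parvispinus_table4_composition.tsv",
}


def _data_path(filename: str):
    return resources.files("mitochar.data").joinpath(filename)


def fixture_annotation(species: str) -> MitogenomeAnnotation:
    """Packaged published annotation for ``tabaci`` or ``parvispinus``."""
    if species not in _ANNOTATION_FILES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    with _data_path(_ANNOTATION_FILES[species]).open() as handle:
        return read_gene_table(handle)


def fixture_table(species: str) -> pd.DataFrame:
    """The full packaged annotation table, including the published
    length and intergenic-space columns used for cross-checking."""
    if species not in _ANNOTATION_FILES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    with _data_path(_ANNOTATION_FILES[species]).open() as handle:
        return pd.read_csv(handle, sep="\t", comment="#", na_values=["."])


def fixture_composition(species: str) -> pd.DataFrame:
    """Published per-gene composition table (percentages, totals, skews)."""
    if species not in _COMPOSITION_FILES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    with _data_path(_COMPOSITION_FILES[species]).open() as handle:
        return pd.read_csv(handle, sep="\t", comment="#").set_index("gene")


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

_BASE_ORDER = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Plant:
    """A literal subsequence written verbatim into the genome.

    ``meta`` carries the expected analysis record (e.g. tandem-repeat
    unit/copies or hairpin arm coordinates) for oracle comparison.
    """

    label: str
    start: int  # genome coordinate, 1-based
    sequence: str
    meta: dict = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


@dataclass
class GenomeSpec:
    """Complete recipe for one synthetic annotated mitogenome."""

    genome_length: int
    layout: list[GeneFeature]
    composition: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    background: tuple[float, float, float, float] = (40.0, 12.0, 12.0, 36.0)  # A, C, G, T %
    plants: list[Plant] = field(default_factory=list)
    seed: int = 0
    taxon_label: str = "synthetic"
    #: extra manifest blocks (e.g. designed spacer/overlap records)
    notes: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, comp in list(self.composition.items()) + [("background", self.background)]:
            if any(p < 0 for p in comp):
                raise ValueError(f"negative composition percentage for {name}")
            if abs(sum(comp) - 100.0) > 1e-6:
                raise ValueError(f"composition for {name} must sum to 100, got {sum(comp)}")
        for f in self.layout:
            if max(f.start, f.end) > self.genome_length:
                raise ValueError(f"feature {f.name} outside genome")
        spans = sorted((p.start, p.end, p.label) for p in self.plants)
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"planted elements {l1} and {l2} overlap")
        for p in self.plants:
            if p.end > self.genome_length:
                raise ValueError(f"planted element {p.label} outside genome")

    def manifest(self) -> dict:
        """The plant manifest: everything the analyses should recover."""
        return {
            "seed": self.seed,
            "genome_length": self.genome_length,
            "layout": [
                {"gene": f.name, "type": f.gene_type, "start": f.start, "end": f.end,
                 "strand": f.strand}
                for f in self.layout
            ],
            "start_stops": {
                f.name: {"start_codon": (f.start_codon or "").upper(),
                         "stop_codon": (f.stop_codon or "").upper()}
                for f in self.layout
                if f.gene_type == "PCG"
            },
            "composition": {k: list(v) for k, v in self.composition.items()},
            "plants": [
                {"label": p.label, "start": p.start, "end": p.end,
                 "sequence": p.sequence, **p.meta}
                for p in self.plants
            ],
            **self.notes,
        }


def _sample(rng: np.random.Generator, length: int, comp: tuple[float, ...]) -> list[str]:
    probs = np.asarray(comp, dtype=float) / 100.0
    return list(rng.choice(_BASE_ORDER, size=length, p=probs))


def _place(genome: list[str], feature: GeneFeature, sense: list[str], n: int) -> None:
    placed = list(reverse_complement("".join(sense))) if feature.strand == "-" else sense
    if feature.is_wrap:
        tail = n - feature.start + 1
        genome[feature.start - 1 :] = placed[:tail]
        genome[: feature.end] = placed[tail:]
    else:
        genome[feature.start - 1 : feature.end] = placed


def generate_genome(spec: GenomeSpec) -> tuple[SequenceRecord, MitogenomeAnnotation]:
    """Sample a genome realizing a :class:`GenomeSpec`.

    Regions are sampled per-position from their composition vector.
    PCGs begin with their specified start codon and end with their
    (possibly incomplete) stop codon on the sense strand; planted
    elements are written verbatim last.  Identical seeds give
    byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.genome_length
    genome = _sample(rng, n, spec.background)

    # non-coding features first, PCGs second so overlap overwrites never
    # clobber a planted start/stop codon
    ordered = [f for f in spec.layout if f.gene_type != "PCG"] + [
        f for f in spec.layout if f.gene_type == "PCG"
    ]
    for feature in ordered:
        length = gene_length(feature, n)
        comp = spec.composition.get(feature.name, spec.background)
        sense = _sample(rng, length, comp)
        if feature.gene_type == "PCG":
            start = (feature.start_codon or "ATG").upper()
            stop = (feature.stop_codon or "TAA").upper()
            if length < len(start) + len(stop):
                raise ValueError(f"PCG {feature.name} too short for its codons")
            sense[: len(start)] = list(start)
            sense[length - len(stop) :] = list(stop)
        _place(genome, feature, sense, n)

    for plant in spec.plants:
        genome[plant.start - 1 : plant.end] = list(plant.sequence.upper())

    record = SequenceRecord(spec.taxon_label, "".join(genome))
    annotation = MitogenomeAnnotation(
        genome_length=n, features=list(spec.layout), circular=True,
        taxon_label=spec.taxon_label,
    )
    return record, annotation


def default_test_suite_spec(seed: int = 0) -> GenomeSpec:
    """A compact spec exercising every feature class the pipeline handles.

    An ~6 kb, 8-gene circular genome with: a wrap-around PCG spanning
    the origin, a minus-strand PCG with an incomplete stop, one 5 bp
    gene overlap, and a 300 bp spacer (the control-region candidate)
    carrying a planted TATA box, GAnT and ATnC motifs, an 8 bp poly-T
    stretch, an ACGT x 4 tandem array and a stem-8/loop-5 hairpin.
    """
    layout = [
        GeneFeature("geneA", "PCG", 101, 3100, "+", start_codon="att", stop_codon="taa"),
        GeneFeature("trnX", "tRNA", 3110, 3172, "+", anticodon="tag"),
        GeneFeature("geneB", "PCG", 3180, 4167, "-", start_codon="ata", stop_codon="t"),
        GeneFeature("trnY", "tRNA", 4163, 4225, "+", anticodon="gta"),
        GeneFeature("rrnX", "rRNA", 4231, 4630, "+"),
        GeneFeature("geneC", "PCG", 4931, 5830, "+", start_codon="atg", stop_codon="taa"),
        GeneFeature("trnZ", "tRNA", 5840, 5902, "-", anticodon="gtt"),
        GeneFeature("geneD", "PCG", 5951, 98, "+", start_codon="atg", stop_codon="taa"),
    ]
    cr_start = 4631  # control region: the 300 bp spacer rrnX -> geneC
    plants = [
        Plant("TATA", 4650, "CTATAC", {"motif": "TATA", "hit_start": 4651, "hit_end": 4654}),
        Plant("GAnT", 4680, "CGAATC", {"motif": "GANT", "hit_start": 4681, "hit_end": 4684}),
        Plant("ATnC", 4700, "GATTCG", {"motif": "ATNC", "hit_start": 4701, "hit_end": 4704}),
        Plant("poly-T", 4730, "A" + "T" * 8 + "A", {"run_start": 4731, "run_end": 4738}),
        Plant("tandem", 4760, "C" + "ACGT" * 4 + "C",
              {"unit": "ACGT", "copies": 4, "array_start": 4761, "array_end": 4776}),
        Plant("hairpin", 4800, "A" + "GGCGACCT" + "AATAA" + "AGGTCGCC" + "A",
              {"stem_len": 8, "loop_len": 5, "arm1_start": 4801, "arm2_start": 4814}),
    ]
    spec = GenomeSpec(
        genome_length=6050,
        layout=layout,
        composition={
            "geneA": (41.0, 12.0, 12.0, 35.0),
            "geneB": (38.0, 13.0, 11.0, 38.0),
            "rrnX": (43.0, 10.0, 11.0, 36.0),
        },
        plants=plants,
        seed=seed,
        taxon_label=f"synthetic-suite-{seed}",
        notes={
            "control_region": {"start": cr_start, "end": cr_start + 299,
                               "upstream": "rrnX", "downstream": "geneC", "gap": 300},
            "overlap": {"upstream": "geneB", "downstream": "trnY", "gap": -5},
        },
    )
    spec.validate()
    return spec
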