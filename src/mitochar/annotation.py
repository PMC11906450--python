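"""Domain types and I/O for annotated circular mitochondrial genomes.

Coordinates are 1-based and fully inclusive throughout, matching the
convention of published mitogenome summary tables.  Conversion to the
0-based half-open convention happens only inside readers and writers.
The origin of a circular genome lies between position ``genome_length``
and position 1; a feature whose ``end`` is smaller than its ``start`` is
a wrap-around feature spanning the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

from Bio import SeqIO

__all__ = [
    "GeneFeature",
    "MitogenomeAnnotation",
    "SequenceRecord",
    "GENE_TYPES",
    "normalize_gene_name",
    "gene_length",
    "extract_feature_sequence",
    "reverse_complement",
    "read_gene_table",
    "write_gene_table",
    "read_genbank",
    "read_fasta",
    "write_fasta",
]

GENE_TYPES = ("PCG", "tRNA", "rRNA", "other")

#: Strand symbols accepted on read.  "H" (heavy) and "L" (light) are the
#: strand names used in the mitochondrial literature; the Unicode minus
#: and en-dash appear in typeset tables.
_STRAND_ALIASES = {
    "+": "+", "H": "+", "h": "+",
    "-": "-", "−": "-", "–": "-", "L": "-", "l": "-",
}

# Canonical lower-case symbols for the 13 protein-coding genes, the two
# rRNAs and the 22 tRNAs; upper-case annotation-pipeline spellings are
# folded onto these so user files and packaged tables share one scheme.
_NAME_ALIASES = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3",
    "atp6": "atp6", "atp8": "atp8",
    "cytb": "cytB", "cob": "cytB", "cytochromeb": "cytB",
    "nad1": "nad1", "nd1": "nad1",
    "nad2": "nad2", "nd2": "nad2",
    "nad3": "nad3", "nd3": "nad3",
    "nad4": "nad4", "nd4": "nad4",
    "nad4l": "nad4L", "nd4l": "nad4L",
    "nad5": "nad5", "nd5": "nad5",
    "nad6": "nad6", "nd6": "nad6",
    "rrnl": "rrnL", "rrn16": "rrnL", "16s": "rrnL",
    "rrns": "rrnS", "rrn12": "rrnS", "12s": "rrnS",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_gene_name(name: str) -> str:
    """Fold a gene symbol onto the canonical naming scheme.

    ``COX1`` -> ``cox1``, ``CYTB``/``cob`` -> ``cytB``, ``ND4L`` ->
    ``nad4L``; tRNA symbols keep their isoacceptor suffix (``trnS1``).
    Unknown symbols are returned unchanged.
    """
    key = name.strip().replace("-", "").replace("_", "").lower()
    if key in _NAME_ALIASES:
        return _NAME_ALIASES[key]
    if key.startswith("trn") and len(key) >= 4:
        # trnX / trnS1 style: upper-case the amino-acid letter only
        return "trn" + key[3].upper() + key[4:]
    return name.strip()


def _clean_strand(symbol: str) -> str:
    try:
        return _STRAND_ALIASES[symbol.strip()]
    except KeyError:
        raise ValueError(f"unknown strand symbol: {symbol!r}") from None


@dataclass
class GeneFeature:
    """One annotated element of a mitogenome.

    ``start``/``end`` are 1-based inclusive.  ``end < start`` denotes a
    wrap-around feature on a circular genome.  ``length_override``
    records a published length that differs from the coordinate-derived
    one (some tables report spliced or trimmed lengths).
    """

    name: str
    gene_type: str
    start: int
    end: int
    strand: str
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    length_override: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"gene_type must be one of {GENE_TYPES}, got {self.gene_type!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: positions are 1-based, got start={self.start} end={self.end}")
        self.strand = _clean_strand(self.strand)
        if self.anticodon is not None and self.gene_type != "tRNA":
            raise ValueError(f"{self.name}: anticodon is only valid on tRNA features")
        if (self.start_codon or self.stop_codon) and self.gene_type != "PCG":
            raise ValueError(f"{self.name}: start/stop codons are only valid on PCG features")

    @property
    def is_wrap(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int, *, use_override: bool = False) -> int:
        if use_override and self.length_override is not None:
            return self.length_override
        return gene_length(self, genome_length)


def gene_length(feature: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circular genome of ``genome_length``.

    Non-wrap features: ``end - start + 1``.  Wrap-around features run
    from ``start`` through the origin to ``end``.
    """
    if not (1 <= feature.start <= genome_length and 1 <= feature.end <= genome_length):
        raise ValueError(
            f"{feature.name}: coordinates ({feature.start}, {feature.end}) "
            f"outside [1, {genome_length}]"
        )
    if feature.is_wrap:
        return (genome_length - feature.start + 1) + feature.end
    return feature.end - feature.start + 1


@dataclass
class MitogenomeAnnotation:
    """Circular genome length plus an ordered list of features."""

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.name} ({f.start}..{f.end}) exceeds genome_length {self.genome_length}"
                )
            if f.is_wrap and not self.circular:
                raise ValueError(f"wrap-around feature {f.name} on a non-circular annotation")

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def sorted_by_start(self) -> list[GeneFeature]:
        """Features in ascending start order; ties broken longer-first."""
        return sorted(
            self.features,
            key=lambda f: (f.start, -gene_length(f, self.genome_length)),
        )

    def get(self, name: str) -> GeneFeature:
        wanted = normalize_gene_name(name)
        for f in self.features:
            if normalize_gene_name(f.name) == wanted:
                return f
        raise KeyError(name)

    def of_type(self, gene_type: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_type == gene_type]


@dataclass
class SequenceRecord:
    """A nucleotide sequence over {A,C,G,T,N}, upper-case canonical."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.identifier}: ambiguity codes other than N are not supported: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_feature_sequence(genome: Union[SequenceRecord, str], feature: GeneFeature) -> str:
    """Sense-strand sequence of a feature.

    Plus-strand features return the genomic slice; minus-strand features
    return its reverse complement.  Wrap-around features concatenate the
    tail (start..genome end) and head (1..end) slices before strand
    processing.
    """
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    n = len(seq)
    if feature.start > n or feature.end > n:
        raise ValueError(
            f"{feature.name}: coordinates ({feature.start}, {feature.end}) outside sequence of length {n}"
        )
    if feature.is_wrap:
        plus = seq[feature.start - 1 :] + seq[: feature.end]
    else:
        plus = seq[feature.start - 1 : feature.end]
    return reverse_complement(plus) if feature.strand == "-" else plus


# ---------------------------------------------------------------------------
# Gene-table TSV
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("gene", "type", "start", "end", "strand")
_OPTIONAL_COLUMNS = ("anticodon", "start_codon", "stop_codon", "length_override")
_MISSING = "."


def read_gene_table(
    source: Union[str, TextIO],
    *,
    genome_length: Optional[int] = None,
    normalize_names: bool = True,
) -> MitogenomeAnnotation:
    """Read a gene-coordinate table (tab-delimited, ``.`` = absent).

    Required columns: gene, type, start, end, strand.  Optional:
    anticodon, start_codon, stop_codon, length_override.  Header comment
    lines ``#genome_length=``, ``#taxon=`` and ``#circular=`` carry
    annotation-level metadata; ``genome_length`` passed as an argument
    wins over the header.
    """
    close = False
    if isinstance(source, str):
        handle: TextIO = open(source)
        close = True
    else:
        handle = source
    try:
        meta: dict[str, str] = {}
        header: Optional[list[str]] = None
        rows: list[dict[str, str]] = []
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in _REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"gene table missing required column(s): {missing}")
                continue
            rows.append(dict(zip(header, cells)))
        if header is None or not rows:
            raise ValueError("gene table contains no features")

        features = []
        for row in rows:
            def opt(col: str) -> Optional[str]:
                v = row.get(col, _MISSING).strip()
                return None if v in (_MISSING, "", "-", "–") else v

            name = row["gene"].strip()
            if normalize_names:
                name = normalize_gene_name(name)
            try:
                start = int(row["start"])
                end = int(row["end"])
            except ValueError:
                raise ValueError(f"non-integer coordinate in row for {name!r}") from None
            override = opt("length_override")
            features.append(
                GeneFeature(
                    name=name,
                    gene_type=row["type"].strip(),
                    start=start,
                    end=end,
                    strand=row["strand"],
                    anticodon=opt("anticodon"),
                    start_codon=opt("start_codon"),
                    stop_codon=opt("stop_codon"),
                    length_override=int(override) if override else None,
                )
            )

        if genome_length is None:
            if "genome_length" in meta:
                genome_length = int(meta["genome_length"])
            else:
                genome_length = max(max(f.start, f.end) for f in features)
        circular = meta.get("circular", "true").lower() != "false"
        return MitogenomeAnnotation(
            genome_length=genome_length,
            features=features,
            circular=circular,
            taxon_label=meta.get("taxon", ""),
        )
    finally:
        if close:
            handle.close()


def write_gene_table(annotation: MitogenomeAnnotation, target: Union[str, TextIO]) -> None:
    """Write the gene-table TSV (inverse of :func:`read_gene_table`)."""
    close = False
    if isinstance(target, str):
        handle: TextIO = open(target, "w")
        close = True
    else:
        handle = target
    try:
        handle.write(f"#genome_length={annotation.genome_length}\n")
        handle.write(f"#circular={'true' if annotation.circular else 'false'}\n")
        if annotation.taxon_label:
            handle.write(f"#taxon={annotation.taxon_label}\n")
        cols = _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS
        handle.write("\t".join(cols) + "\n")
        for f in annotation.features:
            handle.write(
                "\t".join(
                    [
                        f.name,
                        f.gene_type,
                        str(f.start),
                        str(f.end),
                        f.strand,
                        f.anticodon or _MISSING,
                        f.start_codon or _MISSING,
                        f.stop_codon or _MISSING,
                        str(f.length_override) if f.length_override is not None else _MISSING,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# GenBank / FASTA
# ---------------------------------------------------------------------------

_GENBANK_TYPE_MAP = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(source: Union[str, TextIO]) -> tuple[SequenceRecord, MitogenomeAnnotation]:
    """Read a GenBank flat file into (sequence, annotation).

    CDS/tRNA/rRNA features become :class:`GeneFeature`; ``complement``
    locations map to strand ``-``; a two-part ``join(a..L, 1..b)``
    becomes a wrap-around feature.  Bare ``gene`` features duplicated by
    a CDS/tRNA/rRNA with the same span are dropped.
    """
    record = SeqIO.read(source, "genbank")
    if len(record.seq) == 0:
        raise ValueError("GenBank record has no sequence")
    seq = SequenceRecord(record.id or record.name or "genbank", str(record.seq))
    n = len(seq)

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _GENBANK_TYPE_MAP:
            continue
        gene_type = _GENBANK_TYPE_MAP[feat.type]
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or quals.get("locus_tag") or ["?"])[0]
        strand = "-" if feat.location.strand == -1 else "+"
        parts = list(feat.location.parts)
        if len(parts) == 1:
            start = int(parts[0].start) + 1
            end = int(parts[0].end)
        elif len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            # origin-spanning join(a..N, 1..b)
            start = int(parts[0].start) + 1
            end = int(parts[1].end)
        else:
            raise ValueError(f"unsupported compound location for {name}: {feat.location}")
        anticodon = None
        if gene_type == "tRNA" and "anticodon" in quals:
            ac = quals["anticodon"][0]
            anticodon = ac.split("seq:")[-1].rstrip(")").strip().lower() if "seq:" in ac else ac.lower()
        features.append(
            GeneFeature(
                name=normalize_gene_name(name),
                gene_type=gene_type,
                start=start,
                end=end,
                strand=strand,
                anticodon=anticodon,
            )
        )
    annotation = MitogenomeAnnotation(
        genome_length=n,
        features=features,
        circular="circular" in str(record.annotations.get("topology", "")).lower() or True,
        taxon_label=str(record.annotations.get("organism", record.id or "")),
    )
    return seq, annotation


def read_fasta(source: Union[str, TextIO]) -> list[SequenceRecord]:
    return [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(source, "fasta")]


def write_fasta(records: Iterable[SequenceRecord], target: Union[str, TextIO]) -> None:
    close = False
    if isinstance(target, str):
        handle: TextIO = open(target, "w")
        close = True
    else:
        handle = target
    try:
        for rec in records:
            handle.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), 70):
                handle.write(rec.sequence[i : i + 70] + "\n")
    finally:
        if close:
            handle.close()
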