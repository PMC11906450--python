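"""String-level motif and structure scanners for control regions.

Animal mitochondrial control regions carry characteristic elements —
poly-T stretches, TATA boxes, conserved GAnT/ATnC motifs, tandem
repeats and stem-loop (inverted repeat) structures.  These scanners are
exact (no mismatch model) and operate on a region string with 1-based
inclusive coordinates.  No thermodynamic folding is attempted: a "stem
loop" here is a pair of exact reverse-complement arms enclosing a loop
within configured bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import reverse_complement

__all__ = [
    "MotifHit",
    "TandemRepeatRecord",
    "StemLoopRecord",
    "find_poly_t",
    "find_iupac_motif",
    "find_tandem_repeats",
    "find_stem_loops",
    "IUPAC",
]

#: IUPAC nucleotide codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifHit:
    motif_label: str
    start: int
    end: int
    strand: str
    matched_text: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if len(self.matched_text) != self.end - self.start + 1:
            raise ValueError("matched_text length inconsistent with coordinates")


@dataclass(frozen=True)
class TandemRepeatRecord:
    unit: str
    copies: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.copies * len(self.unit) != self.end - self.start + 1:
            raise ValueError("copies * unit length must equal the spanned length")

    @property
    def text(self) -> str:
        return self.unit * self.copies


@dataclass(frozen=True)
class StemLoopRecord:
    stem_len: int
    loop_len: int
    arm1_start: int
    arm2_start: int


def find_poly_t(region: str, min_run: int = 5) -> list[MotifHit]:
    """Maximal runs of T of length >= ``min_run`` (the "T-stretch")."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    region = region.upper()
    hits = []
    i = 0
    n = len(region)
    while i < n:
        if region[i] == "T":
            j = i
            while j < n and region[j] == "T":
                j += 1
            if j - i >= min_run:
                hits.append(
                    MotifHit("poly-T", start=i + 1, end=j, strand="+", matched_text=region[i:j])
                )
            i = j
        else:
            i += 1
    return hits


def _iupac_match(text: str, pattern: str) -> bool:
    return all(base in IUPAC[sym] for base, sym in zip(text, pattern))


def find_iupac_motif(region: str, pattern: str, both_strands: bool = False) -> list[MotifHit]:
    """All (possibly overlapping) matches of an IUPAC pattern.

    With ``both_strands`` the reverse complement of the region is also
    scanned; minus-strand hits are reported in the coordinates of the
    given region.
    """
    region = region.upper()
    pattern = pattern.upper().replace("U", "T")
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbol(s) in pattern: {sorted(bad)}")
    m = len(pattern)
    hits = []
    for i in range(len(region) - m + 1):
        window = region[i : i + m]
        if "N" not in window and _iupac_match(window, pattern):
            hits.append(MotifHit(pattern, start=i + 1, end=i + m, strand="+", matched_text=window))
    if both_strands:
        for i in range(len(region) - m + 1):
            window = region[i : i + m]
            if "N" not in window and _iupac_match(reverse_complement(window), pattern):
                hits.append(
                    MotifHit(pattern, start=i + 1, end=i + m, strand="-", matched_text=window)
                )
    return hits


def _smallest_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


def find_tandem_repeats(
    region: str, min_unit: int = 2, max_unit: int = 50, min_copies: int = 2
) -> list[TandemRepeatRecord]:
    """Maximal exact tandem arrays of unit length within the given range.

    Arrays whose unit is itself periodic are reported once with the
    smallest (primitive) unit; homopolymer arrays only when
    ``min_unit == 1``.  An array is maximal when it cannot be extended
    by a full copy on the left and has no further full copy on the
    right; records are ordered by start position.
    """
    if not (1 <= min_unit <= max_unit):
        raise ValueError("need 1 <= min_unit <= max_unit")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    region = region.upper()
    n = len(region)
    records = []
    for u in range(min_unit, max_unit + 1):
        for i in range(n - 2 * u + 1):
            unit = region[i : i + u]
            if _smallest_period(unit) != u:
                continue  # only primitive units
            if u == 1 and min_unit > 1:
                continue
            # left-maximality: the unit must not also precede position i
            if i >= u and region[i - u : i] == unit:
                continue
            copies = 1
            while region[i + copies * u : i + (copies + 1) * u] == unit:
                copies += 1
            if copies >= min_copies:
                records.append(
                    TandemRepeatRecord(unit=unit, copies=copies, start=i + 1, end=i + copies * u)
                )
    # shifted phases of one array (e.g. CGAx2 inside ACGx3) are contained
    # in the full-span record of the same period; keep only the longest
    def redundant(r: TandemRepeatRecord) -> bool:
        return any(
            len(q.unit) == len(r.unit)
            and q.start <= r.start
            and r.end <= q.end
            and (q.start, q.end) != (r.start, r.end)
            for q in records
        )

    records = [r for r in records if not redundant(r)]
    records.sort(key=lambda r: (r.start, len(r.unit)))
    return records


def find_stem_loops(
    region: str,
    min_stem: int = 6,
    max_stem: int = 20,
    min_loop: int = 3,
    max_loop: int = 30,
) -> list[StemLoopRecord]:
    """Inverted-repeat stem-loop candidates.

    Reports every pair of exact reverse-complement arms of length
    ``min_stem``..``max_stem`` enclosing a loop of length within bounds,
    after suppressing hits whose two arms are both contained inside the
    arms of a longer reported hit.
    """
    if min_stem < 3:
        raise ValueError("min_stem must be >= 3")
    region = region.upper()
    n = len(region)
    raw: list[StemLoopRecord] = []
    for stem in range(min_stem, max_stem + 1):
        for i in range(n - 2 * stem - min_loop + 1):
            arm1 = region[i : i + stem]
            if "N" in arm1:
                continue
            want = reverse_complement(arm1)
            lo = i + stem + min_loop
            hi = min(i + stem + max_loop, n - stem)
            for j in range(lo, hi + 1):
                if region[j : j + stem] == want:
                    raw.append(
                        StemLoopRecord(
                            stem_len=stem,
                            loop_len=j - (i + stem),
                            arm1_start=i + 1,
                            arm2_start=j + 1,
                        )
                    )

    def contained(a: StemLoopRecord, b: StemLoopRecord) -> bool:
        """True when a's arms lie within b's arms and b is strictly longer."""
        if b.stem_len <= a.stem_len:
            return False
        a1 = (a.arm1_start, a.arm1_start + a.stem_len - 1)
        a2 = (a.arm2_start, a.arm2_start + a.stem_len - 1)
        b1 = (b.arm1_start, b.arm1_start + b.stem_len - 1)
        b2 = (b.arm2_start, b.arm2_start + b.stem_len - 1)
        return b1[0] <= a1[0] and a1[1] <= b1[1] and b2[0] <= a2[0] and a2[1] <= b2[1]

    kept = [a for a in raw if not any(contained(a, b) for b in raw)]
    kept.sort(key=lambda r: (r.arm1_start, r.arm2_start, r.stem_len))
    return kept
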