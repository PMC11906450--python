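"""Control-region scanners against brute-force oracles."""

import numpy as np
import pytest

from mitochar.annotation import reverse_complement
from mitochar.motifs import (
    IUPAC,
    find_iupac_motif,
    find_poly_t,
    find_stem_loops,
    find_tandem_repeats,
)


def random_region(seed, length, at_rich=True):
    rng = np.random.default_rng(seed)
    p = [0.38, 0.12, 0.12, 0.38] if at_rich else [0.25] * 4
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


# ---------------------------------------------------------------------------
# oracles: deliberately naive, position-by-position implementations
# ---------------------------------------------------------------------------

def oracle_poly_t(region, min_run):
    hits = []
    for i in range(len(region)):
        if region[i] == "T" and (i == 0 or region[i - 1] != "T"):
            j = i
            while j < len(region) and region[j] == "T":
                j += 1
            if j - i >= min_run:
                hits.append((i + 1, j))
    return hits


def oracle_iupac(region, pattern):
    out = []
    m = len(pattern)
    for i in range(len(region) - m + 1):
        window = region[i : i + m]
        if "N" in window:
            continue
        if all(window[k] in IUPAC[pattern[k]] for k in range(m)):
            out.append(i + 1)
    return out


def oracle_tandem(region, min_unit, max_unit, min_copies):
    """Exhaustive enumeration of all (start, unit, copies) triples,
    filtered to primitive units and left/right maximality."""
    found = set()
    n = len(region)
    for u in range(min_unit, max_unit + 1):
        for i in range(n):
            unit = region[i : i + u]
            if len(unit) < u:
                break
            # primitive unit check
            if any(u % p == 0 and unit == unit[:p] * (u // p) for p in range(1, u)):
                continue
            copies = 1
            while region[i + copies * u : i + copies * u + u] == unit:
                copies += 1
            if copies < min_copies:
                continue
            if i >= u and region[i - u : i] == unit:
                continue  # extendable left
            found.add((i + 1, unit, copies))
    # drop shifted phases contained in a same-period record's span
    kept = set()
    for start, unit, copies in found:
        end = start + copies * len(unit) - 1
        if not any(
            len(u2) == len(unit) and s2 <= start and end <= s2 + c2 * len(u2) - 1
            and (s2, s2 + c2 * len(u2) - 1) != (start, end)
            for s2, u2, c2 in found
        ):
            kept.add((start, unit, copies))
    return kept


def oracle_stem_loops(region, min_stem, max_stem, min_loop, max_loop):
    """All arm pairs by dictionary lookup of reverse complements, then
    containment suppression."""
    n = len(region)
    raw = []
    for stem in range(min_stem, max_stem + 1):
        positions = {}
        for i in range(n - stem + 1):
            positions.setdefault(region[i : i + stem], []).append(i)
        for i in range(n - stem + 1):
            arm = region[i : i + stem]
            if "N" in arm:
                continue
            for j in positions.get(reverse_complement(arm), []):
                loop = j - (i + stem)
                if min_loop <= loop <= max_loop:
                    raw.append((i + 1, j + 1, stem))
    def contained(a, b):
        (a1, a2, sa), (b1, b2, sb) = a, b
        if sb <= sa:
            return False
        return (b1 <= a1 and a1 + sa <= b1 + sb) and (b2 <= a2 and a2 + sa <= b2 + sb)
    return {a for a in raw if not any(contained(a, b) for b in raw)}


class TestPolyT:
    def test_examples(self):
        (hit,) = find_poly_t("AATTTTTAA", 5)
        assert (hit.start, hit.end, hit.matched_text) == (3, 7, "TTTTT")
        assert find_poly_t("ACGACG", 2) == []

    def test_min_run_validated(self):
        with pytest.raises(ValueError):
            find_poly_t("TTTT", 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_run_length_oracle(self, seed):
        region = random_region(seed, 800)
        hits = find_poly_t(region, 4)
        assert [(h.start, h.end) for h in hits] == oracle_poly_t(region, 4)


class TestIUPAC:
    def test_examples(self):
        (hit,) = find_iupac_motif("GACT", "GANT")
        assert (hit.start, hit.matched_text) == (1, "GACT")
        (hit,) = find_iupac_motif("CTATAC", "TATA")
        assert hit.start == 2

    def test_overlapping_matches_reported(self):
        hits = find_iupac_motif("TATATA", "TATA")
        assert [h.start for h in hits] == [1, 3]

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            find_iupac_motif("ACGT", "AXGT")

    def test_both_strands_mirror(self):
        region = "GGGATTC"
        plus_only = find_iupac_motif(region, "GAAT")
        both = find_iupac_motif(region, "GAAT", both_strands=True)
        assert plus_only == []
        assert [(h.start, h.strand) for h in both] == [(4, "-")]

    @pytest.mark.parametrize("pattern", ["GANT", "ATNC", "TATA", "TWTW"])
    def test_matches_oracle(self, pattern):
        region = random_region(11, 600)
        assert [h.start for h in find_iupac_motif(region, pattern)] == oracle_iupac(
            region, pattern
        )


class TestTandemRepeats:
    def test_triplet_array(self):
        (rec,) = find_tandem_repeats("ACGACGACG", 2, 5, 2)
        assert (rec.unit, rec.copies, rec.start, rec.end) == ("ACG", 3, 1, 9)
        assert rec.text == "ACGACGACG"

    def test_no_array(self):
        assert find_tandem_repeats("ACGTACGA", 2, 5, 2) == []

    def test_homopolymers_only_when_unit_one(self):
        assert find_tandem_repeats("AAAA", 2, 5, 2) == []
        recs = find_tandem_repeats("AAAA", 1, 5, 2)
        assert [(r.unit, r.copies) for r in recs] == [("A", 4)]

    def test_periodic_unit_reported_once_with_smallest(self):
        recs = find_tandem_repeats("ATATATAT", 2, 4, 2)
        assert [(r.unit, r.copies) for r in recs] == [("AT", 4)]

    def test_record_reconstructs_source(self):
        region = random_region(21, 400) + "CTTAGTTAGTTAGC" + random_region(22, 100)
        for rec in find_tandem_repeats(region, 2, 10, 2):
            assert region[rec.start - 1 : rec.end] == rec.unit * rec.copies

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        region = random_region(seed + 50, 500)
        if seed == 0:  # one planted array amid random sequence
            region = region[:200] + "C" + "ACGGT" * 3 + "C" + region[200:]
        got = {(r.start, r.unit, r.copies) for r in find_tandem_repeats(region, 2, 8, 2)}
        assert got == oracle_tandem(region, 2, 8, 2)


class TestStemLoops:
    def test_hand_checkable_palindrome(self):
        hits = find_stem_loops("GGGAAATTTCCC", min_stem=3, max_stem=3, min_loop=3, max_loop=8)
        assert any(
            (h.arm1_start, h.arm2_start, h.stem_len, h.loop_len) == (1, 10, 3, 6) for h in hits
        )

    def test_poly_a_empty(self):
        assert find_stem_loops("A" * 60, 3, 10, 3, 10) == []

    def test_min_stem_validated(self):
        with pytest.raises(ValueError):
            find_stem_loops("ACGT", min_stem=2)

    def test_planted_hairpin_recovered(self):
        region = random_region(31, 200) + "AGGCGACCTAATAAAGGTCGCCA" + random_region(32, 100)
        hits = find_stem_loops(region, 6, 20, 3, 30)
        assert any(h.stem_len == 8 and h.loop_len == 5 and h.arm1_start == 202 for h in hits)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle(self, seed):
        region = random_region(seed + 70, 300, at_rich=False)
        got = {(h.arm1_start, h.arm2_start, h.stem_len)
               for h in find_stem_loops(region, 4, 10, 3, 20)}
        assert got == oracle_stem_loops(region, 4, 10, 3, 20)

    def test_mirror_under_reverse_complement(self):
        region = random_region(41, 250, at_rich=False)
        fwd = find_stem_loops(region, 4, 10, 3, 15)
        rev = find_stem_loops(reverse_complement(region), 4, 10, 3, 15)
        n = len(region)
        mirrored = {
            (n - (h.arm2_start + h.stem_len - 1) + 1, n - (h.arm1_start + h.stem_len - 1) + 1,
             h.stem_len)
            for h in fwd
        }
        assert mirrored == {(h.arm1_start, h.arm2_start, h.stem_len) for h in rev}
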