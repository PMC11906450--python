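"""Scan a control region for the elements reported in mitogenome papers:
a T-stretch, TATA box, GAnT/ATnC motifs, tandem repeats and stem-loops.

The region scanned is the longest intergenic spacer of the synthetic
genome, which carries one planted instance of each element class.
"""

from mitochar import compute_adjacencies, control_region_candidate
from mitochar.motifs import (
    find_iupac_motif,
    find_poly_t,
    find_stem_loops,
    find_tandem_repeats,
)
from mitochar.simulate import default_test_suite_spec, generate_genome

spec = default_test_suite_spec(seed=1)
sequence, annotation = generate_genome(spec)
(cr,) = control_region_candidate(compute_adjacencies(annotation))
upstream = annotation.get(cr.upstream_gene)
region = sequence.sequence[upstream.end : upstream.end + cr.gap]
print(f"control region: {cr.gap} bp between {cr.upstream_gene} and {cr.downstream_gene}")

runs = find_poly_t(region, min_run=5)
print(f"poly-T stretches (>=5): {[(h.start, h.end) for h in runs]}")
for pattern in ("TATA", "GANT", "ATNC"):
    hits = find_iupac_motif(region, pattern)
    print(f"{pattern} motif: {len(hits)} hit(s), first at {hits[0].start if hits else '-'}")
for rep in find_tandem_repeats(region, 2, 50, 2):
    print(f"tandem repeat: {rep.unit} x {rep.copies} at {rep.start}-{rep.end}")
for sl in find_stem_loops(region, 6, 20, 3, 30):
    print(f"stem-loop: stem {sl.stem_len} bp / loop {sl.loop_len} bp, "
          f"arms at {sl.arm1_start} and {sl.arm2_start}")

# Positions are 1-based within the scanned region.  All matches are
# exact; hairpins are string-level inverted repeats, not folded structures.
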