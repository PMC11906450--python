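"""Recompute AT/GC skews from a published per-gene composition table.

AT skew = (A-T)/(A+T) and GC skew = (G-C)/(G+C) measure the
compositional asymmetry of each gene's sense strand.  Both are
scale-invariant, so the published percentages are as good as counts.
"""

from mitochar import at_skew, gc_skew
from mitochar.composition import round_half_away
from mitochar.simulate import fixture_composition

comp = fixture_composition("tabaci")
print(f"{'gene':8s} {'AT skew':>8s} {'GC skew':>8s}")
for gene, row in comp.iterrows():
    at = round_half_away(at_skew(row.pct_A, row.pct_T), 3)
    gc = round_half_away(gc_skew(row.pct_G, row.pct_C), 3)
    print(f"{gene:8s} {at:8.3f} {gc:8.3f}")

# Negative AT skew (e.g. nad5: -0.357) means T outnumbers A on the
# sense strand — typical of minus-strand NADH dehydrogenase genes.
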