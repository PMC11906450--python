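"""Codon usage and RSCU of the protein-coding genes of a genome.

RSCU compares each codon's count with the uniform expectation within
its synonymous family: RSCU > 1 means the codon is over-used.  The
invertebrate mitochondrial code (NCBI table 5) is the default.
"""

from mitochar import amino_acid_usage, codon_usage, extract_feature_sequence, rscu
from mitochar.simulate import default_test_suite_spec, generate_genome

sequence, annotation = generate_genome(default_test_suite_spec(seed=1))
cds_set = [extract_feature_sequence(sequence, f) for f in annotation.of_type("PCG")]
table = codon_usage(cds_set)
values = rscu(table)
freqs = table.per_1000()

print(f"{table.n_codons_total} codons pooled over {len(cds_set)} genes")
top = sorted(values, key=lambda c: table.counts[c], reverse=True)[:5]
print("most used codons (count, per-1000, RSCU):")
for codon in top:
    print(f"  {codon.replace('T', 'U')}  {table.counts[codon]:4d}  "
          f"{freqs[codon]:6.1f}  {values[codon]:.3f}")
aa = amino_acid_usage(table)
print("top amino acids:", ", ".join(f"{a} ({n})" for a, n in aa.head(5).items()))
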