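"""Architecture of the two packaged *Thrips* mitogenome annotations.

Loads the published coordinate tables shipped with the package and
recomputes the descriptive statistics a mitogenome paper reports:
spacer/overlap totals, the control-region candidate, strand usage and
the tRNA inventory.  No sequence is needed — coordinates suffice.
"""

from mitochar import (
    architecture_summary,
    compute_adjacencies,
    control_region_candidate,
    fixture_annotation,
    strand_distribution,
    trna_inventory,
)

for species in ("tabaci", "parvispinus"):
    ann = fixture_annotation(species)
    adj = compute_adjacencies(ann)
    s = architecture_summary(adj)
    (cr,) = control_region_candidate(adj)
    plus, minus = strand_distribution(ann)
    inv = trna_inventory(ann)
    print(f"Thrips {species}: {ann.genome_length} bp, {len(ann)} features "
          f"({plus} on +, {minus} on -)")
    print(f"  intergenic: {s.total_spacer_bp} bp at {s.n_spacers} sites; "
          f"overlaps: {s.n_overlaps} (largest {-s.max_overlap.gap} bp, "
          f"{s.max_overlap.upstream_gene}/{s.max_overlap.downstream_gene})")
    print(f"  control-region candidate: {cr.gap} bp between "
          f"{cr.upstream_gene} and {cr.downstream_gene}")
    print(f"  missing tRNAs: {', '.join(sorted(inv.missing))}")
    print()

# The largest positive gap is the putative control region; missing tRNAs
# are relative to the canonical 22 of animal mitogenomes.
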