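"""Delineate the tag-anchored LD block and split it into the two clades.

Builds a synthetic locus, anchors an r2 >= 0.8 block on a clade-defining
tag variant, assigns every haplotype to one of the two deep clades by
rooting a neighbor-joining tree on the outgroup, and reports bootstrap
support and per-clade core haplotypes.
"""

import numpy as np

from haplodistill import (
    SimParams,
    assign_clades,
    bootstrap_bipartition,
    core_haplotypes,
    ld_block_from_tag,
    simulate_two_clade,
)

r = simulate_two_clade(SimParams(seed=1, L=70_000))
m = r.matrix

# tag = the clade-defining variant nearest the locus centre
stem = set(r.truth.stem_positions)
centre = int(np.median(m.positions))
tag = min((v for v in m.variants if v.pos in stem), key=lambda v: abs(v.pos - centre))

block = ld_block_from_tag(m, tag.vid, threshold=0.8)
print(f"tag {tag.vid}: block of {len(block.member_vids)} variants, "
      f"span {block.span_start}-{block.span_end} ({block.span_bp/1000:.1f} kb)")

idx = [i for i, v in enumerate(m.variants) if v.vid in set(block.member_vids)]
block_m = m.subset_rows(idx)
asn = assign_clades(block_m, method="nj_root_split",
                    outgroup_sequence=r.outgroup[idx])
sizes = asn.clade_sizes()
truth = r.truth.clade_labels
agree = np.mean([asn.assignment[h] == truth[h] for h in asn.assignment])
print(f"clades: {sizes[1]} vs {sizes[2]} haplotypes; "
      f"agreement with generator truth {100*agree:.1f}%")

bs = bootstrap_bipartition(block_m, asn, outgroup_sequence=r.outgroup[idx],
                           n_reps=100, seed=1)
print(f"bootstrap support for the two-clade split: {bs.support}/{bs.n_reps}")

core = core_haplotypes(block_m, asn)
fixed = (core["clade1_fraction"] == 1.0) & (core["clade2_fraction"] == 1.0)
print(f"core haplotype table: {len(core)} sites, {int(fixed.sum())} fixed "
      f"within both clades")
# A clean two-clade locus shows 100/100 bootstrap support and a core table
# whose consensus fractions are all 1.0 at the clade-defining sites.
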