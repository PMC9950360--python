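"""Simulate a balanced two-clade locus and inspect its ground truth.

Generates 135 + 65 phased haplotypes over a 70 kb locus whose two clades
split 61,600 generations (~1.54 My) ago, with an archaic lineage on the
clade-2 stem and a 6 My outgroup, then prints what the generator knows.
"""

from haplodistill import SimParams, simulate_two_clade

result = simulate_two_clade(SimParams(seed=1, L=70_000))
m = result.matrix
truth = result.truth

labels = list(truth.clade_labels.values())
print(f"haplotypes: {m.n_haplotypes} ({labels.count(1)} clade-1, {labels.count(2)} clade-2)")
print(f"variant sites: {m.n_variants}")
print(f"clade-defining (fixed inter-clade) sites: {len(truth.stem_positions)}")
print(f"  of which younger than the archaic split: {len(truth.post_archaic_stem_positions)}")
print(f"dense target segment: {truth.target_segment[0]}-{truth.target_segment[1]}")
print(f"within-clade TMRCAs: {truth.tmrca1_gens:.0f} and {truth.tmrca2_gens:.0f} generations")
print(f"archaic het calls: {sum(result.archaic.is_het(p) for p in result.archaic.calls)}")

# The clade-defining sites are the backbone of the analysis: they are what
# the LD block, the core haplotypes and the selection scan should recover.
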