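"""Neighbor-joining tree with bootstrap support.

Builds the NJ tree for two well-separated populations and attaches
support values from 100 column-resampling replicates.
"""

from moabarcode import distances, phylo, synthetic_data as sd

cfg = sd.symmetric_population_config(
    intra=0.003, inter=0.02, n=6, populations=("FarNorth", "FarSouth"), seed=0
)
aln, pops = sd.simulate_alignment(cfg)
tree = phylo.nj_tree(distances.distance_matrix(aln))
tree.support = phylo.bootstrap_support(aln, replicates=100, seed=1)

newick = phylo.to_newick(tree)
print(newick)

side = frozenset(s for s, p in pops.items() if p == "FarSouth")
key = phylo._canonical_side(side, frozenset(aln.sample_ids))
print(f"support for the population split: {tree.support[key]:.0f}%")
# A 2% divergence between populations is ample signal: the split separating
# the two simulated populations is recovered in essentially every replicate.
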