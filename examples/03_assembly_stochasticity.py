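"""Phylogenetic normalised stochasticity ratio (pNST) per treatment x date.

betaMNTD measures the phylogenetic turnover between two plots; comparing it
with a tip-shuffle null yields betaNTI and a stochasticity fraction: ~100%
means assembly indistinguishable from random with respect to the phylogeny,
~0% strong deterministic filtering.
"""

from biofilmstab.stochasticity import nst_by_group, patristic_matrix
from biofilmstab.synthesis import generate_world

world = generate_world(seed=7)
dist, labels = patristic_matrix(world["tree"])
table, results = nst_by_group(
    world["abundances"], dist, labels, n_rand=200, seed=7
)
print(table.round(2).to_string(index=False))
# Each group mean averages n(n-1)/2 pairwise NST values among its plots.
# betaNTI beyond +/-2 flags significant deterministic divergence/convergence.
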