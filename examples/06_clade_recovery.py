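"""Distance-tree clade recovery on synthetic data.

Fits GTR+Gamma+I to the P12RNA supermatrix, computes pairwise ML
distances, builds a neighbor-joining tree, and checks that the planted
4-taxon clade is recovered as monophyletic after outgroup rooting.
"""

from mitokit import (
    SimulationConfig,
    concatenate,
    estimate_model,
    gtr_gi_distance_matrix,
    is_monophyletic,
    nj_tree,
    simulate_dataset,
)
from mitokit.dataset import trim_to_frame

dataset = simulate_dataset(SimulationConfig(n_taxa=10, seed=4, length_scale=0.3))
sm = concatenate(trim_to_frame(dataset.gene_alignments), "P12RNA")

model = estimate_model(sm.sequences, max_pairs=20, maxiter=80, seed=4)
print(
    f"fitted model: alpha={model.alpha:.2f}, p_inv={model.p_inv:.2f}, "
    f"AG={model.exchangeabilities[1]:.1f}, CT={model.exchangeabilities[4]:.1f}"
)

distances = gtr_gi_distance_matrix(sm.sequences, model)
tree = nj_tree(distances)
mono = is_monophyletic(tree, dataset.clade_taxa, outgroup="outgroup")
print(f"planted clade {sorted(dataset.clade_taxa)} monophyletic: {mono}")
print(tree.as_string(schema="newick")[:120] + "...")
# Transition-heavy exchangeabilities (AG, CT) and a small gamma shape are
# typical of mitochondrial DNA; monophyly of the planted clade shows the
# distance pipeline preserves the tree signal end to end.
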