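"""Simulate one chemoreceptor family along the nine-species tree.

A single ancestral gene enters at the root and duplicates, dies, or
pseudogenizes along every branch; the output is a gene tree embedded
in the species tree together with the full event truth.
"""

from chemevol import simulate_gene_family, write_newick
from chemevol.simulate import DEFAULT_SPECIES_TREE

truth = simulate_gene_family(
    DEFAULT_SPECIES_TREE,
    dup_rate=0.4, loss_rate=0.15, pseudo_rate=0.15, seed=42)

print("gene tree:", write_newick(truth.gene_tree))
print("duplication events :", truth.n_duplications)
print("loss events        :", truth.n_losses)
print("pseudogene copies  :", sorted(truth.pseudogene_leaves))
print("copies per species :", truth.copies_per_species())
print()
print("Each leaf is one extant gene copy (<species>_<copy#>); the event")
print("counts are the ground truth that reconciliation should recover.")
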