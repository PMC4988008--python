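"""Reconcile a gene tree with the species tree and date the events.

LCA reconciliation labels every internal gene-tree node as duplication
or speciation and counts losses per edge (duplication cost 1.5, loss
cost 1.0); weakly supported edges (bootstrap < 0.9) may be rearranged
by NNI when that lowers the cost.  Copy-number changes per species
branch come from a minimum-change (Sankoff) reconstruction.
"""

from chemevol import infer_gains_losses, rearrange_weak_edges, reconcile
from chemevol.trees import parse_newick

species = parse_newick("((Dsuz:1,Dbia:1):1,Dtak:2);")

# a duplicated family: Dsuz kept three copies, Dbia one, Dtak two
gene = parse_newick(
    "(((Dsuz_1:1,Dsuz_2:1)0.99:1,(Dsuz_3:1,Dbia_1:1)0.95:1)0.98:1,"
    "(Dtak_1:1,Dtak_2:1)0.97:2);")
rec = reconcile(gene, species)
print(f"duplications={rec.n_duplications} losses={rec.n_losses} "
      f"cost={rec.cost}")
print("annotated:", rec.annotated_newick())

# a weakly supported edge that contradicts the species tree
discordant = parse_newick("((Dsuz_1:1,Dtak_1:1)0.40:1,Dbia_1:2);")
tree, rec2 = rearrange_weak_edges(discordant, species)
print(f"\nafter NNI on weak edges: cost {rec2.cost} "
      f"(was {reconcile(discordant, species).cost})")

ancestral, deltas = infer_gains_losses({"Dsuz": 3, "Dbia": 1, "Dtak": 2},
                                       species)
print("\nancestral copy numbers:",
      {(n.label or 'ancestor'): c for n, c in ancestral.items()})
print("per-branch gains/losses:",
      {(n.label or 'ancestor'): d for n, d in deltas.items()})
print("\nPositive deltas are lineage-specific expansions; negative are")
print("contractions - the birth-and-death picture per species branch.")
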