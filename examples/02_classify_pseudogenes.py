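"""Inject disruptive lesions into an intact CDS and classify the result.

The pseudogene rule is conjunctive: a lesion must remove at least 20 %
of the reference protein AND at least one predicted transmembrane
segment.  A truncation without any lesion is 'partial' (assembly
artifact), not a pseudogene.
"""

import numpy as np

from chemevol import classify_gene_model, predict_tm_segments, translate_cds
from chemevol.simulate import inject_lesion

rng = np.random.default_rng(1)

# a synthetic 7-TM receptor: 21-aa hydrophobic stretches with long
# hydrophilic linkers, the architecture of an insect Or/Gr
codons = ["ATG"]
for _ in range(7):
    codons += [str(rng.choice(("GAT", "GAA", "AAT", "CAA", "AAA")))
               for _ in range(25)]
    codons += [str(rng.choice(("CTG", "GTG", "CTT", "GTC")))
               for _ in range(21)]
codons += ["GAA"] * 10 + ["TAA"]
cds = "".join(codons)
reference = translate_cds(cds).protein
print(f"reference: {len(reference)} aa, "
      f"{len(predict_tm_segments(reference))} predicted TM segments")

for kind, position in [("premature_stop", 120),
                       ("premature_stop", 320),
                       ("frameshift", 100)]:
    lesioned, truth = inject_lesion(cds, kind, position, seed=7)
    result = classify_gene_model(lesioned, reference)
    print(f"{kind:>15} @ codon {position:3d}: lost "
          f"{100 * truth.fraction_lost:5.1f} % of the protein, "
          f"{result.tm_lost} TM segments -> {result.status}")

print()
print("Only lesions crossing both thresholds (>=20 % lost, >=1 TM lost)")
print("are called pseudogenes, mirroring how annotators separate dead")
print("receptor copies from benign polymorphism.")
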