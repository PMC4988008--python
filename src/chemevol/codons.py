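"""Shared genetic-code machinery for the codon-level modules.

The 61 sense codons of the standard nuclear code, in lexicographic order,
are the state space everywhere (simulator, NG86 counting, codon-model
likelihoods).  Stop codons are excluded from the state space by
construction, which is what makes "no stop generated internally" a
structural guarantee rather than a runtime check.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))

#: the 61 sense codons, lexicographic
SENSE_CODONS = tuple(
    sorted(c for c in standard_dna_table.forward_table)
)

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: codon -> single-letter amino acid (sense codons only)
CODON_TO_AA = dict(standard_dna_table.forward_table)

N_CODONS = len(SENSE_CODONS)  # 61

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def codon_diffs(c1: str, c2: str) -> list[int]:
    """Positions (0-based) at which two codons differ."""
    return [i for i in range(3) if c1[i] != c2[i]]


def is_synonymous(c1: str, c2: str) -> bool:
    """True if both are sense codons encoding the same amino acid."""
    return CODON_TO_AA[c1] == CODON_TO_AA[c2]


def neighbors(codon: str) -> list[str]:
    """All nine single-nucleotide mutants of a codon (stops included)."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1:])
    return out
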