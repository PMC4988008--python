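"""MG94xHKY codon substitution model over the 61 sense codons.

Rates are Muse-Gaut style: a single-nucleotide change i->j gets
pi_j * kappa^[transition] * omega^[nonsynonymous]; multi-nucleotide
changes are forbidden.  The generator is normalized to one expected
substitution per codon per unit time, so branch lengths are expected
substitutions per codon site under the branch's own omega.

The generator is reversible for any target frequencies, which lets the
transition matrices be computed through a symmetrized eigendecomposition
(sqrt-pi similarity transform) - stable and cheap enough to re-do at
every omega proposal during optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .codons import (
    CODON_TO_AA,
    N_CODONS,
    NUCLEOTIDES,
    SENSE_CODONS,
    is_transition,
)

# Static single-change structure: for each ordered codon pair differing at
# exactly one position, whether the change is a transition and whether it
# is synonymous.  Computed once at import.
_TS_MASK = np.zeros((N_CODONS, N_CODONS), dtype=bool)
_SYN_MASK = np.zeros((N_CODONS, N_CODONS), dtype=bool)
_SINGLE_MASK = np.zeros((N_CODONS, N_CODONS), dtype=bool)
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [p for p in range(3) if _ci[p] != _cj[p]]
        if len(diffs) != 1:
            continue
        _SINGLE_MASK[_i, _j] = True
        p = diffs[0]
        _TS_MASK[_i, _j] = is_transition(_ci[p], _cj[p])
        _SYN_MASK[_i, _j] = CODON_TO_AA[_ci] == CODON_TO_AA[_cj]


def validate_codon_freqs(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"need {N_CODONS} codon frequencies")
    if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("codon frequencies must be non-negative and sum to 1")
    return pi / pi.sum()


@dataclass
class CodonModel:
    """A reversible MG94xHKY generator with its eigendecomposition."""

    kappa: float
    omega: float
    pi: np.ndarray
    Q: np.ndarray = field(repr=False, default=None)
    _eigen: tuple = field(repr=False, default=None)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the cached symmetric eigendecomposition."""
        vals, right, left = self._eigen
        P = (right * np.exp(vals * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        return P


def mg94_flux(kappa: float, omega: float, pi) -> float:
    """Expected rate of the *unnormalized* MG94 generator.

    Used to put several omega classes on a shared clock: dividing each
    class generator by the background class's flux makes branch
    lengths mean expected substitutions per codon under the background
    process, with elevated-omega sites evolving proportionally faster.
    """
    pi = validate_codon_freqs(pi)
    rate = np.where(_TS_MASK, kappa, 1.0) * np.where(_SYN_MASK, 1.0, omega)
    Q = np.where(_SINGLE_MASK, rate * pi[None, :], 0.0)
    return float((pi[:, None] * Q).sum())


def build_mg94(kappa: float, omega: float, pi,
               rate_scale: float | None = None) -> CodonModel:
    """MG94xHKY generator, normalized to mean rate one.

    With ``rate_scale`` the generator is divided by that externally
    supplied flux instead of its own (shared-clock normalization
    across omega classes); by default it is self-normalized.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    pi = validate_codon_freqs(pi)
    rate = np.where(_TS_MASK, kappa, 1.0) * np.where(_SYN_MASK, 1.0, omega)
    Q = np.where(_SINGLE_MASK, rate * pi[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum() if rate_scale is None else float(rate_scale)
    if scale <= 0:
        raise ValueError("degenerate model: zero total flux")
    Q /= scale
    # symmetrized eigendecomposition; exact because pi_i q_ij = pi_j q_ji
    half = np.sqrt(np.maximum(pi, 1e-300))
    sym = (half[:, None] * Q) / half[None, :]
    vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
    right = vecs / half[:, None]
    left = vecs.T * half[None, :]
    return CodonModel(kappa=kappa, omega=omega, pi=pi,
                      Q=Q, _eigen=(vals, right, left))


def f3x4_frequencies(alignment: dict[str, str]) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Stop codons are removed and the remaining 61 products renormalized.
    A position observing a zero-frequency nucleotide gets a pseudocount
    (with a warning) so downstream generators stay irreducible.
    """
    if not alignment:
        raise ValueError("empty alignment")
    counts = np.zeros((3, 4))
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq in alignment.values():
        seq = seq.upper().replace("-", "")
        if len(seq) % 3:
            raise ValueError("sequence length not a multiple of 3")
        for i, ch in enumerate(seq):
            if ch in nt_index:
                counts[i % 3, nt_index[ch]] += 1
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("alignment has no usable codons")
    if np.any(counts == 0):
        warnings.warn("zero nucleotide count at some codon position; "
                      "applying a pseudocount of 1")
        counts += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]]
         * freqs[2, nt_index[c[2]]] for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)
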