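"""Pairwise divergence: %ID, NG86 dN/dS, and Wilcoxon comparisons.

dN/dS here is the counting estimator of Nei & Gojobori (1986):
synonymous/nonsynonymous *site* counts come from the fraction of
single-nucleotide neighbours of each codon that are synonymous
(mutations to stops excluded from the denominator); *difference*
counts for codon pairs differing at several positions are averaged
uniformly over all mutational pathways that avoid stop codons; both
proportions get the Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p).

The Wilcoxon machinery is exact (full null enumeration via dynamic
programming, midranks for ties, zeros dropped) for the small samples a
per-family comparison produces, switching to the usual normal
approximation with continuity and tie corrections for larger n.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import _protein_aligner, translate_cds
from .codons import CODON_TO_AA, STOP_CODONS, codon_diffs

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

class ProteinAlignment(NamedTuple):
    a: str  # aligned, with '-'
    b: str
    score: float


def global_protein_align(a: str, b: str) -> ProteinAlignment:
    """Optimal global alignment (BLOSUM62, affine open 10 / extend 1)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    bad = (set(a.upper()) | set(b.upper())) - _AA_LETTERS
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    aligner = _protein_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    return ProteinAlignment(a=str(aln[0]), b=str(aln[1]), score=aln.score)


def percent_identity(alignment: ProteinAlignment,
                     count_gap_columns: bool = True) -> float:
    """100 x identical columns / alignment length.

    With ``count_gap_columns`` (default) gap columns stay in the
    denominator; the alternative convention divides by ungapped
    columns only.
    """
    a, b = alignment.a, alignment.b
    if not a:
        raise ValueError("zero-length alignment")
    ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    denom = len(a) if count_gap_columns else sum(
        1 for x, y in zip(a, b) if x != "-" and y != "-")
    if denom == 0:
        raise ValueError("no comparable columns")
    return 100.0 * ident / denom


def thread_codon_alignment(
    alignment: ProteinAlignment, cds_a: str, cds_b: str
) -> tuple[str, str]:
    """Back-translate a protein alignment onto its coding sequences.

    Each aligned residue becomes its source codon; gaps become '---'.
    The CDSs may carry a trailing stop.  A residue that does not match
    its codon's translation is rejected with its position.
    """
    out = []
    for seq, cds in ((alignment.a, cds_a), (alignment.b, cds_b)):
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError("CDS length not a multiple of 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons.pop()
        res = []
        k = 0
        for col, aa in enumerate(seq):
            if aa == "-":
                res.append("---")
                continue
            if k >= len(codons):
                raise ValueError(f"CDS shorter than protein at column {col}")
            if CODON_TO_AA.get(codons[k]) != aa:
                raise ValueError(
                    f"translation mismatch at column {col}: codon "
                    f"{codons[k]} vs residue {aa}")
            res.append(codons[k])
            k += 1
        if k != len(codons):
            raise ValueError("CDS longer than aligned protein")
        out.append("".join(res))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Per position, the synonymous fraction among single-nucleotide
    neighbours, with mutations to stop codons excluded from the
    denominator; the three positions sum to exactly 3 sites.
    """
    codon = codon.upper()
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        variants = [codon[:pos] + nt + codon[pos + 1:]
                    for nt in "ACGT" if nt != codon[pos]]
        sense = [v for v in variants if v not in STOP_CODONS]
        if sense:
            s += sum(CODON_TO_AA[v] == CODON_TO_AA[codon] for v in sense) / len(sense)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    Averages the per-step classification uniformly over all orderings
    of the differing positions whose intermediates are sense codons;
    orderings passing through a stop are discarded (all-blocked pairs
    fall back to the unrestricted average, which cannot occur between
    sense codons in practice).
    """
    diffs = codon_diffs(c1, c2)
    if not diffs:
        return 0.0, 0.0
    valid = []
    blocked = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                nd += 1  # to/from a stop counts as nonsynonymous
                cur = nxt
                continue
            if cur not in STOP_CODONS and CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    pool = valid if valid else blocked
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


@dataclass
class PairwiseSubstitution:
    """NG86 quantities for one aligned coding-sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    ratio: float
    undefined: bool
    n_codons: int

    @staticmethod
    def _jc(p: float) -> float:
        if p >= 0.75:
            return math.nan
        return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair(codon_a: str, codon_b: str) -> PairwiseSubstitution:
    """NG86 estimates for a codon-aligned pair of sequences.

    Columns containing gaps, ambiguity or stop codons are skipped.
    ``ratio`` is NaN with ``undefined=True`` when dS is zero or either
    proportion is Jukes-Cantor-saturated (p >= 3/4).
    """
    if len(codon_a) != len(codon_b) or len(codon_a) % 3:
        raise ValueError("sequences must be codon-aligned and equal length")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(codon_a), 3):
        ca, cb = codon_a[i:i + 3].upper(), codon_b[i:i + 3].upper()
        if (set(ca + cb) - set("ACGT")) or ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_codons += 1
        sa, na = ng86_codon_sites(ca)
        sb, nb = ng86_codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = ng86_pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = PairwiseSubstitution._jc(pS)
    dN = PairwiseSubstitution._jc(pN)
    undefined = math.isnan(dS) or math.isnan(dN) or dS == 0.0
    ratio = math.nan if undefined else dN / dS
    return PairwiseSubstitution(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                                dS=dS, dN=dN, ratio=ratio,
                                undefined=undefined, n_codons=n_codons)


# ---------------------------------------------------------------------------
# Wilcoxon tests (exact with midranks)
# ---------------------------------------------------------------------------

def _doubled_ranks(values: np.ndarray) -> np.ndarray:
    """Midranks doubled to integers (exact DP needs integer weights)."""
    r2 = 2.0 * stats.rankdata(values)
    out = np.rint(r2).astype(int)
    assert np.allclose(out, r2)
    return out


def wilcoxon_signed_rank(
    x, y=None, exact_limit: int = 25
) -> tuple[float, float]:
    """Two-sided signed-rank test; exact null for n <= ``exact_limit``.

    ``x`` is either the vector of paired differences or the first
    sample (with ``y`` the second).  Zero differences are dropped;
    tied absolute differences get midranks.  Returns
    (W = min(W+, W-), two-sided p).  The exact p is
    2 * min(P(W+ <= w), P(W+ >= w)), capped at 1 - identical to full
    enumeration of the 2^n sign vectors.
    """
    d = np.asarray(x, float)
    if y is not None:
        d = d - np.asarray(y, float)
    if d.size < 1:
        raise ValueError("need at least one pair")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; p = 1")
        return 0.0, 1.0
    r2 = _doubled_ranks(np.abs(d))
    w_plus2 = int(r2[d > 0].sum())
    total2 = int(r2.sum())
    W = min(w_plus2, total2 - w_plus2) / 2.0
    n = d.size
    if n <= exact_limit:
        # DP over doubled rank sums of sign vectors
        counts = np.zeros(total2 + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] = counts[r:] + counts[:-r or None]
        counts /= counts.sum()
        p_lo = counts[: w_plus2 + 1].sum()
        p_hi = counts[w_plus2:].sum()
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    else:
        mean = total2 / 2.0
        _, tie_counts = np.unique(r2, return_counts=True)
        var = (r2.astype(float) ** 2).sum() / 4.0
        z = (abs(w_plus2 - mean) - 1.0) / math.sqrt(var)  # cc of 0.5 doubled
        p = min(1.0, 2.0 * stats.norm.sf(z))
    return W, p


def wilcoxon_rank_sum(a, b, exact_limit: int = 20) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney) test; exact for m+n <= limit.

    Returns (U = min(U_a, U_b), two-sided p); ties get midranks, and
    the exact null enumerates all C(m+n, m) group assignments via
    dynamic programming.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = a.size, b.size
    combined = np.concatenate([a, b])
    r2 = _doubled_ranks(combined)
    ra2 = int(r2[:m].sum())
    u_a = (ra2 - m * (m + 1)) / 2.0
    u_b = m * n - u_a
    U = min(u_a, u_b)
    if m + n <= exact_limit:
        # dp[k][s] = number of size-k subsets with doubled rank sum s
        total2 = int(r2.sum())
        dp = np.zeros((m + 1, total2 + 1))
        dp[0, 0] = 1.0
        for r in r2:
            for k in range(m, 0, -1):
                dp[k, r:] += dp[k - 1, :-r or None]
        dist = dp[m]
        dist /= dist.sum()
        p_lo = dist[: ra2 + 1].sum()
        p_hi = dist[ra2:].sum()
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    else:
        mean = m * n / 2.0
        N = m + n
        ranks = r2 / 2.0
        tie_term = 0.0
        for _, c in zip(*np.unique(ranks, return_counts=True)):
            tie_term += c ** 3 - c
        var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        z = (abs(u_a - mean) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(z))
    return U, p


# ---------------------------------------------------------------------------
# batch records and summaries
# ---------------------------------------------------------------------------

@dataclass
class DivergenceRecord:
    """Divergence of one gene against its outgroup homolog."""

    gene: str
    homolog: str
    species: str
    family: str
    pct_id: float
    sub: PairwiseSubstitution


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "homolog": r.homolog, "species": r.species,
        "family": r.family, "pct_id": r.pct_id, "S": r.sub.S, "N": r.sub.N,
        "Sd": r.sub.Sd, "Nd": r.sub.Nd, "dS": r.sub.dS, "dN": r.sub.dN,
        "dnds": r.sub.ratio, "undefined": r.sub.undefined,
    } for r in records])


def diverge_pair(
    gene: str, homolog: str, species: str, family: str,
    cds: str, outgroup_cds: str,
) -> DivergenceRecord:
    """%ID and NG86 divergence of one gene against an outgroup CDS."""
    prot = translate_cds(cds).protein
    prot_out = translate_cds(outgroup_cds).protein
    aln = global_protein_align(prot, prot_out)
    codon_a, codon_b = thread_codon_alignment(aln, cds, outgroup_cds)
    return DivergenceRecord(
        gene=gene, homolog=homolog, species=species, family=family,
        pct_id=percent_identity(aln), sub=ng86_pair(codon_a, codon_b))


def divergence_summary(records) -> dict[str, pd.DataFrame]:
    """Family/species means plus paired and unpaired Wilcoxon tests.

    Returns {'means': per species x family mean dN/dS/ratio,
    'paired': between-species signed-rank tests on shared homologs,
    'unpaired': Or-vs-Gr rank-sum tests per species}.  Undefined
    ratios are excluded from ratio means and tests.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    means = (df.groupby(["species", "family"])[["dN", "dS", "dnds"]]
             .mean().round(4).reset_index())
    paired_rows = []
    species = sorted(df["species"].unique())
    for fam in sorted(df["family"].unique()):
        sub = df[df["family"] == fam]
        for sp1, sp2 in itertools.combinations(species, 2):
            merged = pd.merge(sub[sub.species == sp1], sub[sub.species == sp2],
                              on="homolog", suffixes=("_1", "_2"))
            if merged.empty:
                continue
            for param in ("dN", "dS", "dnds"):
                pair = merged[[f"{param}_1", f"{param}_2"]].dropna()
                if pair.empty:
                    continue
                _, p = wilcoxon_signed_rank(pair[f"{param}_1"].to_numpy(),
                                            pair[f"{param}_2"].to_numpy())
                paired_rows.append({"family": fam, "species_1": sp1,
                                    "species_2": sp2, "parameter": param,
                                    "n": len(pair), "p_value": p})
    unpaired_rows = []
    for sp in species:
        sub = df[df["species"] == sp]
        ors = sub[sub.family == "Or"]
        grs = sub[sub.family == "Gr"]
        if ors.empty or grs.empty:
            continue
        for param in ("dN", "dS", "dnds"):
            x = ors[param].dropna().to_numpy()
            y = grs[param].dropna().to_numpy()
            if not len(x) or not len(y):
                continue
            _, p = wilcoxon_rank_sum(x, y)
            unpaired_rows.append({
                "species": sp, "parameter": param,
                "mean_Or": round(float(x.mean()), 4),
                "mean_Gr": round(float(y.mean()), 4), "p_value": p})
    return {"means": means,
            "paired": pd.DataFrame(paired_rows),
            "unpaired": pd.DataFrame(unpaired_rows)}
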