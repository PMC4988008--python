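"""Gene-model classification and repertoire bookkeeping.

The central rule: a chemoreceptor gene model is a *pseudogene* when a
disruptive lesion (mutated start codon, premature stop, or frameshift)
removes at least 20 % of the reference protein AND at least one
predicted transmembrane segment, judged against an intact homolog.
Models shortened by assembly truncation with no lesion are *partial*
and sit outside both the locus and functional counts.  Everything else
is intact.

Transmembrane segments are called with a deterministic Kyte-Doolittle
hydropathy scan (window 19, mean threshold 1.6, minimum segment 15 aa,
merge gap < 5 aa) - a transparent stand-in for neural topology
predictors, chosen so every test fixture is decidable by hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .codons import CODON_TO_AA, STOP_CODONS

PSEUDOGENE_FRACTION_THRESHOLD = 0.20

#: epithet -> 4-letter community tag for species handled here
SPECIES_TAGS = {
    "ananassae": "Dana",
    "biarmipes": "Dbia",
    "elegans": "Dele",
    "erecta": "Dere",
    "eugracilis": "Deug",
    "ficusphila": "Dfic",
    "kikkawai": "Dkik",
    "melanogaster": "Dmel",
    "rhopaloa": "Drho",
    "sechellia": "Dsec",
    "simulans": "Dsim",
    "suzukii": "Dsuz",
    "takahashii": "Dtak",
    "yakuba": "Dyak",
}


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

class Translation(NamedTuple):
    protein: str
    internal_stop_at: int | None  # codon index of the first internal stop


def translate_cds(cds: str) -> Translation:
    """Translate a CDS under the standard code.

    The trailing stop is dropped; an internal stop truncates the
    protein and is flagged with its codon index.  Non-ACGT characters
    or a length not divisible by three are rejected.
    """
    cds = cds.upper()
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    protein = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            if i == len(cds) - 3:
                break  # trailing stop
            return Translation("".join(protein), i // 3)
        protein.append(CODON_TO_AA[codon])
    return Translation("".join(protein), None)


def translate_to_first_stop(dna: str, rescue_start: bool = True) -> str:
    """Translate to the first stop, tolerating lesioned input.

    A mutated start codon is rescued at the next in-frame ATG (the
    least destructive reading); trailing partial codons from
    frameshifts are ignored.  Returns the functional protein remnant.
    """
    dna = dna.upper()
    start = 0
    if rescue_start and dna[:3] != "ATG":
        nxt = None
        for i in range(3, len(dna) - 2, 3):
            if dna[i:i + 3] == "ATG":
                nxt = i
                break
        if nxt is None:
            return ""
        start = nxt
    protein = []
    for i in range(start, len(dna) - 2, 3):
        codon = dna[i:i + 3]
        if codon in STOP_CODONS:
            break
        protein.append(CODON_TO_AA.get(codon, "X"))
    return "".join(protein)


# ---------------------------------------------------------------------------
# transmembrane segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TMSegment:
    start: int  # 1-based inclusive
    end: int
    mean_hydropathy: float


def predict_tm_segments(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_length: int = 15,
    merge_gap: int = 5,
) -> list[TMSegment]:
    """Kyte-Doolittle sliding-window transmembrane segment prediction.

    A residue is membrane-flagged when the mean hydropathy of the
    window centred on it reaches ``threshold``; runs of flagged
    centres are extended to the window extent, merged when separated
    by fewer than ``merge_gap`` residues, and dropped when shorter
    than ``min_length``.
    """
    n = len(protein)
    if n < window:
        warnings.warn("protein shorter than the hydropathy window; "
                      "no TM prediction possible")
        return []
    scores = [KYTE_DOOLITTLE.get(a, 0.0) for a in protein.upper()]
    half = window // 2
    flagged = []
    running = sum(scores[:window])
    for center in range(half, n - half):
        if center > half:
            running += scores[center + half] - scores[center - half - 1]
        if running / window >= threshold:
            flagged.append(center)
    # runs of flagged centres -> candidate segments (window extent)
    raw = []
    for c in flagged:
        if raw and c == raw[-1][1] + 1:
            raw[-1][1] = c
        else:
            raw.append([c, c])
    cand = [[max(0, a - half), min(n - 1, b + half)] for a, b in raw]
    merged: list[list[int]] = []
    for seg in cand:
        if merged and seg[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], seg[1])
        else:
            merged.append(seg)
    out = []
    for a, b in merged:
        if b - a + 1 >= min_length:
            mean_h = sum(scores[a:b + 1]) / (b - a + 1)
            out.append(TMSegment(start=a + 1, end=b + 1,
                                 mean_hydropathy=round(mean_h, 4)))
    return out


# ---------------------------------------------------------------------------
# gene models and classification
# ---------------------------------------------------------------------------

@dataclass
class Lesion:
    kind: str  # start_loss | premature_stop | frameshift
    position: int  # codon index (0-based) where the lesion manifests
    fraction_lost: float
    tm_lost: int


@dataclass
class GeneModel:
    """One annotated chemoreceptor locus."""

    id: str
    species: str
    cds: str
    scaffold: str = ""
    strand: str = "+"
    exons: tuple = ()
    protein: str = ""
    status: str = "intact"  # intact | pseudogene | partial
    lesions: list = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.exons:
            total = sum(e - s + 1 for s, e in self.exons)
            if total != len(self.cds):
                raise ValueError("exon lengths do not sum to CDS length")

    @property
    def family(self) -> str:
        rest = self.id[4:] if self.id[:4].istitle() and len(self.id) > 4 else self.id
        for fam in ("Orco", "Or", "Gr"):
            if rest.startswith(fam) or fam in self.id:
                return "Or" if fam in ("Or", "Orco") else "Gr"
        raise ValueError(f"cannot infer family from id {self.id!r}")


@dataclass
class Classification:
    status: str
    lesions: list
    functional_protein: str
    fraction_lost: float
    tm_lost: int


def classify_gene_model(
    candidate: GeneModel | str,
    reference_protein: str,
    conjunctive: bool = True,
    fraction_threshold: float = PSEUDOGENE_FRACTION_THRESHOLD,
    tm_threshold: int = 1,
) -> Classification:
    """Classify a gene model as intact / pseudogene / partial.

    ``candidate`` supplies a CDS; ``reference_protein`` is the intact
    homolog the loss is measured against.  Under the default
    conjunctive rule the model is a pseudogene only when a lesion
    removes >= ``fraction_threshold`` of the reference protein AND
    >= ``tm_threshold`` predicted TM segments; with
    ``conjunctive=False`` either condition suffices.
    """
    if not reference_protein:
        raise ValueError("reference protein must be non-empty")
    cds = (candidate.cds if isinstance(candidate, GeneModel) else candidate).upper()
    if not cds:
        raise ValueError("candidate has no CDS")

    lesions: list[Lesion] = []
    frameshift = bool(len(cds) % 3)
    start_lost = cds[:3] != "ATG"
    remnant = translate_to_first_stop(cds, rescue_start=True)
    # premature stop: an in-frame stop before the final codon
    stop_idx = None
    start = 0
    if start_lost:
        for i in range(3, len(cds) - 2, 3):
            if cds[i:i + 3] == "ATG":
                start = i
                break
        else:
            start = None
    if start is not None:
        for i in range(start, len(cds) - 5, 3):
            if cds[i:i + 3] in STOP_CODONS:
                stop_idx = i // 3
                break

    ref_len = len(reference_protein)
    fraction_lost = max(0.0, 1.0 - len(remnant) / ref_len)
    ref_tm = len(predict_tm_segments(reference_protein))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cand_tm = len(predict_tm_segments(remnant)) if remnant else 0
    tm_lost = max(0, ref_tm - cand_tm)

    if start_lost:
        lesions.append(Lesion("start_loss", 0, fraction_lost, tm_lost))
    if stop_idx is not None and not frameshift:
        lesions.append(Lesion("premature_stop", stop_idx, fraction_lost, tm_lost))
    if frameshift:
        lesions.append(Lesion("frameshift", len(remnant), fraction_lost, tm_lost))

    if lesions:
        broken = (fraction_lost >= fraction_threshold and tm_lost >= tm_threshold
                  ) if conjunctive else (
                  fraction_lost >= fraction_threshold or tm_lost >= tm_threshold)
        status = "pseudogene" if broken else "intact"
    elif fraction_lost >= fraction_threshold:
        status = "partial"  # assembly truncation, no lesion
    else:
        status = "intact"
    if isinstance(candidate, GeneModel):
        candidate.status = status
        candidate.lesions = lesions
    return Classification(status=status, lesions=lesions,
                          functional_protein=remnant,
                          fraction_lost=round(fraction_lost, 6),
                          tm_lost=tm_lost)


# ---------------------------------------------------------------------------
# repertoire bookkeeping
# ---------------------------------------------------------------------------

def summarize_repertoire(
    models: Iterable[GeneModel],
    splice_table: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per species x family repertoire counts (Table-1-style arithmetic).

    ``splice_table`` maps gene id -> number of encoded isoforms (> 1
    marks an alternatively spliced gene).  Partial models are excluded
    from both the locus and functional counts; the identities
    functional = loci - pseudogenes and
    proteins = functional - spliced_genes + isoforms hold by
    construction.
    """
    splice_table = splice_table or {}
    rows: dict[tuple[str, str], dict] = {}
    for m in models:
        if m.status == "partial":
            continue
        key = (m.species, m.family)
        row = rows.setdefault(key, {
            "species": key[0], "family": key[1], "loci": 0,
            "functional_genes": 0, "pseudogenes": 0,
            "genes_with_splice_variants": 0, "splice_variants": 0,
        })
        row["loci"] += 1
        if m.status == "pseudogene":
            row["pseudogenes"] += 1
        else:
            row["functional_genes"] += 1
            iso = splice_table.get(m.id, 1)
            if iso > 1:
                row["genes_with_splice_variants"] += 1
                row["splice_variants"] += iso
    out = pd.DataFrame(sorted(rows.values(),
                              key=lambda r: (r["species"], r["family"])))
    if out.empty:
        return pd.DataFrame(columns=[
            "species", "family", "loci", "functional_genes", "pseudogenes",
            "genes_with_splice_variants", "splice_variants",
            "total_functional_proteins", "pct_pseudogenes"])
    out["total_functional_proteins"] = (
        out["functional_genes"] - out["genes_with_splice_variants"]
        + out["splice_variants"])
    out["pct_pseudogenes"] = (100.0 * out["pseudogenes"] / out["loci"]).round(1)
    return out


def repertoire_from_counts(
    species: str, family: str, loci: int, pseudogenes: int,
    spliced_genes: int, isoforms: int,
) -> pd.DataFrame:
    """Table-1 arithmetic from printed counts (no gene models needed)."""
    functional = loci - pseudogenes
    return pd.DataFrame([{
        "species": species, "family": family, "loci": loci,
        "functional_genes": functional, "pseudogenes": pseudogenes,
        "genes_with_splice_variants": spliced_genes,
        "splice_variants": isoforms,
        "total_functional_proteins": functional - spliced_genes + isoforms,
        "pct_pseudogenes": round(100.0 * pseudogenes / loci, 1) if loci else 0.0,
    }])


# ---------------------------------------------------------------------------
# orthogroups and lost lineages
# ---------------------------------------------------------------------------

def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(scoring=None)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def assign_orthogroups(
    proteomes: dict[str, dict[str, str]]
) -> pd.DataFrame:
    """Reciprocal-best-hit orthogroups from per-species protein sets.

    All cross-species pairs are scored with affine-gap global alignment
    (BLOSUM62, open 10 / extend 1); each gene's best hit per other
    species (ties broken by lexicographic gene id) contributes an edge
    when reciprocal, and connected components of the RBH graph are the
    orthogroups.  Genes without any reciprocal partner form singletons.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two species")
    all_ids = [g for sp in proteomes.values() for g in sp]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("duplicate gene ids across proteomes")
    aligner = _protein_aligner()
    species = sorted(proteomes)
    gene_species = {g: sp for sp in species for g in proteomes[sp]}

    score_cache: dict[tuple[str, str], float] = {}

    def score(g1, g2):
        key = (g1, g2) if g1 < g2 else (g2, g1)
        if key not in score_cache:
            score_cache[key] = aligner.score(
                proteomes[gene_species[key[0]]][key[0]],
                proteomes[gene_species[key[1]]][key[1]])
        return score_cache[key]

    best: dict[tuple[str, str], str] = {}  # (gene, other species) -> best hit
    for sp_a in species:
        for g in sorted(proteomes[sp_a]):
            for sp_b in species:
                if sp_b == sp_a or not proteomes[sp_b]:
                    continue
                hit = max(sorted(proteomes[sp_b]),
                          key=lambda h: (score(g, h), ), default=None)
                # max keeps the first of equal-score hits; sorted input
                # makes that the lexicographically smallest id
                if hit is not None:
                    best[(g, sp_b)] = hit

    parent = {g: g for g in all_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for (g, sp_b), hit in best.items():
        if best.get((hit, gene_species[g])) == g:
            union(g, hit)

    components: dict[str, list[str]] = {}
    for g in all_ids:
        components.setdefault(find(g), []).append(g)
    rows = []
    for i, comp in enumerate(
            sorted((sorted(c) for c in components.values()))):
        og = f"OG{i + 1:04d}"
        for g in comp:
            rows.append({"og_id": og, "species": gene_species[g], "gene": g})
    return pd.DataFrame(rows)


def call_lost_lineages(
    orthogroups: pd.DataFrame,
    statuses: dict[str, str],
    species: Iterable[str] | None = None,
) -> dict[str, list[str]]:
    """Orthogroups with no intact member per species (lost lineages).

    A lineage counts as lost in a species when the species has no
    intact member of the orthogroup - whether its members are
    pseudogenes/partials (vestiges) or absent entirely.
    """
    if species is None:
        species = sorted(orthogroups["species"].unique())
    species = list(species)
    missing = [g for g in orthogroups["gene"] if g not in statuses]
    if missing:
        raise ValueError(f"no status for genes: {missing[:5]}")
    lost: dict[str, list[str]] = {sp: [] for sp in species}
    for og_id, grp in orthogroups.groupby("og_id"):
        intact_sp = {r.species for r in grp.itertuples()
                     if statuses[r.gene] == "intact"}
        for sp in species:
            if sp not in intact_sp:
                lost[sp].append(og_id)
    return {sp: sorted(v) for sp, v in lost.items()}


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------

def name_gene(
    homolog: str,
    species: str,
    copy_index: int | None = None,
    is_pseudo: bool = False,
) -> str:
    """Community-style gene id: D + 3-letter epithet + homolog [+ -N] [+ P].

    ``species`` may be a full epithet ('suzukii') or a known 4-letter
    tag ('Dsuz').  ``copy_index`` is given only for duplicates.
    """
    if species in SPECIES_TAGS:
        tag = SPECIES_TAGS[species]
    elif species in SPECIES_TAGS.values():
        tag = species
    else:
        raise ValueError(f"unknown species {species!r}")
    name = f"{tag}{homolog}"
    if copy_index is not None:
        name += f"-{copy_index}"
    if is_pseudo:
        name += "P"
    return name
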