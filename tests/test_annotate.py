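"""Classification, repertoire arithmetic, orthogroups, nomenclature."""

import numpy as np
import pytest
from Bio.Seq import Seq

from _oracles import global_align_score
from chemevol.annotate import (
    GeneModel,
    assign_orthogroups,
    call_lost_lineages,
    classify_gene_model,
    name_gene,
    predict_tm_segments,
    repertoire_from_counts,
    summarize_repertoire,
    translate_cds,
)
from chemevol.simulate import inject_lesion, random_intact_cds


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def test_translate_basic_and_flags():
    assert translate_cds("ATGTTTTAA") == ("MF", None)
    assert translate_cds("ATGTAAAAA") == ("M", 1)
    with pytest.raises(ValueError):
        translate_cds("ATGXTTTAA")
    with pytest.raises(ValueError):
        translate_cds("ATGTT")


def test_translate_matches_biopython_oracle():
    cds = random_intact_cds(300, seed=12)
    ours = translate_cds(cds).protein
    theirs = str(Seq(cds).translate()).rstrip("*")
    assert ours == theirs


# ---------------------------------------------------------------------------
# TM prediction
# ---------------------------------------------------------------------------

def test_tm_poly_leucine_single_segment():
    segs = predict_tm_segments("L" * 30)
    assert len(segs) == 1
    assert segs[0].end - segs[0].start + 1 >= 28


def test_tm_poly_aspartate_none():
    assert predict_tm_segments("D" * 30) == []


def _seven_tm_protein():
    return "D" * 15 + ("L" * 21 + "D" * 15) * 7


def test_tm_synthetic_seven_tm_protein():
    assert len(predict_tm_segments(_seven_tm_protein())) == 7


def test_tm_short_protein_warns_empty():
    with pytest.warns(UserWarning):
        assert predict_tm_segments("LLLL") == []


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _cds_for(protein: str) -> str:
    codon = {"L": "CTG", "D": "GAT", "M": "ATG", "A": "GCT"}
    return "ATG" + "".join(codon[a] for a in protein) + "TAA"


def test_premature_stop_losing_half_is_pseudogene():
    ref = _seven_tm_protein()
    cds = _cds_for(ref)
    n_cod = len(cds) // 3
    les, truth = inject_lesion(cds, "premature_stop", n_cod // 2, seed=1)
    assert 0.4 < truth.fraction_lost < 0.6
    result = classify_gene_model(les, "M" + ref)
    assert result.status == "pseudogene"
    assert result.tm_lost >= 3
    assert result.lesions[0].kind == "premature_stop"


def test_small_loss_stays_intact():
    ref = _seven_tm_protein()
    cds = _cds_for(ref)
    n_cod = len(cds) // 3
    les, truth = inject_lesion(cds, "premature_stop", int(n_cod * 0.92), seed=1)
    assert truth.fraction_lost < 0.20
    assert classify_gene_model(les, "M" + ref).status == "intact"


def test_conjunctive_rule_requires_tm_loss():
    """A 25 % loss with no TM in the lost tail is intact under the
    conjunctive rule, pseudogene under either-sufficient."""
    # TMs only in the first 60 %; featureless acidic tail after
    ref = "M" + ("L" * 21 + "D" * 10) * 5 + "D" * 100
    cds = _cds_for(ref[1:])
    n_cod = len(cds) // 3
    les, truth = inject_lesion(cds, "premature_stop", int(n_cod * 0.75), seed=2)
    assert truth.fraction_lost >= 0.20
    conj = classify_gene_model(les, ref)
    assert conj.tm_lost == 0
    assert conj.status == "intact"
    disj = classify_gene_model(les, ref, conjunctive=False)
    assert disj.status == "pseudogene"


def test_truncation_without_lesion_is_partial():
    ref = _seven_tm_protein()
    cds = _cds_for(ref)
    # assembly truncation: drop the last 40 % of codons and the stop
    keep = (len(cds) // 3) * 6 // 10
    truncated = cds[: 3 * keep]
    result = classify_gene_model(truncated, "M" + ref)
    assert result.status == "partial"
    assert result.lesions == []


def test_classify_rejects_empty_reference():
    with pytest.raises(ValueError):
        classify_gene_model("ATGTTTTAA", "")


# ---------------------------------------------------------------------------
# repertoire arithmetic
# ---------------------------------------------------------------------------

def _models(species, family, n_intact, n_pseudo):
    out = []
    for i in range(n_intact + n_pseudo):
        pseudo = i >= n_intact
        out.append(GeneModel(
            id=f"{species}{family}{i + 1}{'P' if pseudo else ''}",
            species=species, cds="ATGTTTTAA",
            status="pseudogene" if pseudo else "intact"))
    return out


def test_suzukii_or_repertoire_numbers():
    """71 Or loci with 9 pseudogenes and 2 spliced genes encoding 6
    isoforms give 62 functional genes, 66 proteins, 12.7 % pseudogenes."""
    models = _models("Dsuz", "Or", 62, 9)
    splice = {"DsuzOr1": 3, "DsuzOr2": 3}
    table = summarize_repertoire(models, splice)
    row = table.iloc[0]
    assert row["loci"] == 71
    assert row["functional_genes"] == 62
    assert row["pseudogenes"] == 9
    assert row["total_functional_proteins"] == 66
    assert row["pct_pseudogenes"] == 12.7


def test_suzukii_gr_repertoire_numbers():
    models = _models("Dsuz", "Gr", 71, 3)
    splice = {"DsuzGr1": 4, "DsuzGr2": 4, "DsuzGr3": 5}
    row = summarize_repertoire(models, splice).iloc[0]
    assert row["loci"] == 74
    assert row["functional_genes"] == 71
    assert row["total_functional_proteins"] == 81


@pytest.mark.parametrize(
    "species,family,loci,pseudo,spliced,iso,functional,proteins",
    [
        ("Dsuz", "Or", 71, 9, 2, 6, 62, 66),
        ("Dbia", "Or", 64, 4, 2, 7, 60, 65),
        ("Dtak", "Or", 71, 1, 2, 9, 70, 77),
        ("Dsuz", "Gr", 74, 3, 3, 13, 71, 81),
        ("Dbia", "Gr", 74, 0, 3, 12, 74, 83),
        ("Dtak", "Gr", 88, 6, 3, 12, 82, 91),
    ])
def test_repertoire_identities_hold_for_all_annotated_species(
        species, family, loci, pseudo, spliced, iso, functional, proteins):
    row = repertoire_from_counts(species, family, loci, pseudo,
                                 spliced, iso).iloc[0]
    assert row["functional_genes"] == functional
    assert row["total_functional_proteins"] == proteins


def test_empty_model_list_gives_empty_table():
    assert summarize_repertoire([]).empty


def test_partials_excluded_from_counts():
    models = _models("Dsuz", "Or", 3, 1)
    models.append(GeneModel(id="DsuzOr99", species="Dsuz",
                            cds="ATGTTTTAA", status="partial"))
    row = summarize_repertoire(models).iloc[0]
    assert row["loci"] == 4 and row["functional_genes"] == 3


# ---------------------------------------------------------------------------
# orthogroups
# ---------------------------------------------------------------------------

def test_identical_proteomes_pair_up():
    prots = {"A": {"A_x": "MKLLVVLLAA", "A_y": "MWWDDEEKKR"},
             "B": {"B_x": "MKLLVVLLAA", "B_y": "MWWDDEEKKR"}}
    table = assign_orthogroups(prots)
    groups = table.groupby("og_id")["gene"].apply(sorted).tolist()
    assert sorted(map(tuple, groups)) == [("A_x", "B_x"), ("A_y", "B_y")]


def test_unreciprocated_protein_is_singleton():
    prots = {
        "A": {"A_x": "MKLLVVLLAA"},
        "B": {"B_x": "MKLLVVLLAA", "B_z": "MWWWWWWWWW"},
    }
    table = assign_orthogroups(prots)
    sizes = table.groupby("og_id").size()
    assert sorted(sizes) == [1, 2]


def test_orthogroups_match_score_matrix_oracle():
    """Components agree with RBH built from an independent Gotoh DP."""
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(0)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    base = ["".join(rng.choice(list(aas), size=12)) for _ in range(3)]

    def mutate(s, k):
        s = list(s)
        for pos in rng.choice(len(s), size=k, replace=False):
            s[pos] = rng.choice(list(aas))
        return "".join(s)

    prots = {
        "A": {f"A_g{i}": base[i] for i in range(3)},
        "B": {f"B_g{i}": mutate(base[i], 2) for i in range(3)},
        "C": {f"C_g{i}": mutate(base[i], 3) for i in range(2)},
    }
    table = assign_orthogroups(prots)
    got = sorted(tuple(sorted(g)) for _, g in table.groupby("og_id")["gene"])

    # oracle: full score matrix via the DP in _oracles, then RBH + union
    genes = [(sp, g) for sp in sorted(prots) for g in sorted(prots[sp])]
    score = {}
    for i, (sa, ga) in enumerate(genes):
        for sb, gb in genes[i + 1:]:
            score[(ga, gb)] = score[(gb, ga)] = global_align_score(
                prots[sa][ga], prots[sb][gb], blosum)
    best = {}
    for sa, ga in genes:
        for sb in sorted(prots):
            if sb == sa:
                continue
            cands = sorted(prots[sb])
            best[(ga, sb)] = max(cands, key=lambda h: (score[(ga, h)],
                                                       -ord(h[0]), h < h))
            best[(ga, sb)] = sorted(
                cands, key=lambda h: (-score[(ga, h)], h))[0]
    parent = {g: g for _, g in genes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for (ga, sb), h in best.items():
        sa = ga.split("_")[0]
        if best.get((h, sa)) == ga:
            ra, rb = find(ga), find(h)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    comps = {}
    for _, g in genes:
        comps.setdefault(find(g), []).append(g)
    want = sorted(tuple(sorted(c)) for c in comps.values())
    assert got == want


def test_orthogroups_symmetric_under_species_order():
    prots = {
        "B": {"B_x": "MKLLVVLLAA", "B_y": "MWWDDEEKKR"},
        "A": {"A_x": "MKLLVVLLAA", "A_y": "MWWDDEEKKR"},
    }
    t1 = assign_orthogroups(prots)
    t2 = assign_orthogroups(dict(reversed(list(prots.items()))))
    g1 = sorted(tuple(sorted(g)) for _, g in t1.groupby("og_id")["gene"])
    g2 = sorted(tuple(sorted(g)) for _, g in t2.groupby("og_id")["gene"])
    assert g1 == g2


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError):
        assign_orthogroups({"A": {"x": "MKL"}, "B": {"x": "MKL"}})


# ---------------------------------------------------------------------------
# lost lineages
# ---------------------------------------------------------------------------

def _og_table():
    import pandas as pd
    rows = []
    spec = {
        "Or74a": {"Dsuz": "pseudogene", "Dbia": "intact", "Dtak": "intact"},
        "Or85a": {"Dsuz": "pseudogene", "Dbia": "intact", "Dtak": "intact"},
        "Or98b": {"Dsuz": "pseudogene", "Dbia": "intact", "Dtak": "intact"},
        "Or33c": {"Dsuz": "intact", "Dbia": "pseudogene", "Dtak": "intact"},
        "Or42a": {"Dsuz": "intact", "Dbia": "intact", "Dtak": "intact"},
    }
    statuses = {}
    for og, members in spec.items():
        for sp, status in members.items():
            gene = f"{sp}{og}"
            rows.append({"og_id": og, "species": sp, "gene": gene})
            statuses[gene] = status
    return pd.DataFrame(rows), statuses


def test_lost_lineages_match_annotated_pattern():
    """Or74a/Or85a/Or98b lost in Dsuz, Or33c in Dbia, none in Dtak."""
    table, statuses = _og_table()
    lost = call_lost_lineages(table, statuses)
    assert lost["Dsuz"] == ["Or74a", "Or85a", "Or98b"]
    assert lost["Dbia"] == ["Or33c"]
    assert lost["Dtak"] == []


def test_og_intact_everywhere_lost_nowhere():
    table, statuses = _og_table()
    for sp_lost in call_lost_lineages(
            table[table.og_id == "Or42a"], statuses).values():
        assert sp_lost == []


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("args,want", [
    (("Or23a", "suzukii", 2, False), "DsuzOr23a-2"),
    (("Or67a", "suzukii", None, True), "DsuzOr67aP"),
    (("Gr59d", "takahashii", 1, False), "DtakGr59d-1"),
    (("Or33c", "Dbia", None, False), "DbiaOr33c"),
])
def test_gene_naming(args, want):
    assert name_gene(*args) == want


def test_unknown_species_rejected():
    with pytest.raises(ValueError):
        name_gene("Or1", "martianus")
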