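"""Codon model, pruning likelihood, branch-site LRT machinery."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from _oracles import bh_enum, holm_enum, loglik_enum
from chemevol.codonmodel import (
    build_mg94,
    f3x4_frequencies,
    mg94_flux,
    uniform_codon_freqs,
)
from chemevol.codons import CODON_INDEX, SENSE_CODONS
from chemevol.selection import (
    PruningEngine,
    benjamini_hochberg,
    fit_branch_site,
    holm_bonferroni,
    lrt_pvalue,
    scan_gene_sets,
    site_posteriors,
    tree_loglik,
)
from chemevol.simulate import SimConfig, evolve_codons
from chemevol.trees import parse_newick


# ---------------------------------------------------------------------------
# F3x4 and the generator
# ---------------------------------------------------------------------------

def test_f3x4_uniform_composition_gives_uniform_pi():
    # all 61 sense codons once: not perfectly uniform nucleotide-wise,
    # so build a synthetic alignment with equal nucleotide counts per
    # position instead
    seqs = {"a": "".join(nt * 3 for nt in "ACGT")}  # AAA CCC GGG TTT
    pi = f3x4_frequencies(seqs)
    assert pi.sum() == pytest.approx(1.0)
    # every sense codon has probability (1/4)^3 before stop exclusion;
    # renormalization by (1 - 3/64) makes them equal
    assert np.allclose(pi, 1 / 61, atol=1e-12)


def test_f3x4_zero_count_position_warns_with_pseudocount():
    with pytest.warns(UserWarning):
        pi = f3x4_frequencies({"a": "AAAAAA"})
    assert pi.sum() == pytest.approx(1.0)


def test_f3x4_repeated_codon_is_modal():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pi = f3x4_frequencies({"a": "ATG" * 30})
    assert SENSE_CODONS[int(np.argmax(pi))] == "ATG"


def test_mg94_generator_invariants():
    pi = uniform_codon_freqs()
    model = build_mg94(kappa=2.5, omega=0.4, pi=pi)
    Q = model.Q
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-10)
    # detailed balance
    flux = pi[:, None] * Q
    assert np.allclose(flux, flux.T, atol=1e-12)
    # unit mean rate
    assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-10)
    # multi-nucleotide changes forbidden
    for i, ci in enumerate(SENSE_CODONS[:10]):
        for j, cj in enumerate(SENSE_CODONS[:10]):
            diffs = sum(a != b for a, b in zip(ci, cj))
            if diffs > 1:
                assert Q[i, j] == 0.0


def test_transition_matrix_matches_scipy_expm():
    pi = uniform_codon_freqs()
    model = build_mg94(kappa=2.0, omega=1.0, pi=pi)
    for t in (0.01, 0.1, 1.0):
        P = model.transition_matrix(t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(P, expm(model.Q * t), atol=1e-9)


def test_shared_clock_flux_normalization():
    """Elevated-omega matrices under the background clock run faster."""
    pi = uniform_codon_freqs()
    f1 = mg94_flux(2.0, 0.2, pi)
    m_fast = build_mg94(2.0, 5.0, pi, rate_scale=f1)
    rate = -(pi * np.diag(m_fast.Q)).sum()
    assert rate > 5.0  # several-fold faster than the background clock


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def _toy_alignment(tree_text, n_sites, seed, omega=0.5):
    tree = parse_newick(tree_text)
    cfg = SimConfig(seed=seed, n_codons=n_sites,
                    site_classes=((1.0, omega),))
    aln, _ = evolve_codons(tree, cfg)
    return tree, aln


def test_single_sequence_zero_tree_loglik_is_log_pi():
    tree = parse_newick("(A_1:0.0,B_1:0.0);")
    cfg = SimConfig(seed=1, n_codons=20)
    aln, _ = evolve_codons(tree, cfg)
    pi = uniform_codon_freqs()
    model = build_mg94(2.0, 1.0, pi)
    models = {n: model for n in tree.postorder() if n.parent is not None}
    lnl, _ = tree_loglik(aln, tree, [(1.0, models)], pi)
    want = sum(math.log(pi[CODON_INDEX[aln["A_1"][i:i + 3]]])
               for i in range(0, len(aln["A_1"]), 3))
    assert lnl == pytest.approx(want, rel=1e-12)


@pytest.mark.parametrize("tree_text,n_sites", [
    ("((A_1:0.2,B_1:0.3):0.1,C_1:0.4);", 2),
    ("((A_1:0.1,B_1:0.1):0.2,(C_1:0.3,D_1:0.1):0.1);", 3),
])
def test_pruning_matches_state_enumeration(tree_text, n_sites):
    """Pruning lnL equals exhaustive summation over internal states."""
    tree, aln = _toy_alignment(tree_text, n_sites, seed=3)
    pi = uniform_codon_freqs()
    model = build_mg94(2.0, 0.5, pi)
    models = {n: model for n in tree.postorder() if n.parent is not None}
    lnl, _ = tree_loglik(aln, tree, [(1.0, models)], pi)
    leaf_states = {
        name: [CODON_INDEX[seq[3 * i:3 * i + 3]] for i in range(n_sites)]
        for name, seq in aln.items()}
    P_of_node = {n: model.transition_matrix(n.length)
                 for n in tree.postorder() if n.parent is not None}
    want = loglik_enum(tree, leaf_states, P_of_node, pi)
    assert abs(lnl - want) / abs(want) < 1e-10


def test_site_likelihoods_sum_to_one_over_observations():
    """Summing site likelihood over every possible leaf pair equals 1."""
    pi = uniform_codon_freqs()
    model = build_mg94(1.5, 0.8, pi)
    tree = parse_newick("(A_1:0.2,B_1:0.4);")
    Pa = model.transition_matrix(0.2)
    Pb = model.transition_matrix(0.4)
    total = float(np.einsum("r,ra,rb->", pi, Pa, Pb))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_duplicated_pattern_doubles_contribution():
    tree, aln = _toy_alignment("((A_1:0.2,B_1:0.3):0.1,C_1:0.4);", 4, seed=9)
    pi = uniform_codon_freqs()
    model = build_mg94(2.0, 0.5, pi)
    models = {n: model for n in tree.postorder() if n.parent is not None}
    lnl1, _ = tree_loglik(aln, tree, [(1.0, models)], pi)
    doubled = {k: v + v for k, v in aln.items()}
    lnl2, _ = tree_loglik(doubled, tree, [(1.0, models)], pi)
    assert lnl2 == pytest.approx(2 * lnl1, rel=1e-12)


def test_alignment_tree_mismatch_lists_offenders():
    tree = parse_newick("(A_1:0.1,B_1:0.1);")
    with pytest.raises(ValueError, match="B_1"):
        PruningEngine({"A_1": "ATG", "X_1": "ATG"}, tree)


# ---------------------------------------------------------------------------
# LRT p-values and corrections
# ---------------------------------------------------------------------------

def test_lrt_pvalue_examples_and_monotonicity():
    assert lrt_pvalue(0.0) == 1.0
    assert lrt_pvalue(2.71) == pytest.approx(
        0.5 * stats.chi2.sf(2.71, 1), rel=1e-12)
    assert lrt_pvalue(2.71) == pytest.approx(0.05, abs=2e-3)
    grid = [lrt_pvalue(x) for x in (0.01, 0.5, 1, 2, 5, 10)]
    assert all(a > b for a, b in zip(grid, grid[1:]))
    assert lrt_pvalue(5.0, null="chi2") == pytest.approx(
        stats.chi2.sf(5.0, 1))
    with pytest.raises(ValueError):
        lrt_pvalue(-1.0)


def test_holm_examples_and_oracle():
    assert holm_bonferroni([0.03]) == pytest.approx([0.03])
    assert holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])
    rng = np.random.default_rng(2)
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 12)))
        assert holm_bonferroni(p) == pytest.approx(holm_enum(p.tolist()))


def test_bh_examples_and_oracle():
    assert benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)
    assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04] * 4)
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 12)))
        q = benjamini_hochberg(p)
        assert q == pytest.approx(bh_enum(p.tolist()))
        assert np.all(q >= p - 1e-12)


# ---------------------------------------------------------------------------
# branch-site fits
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def selected_fit(nine_species_truth):
    truth = nine_species_truth
    cfg = SimConfig(seed=104, n_codons=500,
                    site_classes=((0.9, 0.2), (0.1, 5.0)),
                    foreground_branches=("Dsuz",))
    aln, site_class = evolve_codons(truth.gene_tree, cfg, truth=truth)
    fit = fit_branch_site(aln, truth.gene_tree, "Dsuz_1")
    return fit, site_class


def test_alternative_never_below_null(selected_fit):
    fit, _ = selected_fit
    assert fit.lnL_alt >= fit.lnL_null - 1e-6
    assert fit.LR >= 0.0


def test_selection_recovered_on_foreground(selected_fit):
    fit, _ = selected_fit
    assert fit.converged
    assert fit.omega2 > 1.0
    assert fit.LR > 3.0
    assert 0.02 < fit.p2 < 0.3


def test_null_simulation_gives_small_lr(nine_species_truth):
    truth = nine_species_truth
    lrs = []
    for seed in (601, 602, 603):
        cfg = SimConfig(seed=seed, n_codons=200, site_classes=((1.0, 0.2),))
        aln, _ = evolve_codons(truth.gene_tree, cfg, truth=truth)
        fit = fit_branch_site(aln, truth.gene_tree, "Dsuz_1")
        lrs.append(fit.LR)
    assert np.mean(lrs) < 2.0


def test_posteriors_enrich_true_selected_sites(selected_fit):
    fit, site_class = selected_fit
    post = site_posteriors(fit)
    assert np.all((post.posterior >= 0) & (post.posterior <= 1))
    sel = site_class == 1
    assert post.posterior[sel].mean() > post.posterior[~sel].mean() + 0.2
    if len(post.flagged):
        flagged_true = np.isin(post.flagged, np.nonzero(sel)[0])
        assert flagged_true.mean() > 0.5


def test_grid_posteriors_close_to_neb(selected_fit):
    fit, _ = selected_fit
    neb = site_posteriors(fit, method="neb")
    grid = site_posteriors(fit, method="grid", grid_size=6)
    # same ranking of the top sites
    top_neb = set(np.argsort(neb.posterior)[-10:])
    top_grid = set(np.argsort(grid.posterior)[-10:])
    assert len(top_neb & top_grid) >= 6


def test_unknown_branch_rejected(nine_species_truth):
    truth = nine_species_truth
    cfg = SimConfig(seed=11, n_codons=30)
    aln, _ = evolve_codons(truth.gene_tree, cfg, truth=truth)
    with pytest.raises(ValueError, match="no branch"):
        fit_branch_site(aln, truth.gene_tree, "Dxxx_9")


# ---------------------------------------------------------------------------
# gene-set scan
# ---------------------------------------------------------------------------

def _batch(nine_species_truth, n_sets=4, selected=("set1",)):
    truth = nine_species_truth
    sets = []
    for i in range(n_sets):
        name = f"set{i}"
        fg = ("Dsuz",) if name in selected else ()
        classes = ((0.9, 0.2), (0.1, 6.0)) if fg else ((1.0, 0.2),)
        cfg = SimConfig(seed=900 + i, n_codons=400, site_classes=classes,
                        foreground_branches=fg)
        aln, _ = evolve_codons(truth.gene_tree, cfg, truth=truth)
        sets.append({"name": name, "alignment": aln,
                     "tree": truth.gene_tree})
    return sets


def test_scan_flags_only_the_selected_set(nine_species_truth):
    sets = _batch(nine_species_truth)
    table = scan_gene_sets(sets, branches={None: ["Dsuz_1", "Dtak_1"]})
    sig = table[table.p_holm < 0.05]
    assert set(sig["set"]) == {"set1"}
    assert set(sig["branch"]) == {"Dsuz_1"}
    assert {"omega1", "p2_pct", "omega2", "LR", "p_raw", "p_holm",
            "q_bh", "flagged_sites"} <= set(table.columns)


def test_scan_order_invariant(nine_species_truth):
    sets = _batch(nine_species_truth, n_sets=3)
    t1 = scan_gene_sets(sets, branches={None: ["Dsuz_1"]})
    t2 = scan_gene_sets(list(reversed(sets)), branches={None: ["Dsuz_1"]})
    assert t1.equals(t2)


def test_scan_skips_bad_sets(nine_species_truth):
    sets = _batch(nine_species_truth, n_sets=2, selected=())
    sets.append({"name": "broken", "alignment": {"A_1": "ATG"},
                 "tree": parse_newick("(A_1:1,B_1:1);")})
    table = scan_gene_sets(sets, branches={None: ["Dsuz_1"]})
    assert "broken" not in set(table["set"])
    assert any(s["set"] == "broken" for s in table.attrs["skipped"])
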