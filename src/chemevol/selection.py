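"""Branch-site likelihood tests for episodic diversifying selection.

The model is the fixed two-class branch-site arrangement on an
MG94xHKY codon process with F3x4 frequencies: all sites evolve at a
shared omega1 on background branches, while on one designated
foreground branch a fraction p2 of sites switches to omega2 >= 1.  The
null pins omega2 = 1; twice the log-likelihood difference is referred
to a 50:50 mixture of a point mass at zero and chi-square(1df) (the
boundary null), with plain chi-square(1df) available as a conservative
switch.  Per-site empirical-Bayes posteriors identify the selected
sites (naive EB at the MLEs, optionally averaged over a uniform
parameter grid).

Nuisance parameters follow the usual two-stage scheme: a baseline
single-omega fit estimates kappa and the tree scale, which the
class-parameter optimization then holds fixed.

Multiple testing: Holm-Bonferroni within a gene set (familywise error
across the branches tested in that set), Benjamini-Hochberg across
gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .codonmodel import CodonModel, build_mg94, f3x4_frequencies, mg94_flux
from .codons import CODON_INDEX
from .trees import TreeNode

__all__ = [
    "PruningEngine", "BranchSiteFit", "fit_branch_site", "tree_loglik",
    "lrt_pvalue", "holm_bonferroni", "benjamini_hochberg",
    "site_posteriors", "scan_gene_sets", "branch_label",
]


def branch_label(node: TreeNode) -> str:
    """Stable identifier of the branch above a node."""
    return node.label if (node.label and node.is_leaf) else (
        node.label or "|".join(sorted(node.leaf_names())))


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------

class PruningEngine:
    """Felsenstein pruning over the 61 sense-codon states.

    Site patterns are compressed once at construction; every
    likelihood evaluation is a postorder sweep of (patterns x 61) @
    (61 x 61) products, cheap enough to sit inside an optimizer loop.
    """

    def __init__(self, alignment: dict[str, str], tree: TreeNode):
        leaf_names = set(tree.leaf_names())
        row_names = set(alignment)
        if leaf_names != row_names:
            missing = sorted(leaf_names - row_names)
            extra = sorted(row_names - leaf_names)
            raise ValueError(
                f"alignment/tree mismatch; missing rows {missing}, "
                f"unmatched rows {extra}")
        lengths = {len(s) for s in alignment.values()}
        if len(lengths) != 1 or next(iter(lengths)) % 3:
            raise ValueError("alignment rows must be equal length codon sequences")
        self.tree = tree
        self.nodes = list(tree.postorder())
        self.leaves = [n for n in self.nodes if n.is_leaf]
        n_sites = next(iter(lengths)) // 3
        mat = np.empty((len(self.leaves), n_sites), dtype=np.int64)
        for r, leaf in enumerate(self.leaves):
            seq = alignment[leaf.label].upper()
            for i in range(n_sites):
                codon = seq[3 * i: 3 * i + 3]
                if codon not in CODON_INDEX:
                    raise ValueError(
                        f"row {leaf.label}: {codon!r} at codon {i} is not a "
                        "sense codon (alignments here are gap-free)")
                mat[r, i] = CODON_INDEX[codon]
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True)
        self.pattern_of_site = inverse
        self.pattern_counts = counts.astype(float)
        self.n_sites = n_sites
        self.n_patterns = patterns.shape[1]
        self.leaf_states = {leaf: patterns[r] for r, leaf in enumerate(self.leaves)}

    # -- single-class sweep --------------------------------------------
    def partials(self, P_map: dict[TreeNode, np.ndarray],
                 only_path_from: TreeNode | None = None,
                 base: dict | None = None) -> dict:
        """Conditional likelihoods per node; optionally redo one root path.

        With ``only_path_from`` set, nodes off the path from that node
        to the root are reused from ``base`` (the foreground-override
        trick for two-class models).
        """
        out = dict(base) if base is not None else {}
        path = None
        if only_path_from is not None:
            path = set()
            n = only_path_from
            while n is not None:
                path.add(n)
                n = n.parent
        for node in self.nodes:
            if node.is_leaf:
                continue
            if path is not None and node not in path and node in out:
                continue
            part = None
            for child in node.children:
                P = P_map[child]
                if child.is_leaf:
                    msg = P[:, self.leaf_states[child]].T
                else:
                    msg = out[child] @ P.T
                part = msg if part is None else part * msg
            out[node] = part
        return out

    def pattern_likelihoods(self, P_map: dict[TreeNode, np.ndarray],
                            pi: np.ndarray, **kw) -> np.ndarray:
        root_part = self.partials(P_map, **kw)[self.tree]
        return np.maximum(root_part @ pi, 1e-300)

    def loglik(self, class_likelihoods: list[np.ndarray],
               weights: np.ndarray) -> tuple[float, np.ndarray]:
        """Mixture log-likelihood and per-pattern site log-likelihoods."""
        mix = np.zeros_like(class_likelihoods[0])
        for w, lk in zip(weights, class_likelihoods):
            mix += w * lk
        site_lnl = np.log(np.maximum(mix, 1e-300))
        return float((site_lnl * self.pattern_counts).sum()), site_lnl


def tree_loglik(
    alignment: dict[str, str],
    tree: TreeNode,
    mixture: list[tuple[float, dict[TreeNode, CodonModel]]],
    pi: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mixture log-likelihood of an alignment on a tree.

    ``mixture`` is a list of (weight, branch -> CodonModel) classes;
    each branch is keyed by its child node and evolves for that node's
    branch length.  Returns (lnL, per-site log-likelihoods expanded
    back to site order).
    """
    engine = PruningEngine(alignment, tree)
    class_liks = []
    weights = []
    for w, models in mixture:
        P_map = {n: models[n].transition_matrix(n.length or 0.0)
                 for n in engine.nodes if n.parent is not None}
        class_liks.append(engine.pattern_likelihoods(P_map, pi))
        weights.append(w)
    lnl, site_lnl = engine.loglik(class_liks, np.asarray(weights))
    return lnl, site_lnl[engine.pattern_of_site]


# ---------------------------------------------------------------------------
# model cache
# ---------------------------------------------------------------------------

class _ModelCache:
    def __init__(self, pi):
        self.pi = pi
        self._cache: dict[tuple, CodonModel] = {}
        self._flux: dict[tuple, float] = {}

    def get(self, kappa: float, omega: float,
            clock_omega: float | None = None) -> CodonModel:
        """Model for omega; ``clock_omega`` shares that class's clock.

        The foreground elevated class is normalized by the background
        class's flux so that omega2 sites evolve faster rather than
        merely differing in composition - matching the simulator's
        shared-clock convention.
        """
        key = (round(kappa, 12), round(omega, 12),
               None if clock_omega is None else round(clock_omega, 12))
        if key not in self._cache:
            rate_scale = None
            if clock_omega is not None:
                fkey = (round(kappa, 12), round(clock_omega, 12))
                if fkey not in self._flux:
                    self._flux[fkey] = mg94_flux(kappa, clock_omega, self.pi)
                rate_scale = self._flux[fkey]
            self._cache[key] = build_mg94(kappa, omega, self.pi,
                                          rate_scale=rate_scale)
        return self._cache[key]


# ---------------------------------------------------------------------------
# branch-site fit
# ---------------------------------------------------------------------------

@dataclass
class BranchSiteFit:
    """MLEs and log-likelihoods of one branch-site test."""

    foreground: str
    kappa: float
    omega1: float
    p2: float
    omega2: float
    lnL_alt: float
    lnL_null: float
    omega1_null: float
    p2_null: float
    scale: float
    converged: bool
    engine: PruningEngine = field(repr=False, default=None)
    pi: np.ndarray = field(repr=False, default=None)
    _cache: _ModelCache = field(repr=False, default=None)
    _fg_node: TreeNode = field(repr=False, default=None)

    @property
    def LR(self) -> float:
        lr = 2.0 * (self.lnL_alt - self.lnL_null)
        if lr < -1e-6:
            raise AssertionError("alternative fit worse than null beyond tolerance")
        return max(0.0, lr)


def _branch_site_objective(engine, cache, fg_node, scaled_len):
    """Factory for the two-class mixture negative log-likelihood.

    Class A: omega1 on every branch.  Class B: omega1 on background,
    omega2 on the foreground branch.  Only the root path is recomputed
    for class B.
    """
    def evaluate(kappa, omega1, omega2, p2):
        m1 = cache.get(kappa, omega1)
        P_bg = {n: m1.transition_matrix(scaled_len[n]) for n in scaled_len}
        base = engine.partials(P_bg)
        likA = np.maximum(base[engine.tree] @ cache.pi, 1e-300)
        if omega2 == omega1:
            likB = likA
        else:
            m2 = cache.get(kappa, omega2, clock_omega=omega1)
            P_fg = dict(P_bg)
            P_fg[fg_node] = m2.transition_matrix(scaled_len[fg_node])
            partB = engine.partials(P_fg, only_path_from=fg_node, base=base)
            likB = np.maximum(partB[engine.tree] @ cache.pi, 1e-300)
        lnl, _ = engine.loglik([likA, likB], np.array([1.0 - p2, p2]))
        return lnl, likA, likB
    return evaluate


def _fit_baseline(engine, cache, base_len, start=(2.0, 0.3, 1.0)):
    """Single-omega MG94 fit of (kappa, omega, tree scale)."""
    def nll(theta):
        kappa, omega, scale = np.exp(theta)
        model = cache.get(kappa, omega)
        P_map = {n: model.transition_matrix(scale * base_len[n])
                 for n in base_len}
        lik = engine.pattern_likelihoods(P_map, cache.pi)
        return -(np.log(lik) * engine.pattern_counts).sum()

    res = optimize.minimize(
        nll, np.log(np.asarray(start)), method="L-BFGS-B",
        bounds=[(np.log(0.05), np.log(50.0))] * 2 + [(np.log(1e-3), np.log(1e3))],
        options={"maxiter": 200, "ftol": 1e-10})
    kappa, omega, scale = np.exp(res.x)
    return kappa, omega, scale, -res.fun, res.success


_NULL_STARTS = ((0.2, 0.1), (0.6, 0.05), (0.95, 0.3))
_ALT_STARTS = ((0.2, 0.1, 5.0), (0.6, 0.05, 2.0), (0.95, 0.2, 10.0))
_WMAX = 50.0


def fit_branch_site(
    alignment: dict[str, str],
    tree: TreeNode,
    foreground_branch: str,
    pi: np.ndarray | None = None,
    omega1_max: float = 1.0,
    tol: float = 1e-6,
) -> BranchSiteFit:
    """Fit the branch-site alternative and null for one foreground branch.

    ``foreground_branch`` is a leaf name or the 'a|b|c' sorted-leaf
    signature of an internal branch.  Frequencies default to F3x4 from
    the alignment.  Returns the fit with ``converged=False`` (never an
    exception) when any stage reports non-convergence.
    """
    if len(alignment) < 3:
        raise ValueError("need at least three sequences")
    if pi is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi = f3x4_frequencies(alignment)
    engine = PruningEngine(alignment, tree)
    fg_node = None
    for node in engine.nodes:
        if node.parent is not None and branch_label(node) == foreground_branch:
            fg_node = node
            break
    if fg_node is None:
        raise ValueError(f"no branch labelled {foreground_branch!r}")
    base_len = {n: (n.length if n.length and n.length > 0 else 0.05)
                for n in engine.nodes if n.parent is not None}
    cache = _ModelCache(pi)
    kappa, _, scale, _, ok_base = _fit_baseline(engine, cache, base_len)
    scaled_len = {n: scale * v for n, v in base_len.items()}
    objective = _branch_site_objective(engine, cache, fg_node, scaled_len)

    def null_nll(x):
        return -objective(kappa, x[0], 1.0, x[1])[0]

    def alt_nll(x):
        return -objective(kappa, x[0], x[2], x[1])[0]

    bounds_null = [(1e-4, omega1_max), (1e-4, 0.999)]
    best_null = None
    for w1, p2 in _NULL_STARTS:
        res = optimize.minimize(
            null_nll, [min(w1, omega1_max), p2], method="L-BFGS-B",
            bounds=bounds_null, options={"maxiter": 100, "ftol": tol * 1e-2})
        if best_null is None or res.fun < best_null.fun - 1e-12:
            best_null = res
    lnL_null = -best_null.fun
    w1_null, p2_null = best_null.x

    bounds_alt = bounds_null + [(1.0, _WMAX)]
    starts = [np.array([min(w1, omega1_max), p2, w2])
              for w1, p2, w2 in _ALT_STARTS]
    starts.append(np.array([w1_null, p2_null, 1.0]))  # nesting guarantee
    best_alt = None
    for x0 in starts:
        res = optimize.minimize(
            alt_nll, x0, method="L-BFGS-B", bounds=bounds_alt,
            options={"maxiter": 100, "ftol": tol * 1e-2})
        if best_alt is None or res.fun < best_alt.fun - 1e-12:
            best_alt = res
    lnL_alt = -best_alt.fun
    if lnL_alt < lnL_null:  # numerically guarantee nesting
        lnL_alt = lnL_null
        best_alt.x = np.array([w1_null, p2_null, 1.0])
    omega1, p2, omega2 = best_alt.x
    return BranchSiteFit(
        foreground=foreground_branch, kappa=float(kappa),
        omega1=float(omega1), p2=float(p2), omega2=float(omega2),
        lnL_alt=float(lnL_alt), lnL_null=float(lnL_null),
        omega1_null=float(w1_null), p2_null=float(p2_null),
        scale=float(scale),
        converged=bool(ok_base and best_null.success and best_alt.success),
        engine=engine, pi=pi, _cache=cache, _fg_node=fg_node)


# ---------------------------------------------------------------------------
# LRT and corrections
# ---------------------------------------------------------------------------

def lrt_pvalue(LR: float, null: str = "chibar") -> float:
    """P-value of the branch-site LRT.

    ``chibar`` (default): 50:50 mixture of a point mass at zero and
    chi-square with 1 df, the boundary null for omega2 = 1; ``chi2``:
    plain chi-square(1), conservative.
    """
    if LR < -1e-6:
        raise ValueError("negative likelihood ratio")
    LR = max(0.0, LR)
    if null == "chibar":
        return 1.0 if LR == 0.0 else float(0.5 * stats.chi2.sf(LR, df=1))
    if null == "chi2":
        return float(stats.chi2.sf(LR, df=1))
    raise ValueError(f"unknown null {null!r}")


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm-adjusted p-values (FWER control within a gene set)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="holm")[1]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values (FDR control across gene sets)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# site posteriors
# ---------------------------------------------------------------------------

@dataclass
class SitePosterior:
    posterior: np.ndarray  # per codon site, P(omega2 class | data)
    flagged: np.ndarray  # sites with posterior > threshold
    threshold: float
    method: str


def site_posteriors(
    fit: BranchSiteFit,
    threshold: float = 0.95,
    method: str = "neb",
    grid_size: int = 10,
) -> SitePosterior:
    """Per-site posterior membership in the elevated class.

    ``neb``: empirical Bayes at the MLEs.  ``grid``: the posterior is
    averaged over a uniform ``grid_size`` x ``grid_size`` grid on
    (p2, omega2 in [1, 50]), weighting each grid point by its data
    likelihood - a coarse Bayes-empirical-Bayes analogue.
    """
    if not fit.converged:
        raise ValueError("cannot compute posteriors from an unconverged fit")
    engine = fit.engine
    scaled_len = {n: fit.scale * (n.length if n.length and n.length > 0 else 0.05)
                  for n in engine.nodes if n.parent is not None}
    objective = _branch_site_objective(engine, fit._cache, fit._fg_node,
                                       scaled_len)
    if method == "neb":
        _, likA, likB = objective(fit.kappa, fit.omega1, fit.omega2, fit.p2)
        num = fit.p2 * likB
        den = num + (1.0 - fit.p2) * likA
        post = num / den
    elif method == "grid":
        p2_grid = np.linspace(0.5 / grid_size, 1 - 0.5 / grid_size, grid_size)
        w2_grid = np.linspace(1.0, _WMAX, grid_size)
        posts, marg = [], []
        for w2 in w2_grid:
            _, likA, likB = objective(fit.kappa, fit.omega1, w2, 0.5)
            for p2 in p2_grid:
                mix = p2 * likB + (1 - p2) * likA
                lnl = (np.log(np.maximum(mix, 1e-300))
                       * engine.pattern_counts).sum()
                posts.append(p2 * likB / np.maximum(mix, 1e-300))
                marg.append(lnl)
        marg = np.asarray(marg)
        w = np.exp(marg - marg.max())
        w /= w.sum()
        post = np.tensordot(w, np.asarray(posts), axes=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    post_sites = post[engine.pattern_of_site]
    return SitePosterior(posterior=post_sites,
                         flagged=np.nonzero(post_sites > threshold)[0],
                         threshold=threshold, method=method)


# ---------------------------------------------------------------------------
# gene-set scan
# ---------------------------------------------------------------------------

def scan_gene_sets(
    gene_sets: list[dict],
    branches: dict[str, list[str]] | None = None,
    pi: np.ndarray | None = None,
    null: str = "chibar",
    beb_threshold: float = 0.95,
    omega1_max: float = 1.0,
) -> pd.DataFrame:
    """Branch-site scan over gene sets with two-level correction.

    Each gene set is a dict with keys ``name``, ``alignment`` (codon
    dict) and ``tree`` (TreeNode with branch lengths).  By default all
    branches (internal and external, root excluded) are tested;
    ``branches`` restricts the tested branches per set.  Raw LRT
    p-values get Holm correction within each set and
    Benjamini-Hochberg across everything.  Sets failing validation are
    skipped with a logged reason column in the returned attrs.
    """
    rows = []
    skipped = []
    for gs in sorted(gene_sets, key=lambda g: g["name"]):
        name, aln, tree = gs["name"], gs["alignment"], gs["tree"]
        try:
            engine_nodes = [n for n in tree.postorder() if n.parent is not None]
            if branches and name in branches:
                todo = branches[name]
            elif branches and None in branches:
                todo = branches[None]
            else:
                todo = [branch_label(n) for n in engine_nodes]
            fits = []
            for br in todo:
                fit = fit_branch_site(aln, tree, br, pi=pi,
                                      omega1_max=omega1_max)
                p_raw = lrt_pvalue(fit.LR, null=null)
                fits.append((br, fit, p_raw))
        except ValueError as exc:
            skipped.append({"set": name, "reason": str(exc)})
            continue
        p_holm = holm_bonferroni([p for _, _, p in fits])
        for (br, fit, p_raw), ph in zip(fits, p_holm):
            n_flagged = 0
            if fit.converged:
                n_flagged = len(site_posteriors(
                    fit, threshold=beb_threshold).flagged)
            rows.append({
                "set": name, "branch": br, "omega1": round(fit.omega1, 4),
                "p2_pct": round(100.0 * fit.p2, 2),
                "omega2": round(fit.omega2, 4), "LR": round(fit.LR, 4),
                "p_raw": p_raw, "p_holm": ph,
                "converged": fit.converged, "flagged_sites": n_flagged,
            })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_bh"] = benjamini_hochberg(out["p_raw"].to_numpy())
        out = out.sort_values(["set", "branch"]).reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out
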