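"""Rooted trees, newick I/O, and lightweight phylogenetic inference.

The tree container is deliberately small and mutable (parent links,
ordered children) because the simulator, the pruning likelihood, NNI
rearrangement and reconciliation all need to walk and edit it cheaply.
Newick round-trips preserve topology, branch lengths (10 significant
digits) and internal-node labels, which is where bootstrap supports
live by convention.

Tree *search* is intentionally minimal: neighbor joining on
model-corrected distances plus nonparametric bootstrap.  User-supplied
trees are accepted by every downstream stage, so NJ is a convenience,
not a commitment.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import optimize, stats


class NewickError(ValueError):
    """Malformed newick input; message carries the character position."""


class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    # -- structure -----------------------------------------------------
    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def support(self) -> float | None:
        """Internal-node label interpreted as a support value, if numeric."""
        if self.is_leaf or self.label is None:
            return None
        try:
            return float(self.label)
        except ValueError:
            return None

    @support.setter
    def support(self, value: float) -> None:
        self.label = format(float(value), ".10g")

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self):
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> "TreeNode":
        for n in self.postorder():
            if n.label == label:
                return n
        raise KeyError(f"no node labelled {label!r}")

    def copy(self) -> "TreeNode":
        dup = TreeNode(self.label, self.length)
        for child in self.children:
            dup.add_child(child.copy())
        return dup

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<TreeNode {self.label!r} len={self.length}>"


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

_SPECIALS = set("(),:;")


def parse_newick(text: str) -> TreeNode:
    """Parse a newick string into a rooted tree.

    Internal-node labels are kept verbatim (numeric ones double as
    bootstrap supports).  Duplicate leaf labels and unbalanced
    parentheses are rejected with the offending position.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("newick text must end with ';'")
    pos = 0

    def error(msg):
        raise NewickError(f"{msg} at position {pos}")

    def parse_label():
        nonlocal pos
        start = pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            while pos < len(text) and text[pos] != "'":
                pos += 1
            if pos >= len(text):
                error("unterminated quoted label")
            pos += 1
            return text[start + 1:pos - 1]
        while pos < len(text) and text[pos] not in _SPECIALS:
            pos += 1
        return text[start:pos] or None

    def parse_node():
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_node())
                if pos >= len(text):
                    error("unbalanced parentheses")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {text[pos]!r}")
        node.label = parse_label()
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in _SPECIALS:
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                error(f"bad branch length {text[start:pos]!r}")
        return node

    root = parse_node()
    if pos != len(text) - 1 or text[pos] != ";":
        error("trailing characters after tree")
    names = root.leaf_names()
    dup = {n for n in names if names.count(n) > 1}
    if dup:
        raise NewickError(f"duplicate leaf labels: {sorted(dup)}")
    return root


def _fmt_len(x: float) -> str:
    return format(x, ".10g")


def write_newick(root: TreeNode) -> str:
    def render(node):
        if node.is_leaf:
            s = node.label or ""
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.label is not None:
                s += node.label
        if node.length is not None:
            s += ":" + _fmt_len(node.length)
        return s

    return render(root) + ";"


def sorted_newick(root: TreeNode) -> str:
    """Canonical topology-only newick (children sorted by leaf content).

    Used as a deterministic tie-break key and for topology comparisons.
    """
    def render(node):
        if node.is_leaf:
            return node.label or ""
        parts = sorted(render(c) for c in node.children)
        return "(" + ",".join(parts) + ")"

    return render(root) + ";"


# ---------------------------------------------------------------------------
# rooting / bipartitions
# ---------------------------------------------------------------------------

def root_with_outgroup(root: TreeNode, outgroup: str) -> TreeNode:
    """Re-root on the edge leading to a named leaf (length split evenly).

    The tree is copied; degree-two nodes created at the old root are
    suppressed (their lengths summed).
    """
    tree = root.copy()
    og = tree.find(outgroup)
    if og.parent is None:
        raise ValueError("outgroup is already the root")
    # reverse parent links from og's parent up to the old root
    path = []
    node = og.parent
    while node is not None:
        path.append(node)
        node = node.parent
    new_root = TreeNode()
    half = (og.length / 2.0) if og.length is not None else None
    og_parent = path[0]
    og_parent.children.remove(og)
    og.length = half
    new_root.add_child(og)
    # rehang: walk up the old path, flipping each edge
    prev = new_root
    carry_len = half
    for i, node in enumerate(path):
        nxt = path[i + 1] if i + 1 < len(path) else None
        if nxt is not None:
            nxt.children.remove(node)
        edge_len = node.length
        node.length = carry_len
        node.parent = None
        prev.add_child(node)
        carry_len = edge_len
        prev = node
    # suppress a degree-one former root
    for node in list(new_root.postorder()):
        if not node.is_leaf and len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            node.parent.children[node.parent.children.index(node)] = child
            child.parent = node.parent
    return new_root


def prune_to_leaves(root: TreeNode, keep: set[str]) -> TreeNode:
    """Copy of the tree restricted to the named leaves.

    Dropped leaves are removed, childless internals pruned, and unary
    nodes suppressed with their lengths summed.
    """
    tree = root.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if node is tree:
                continue
            if (node.is_leaf and node.label not in keep) or (
                    not node.is_leaf and not node.children):
                node.parent.children.remove(node)
                changed = True
    for node in list(tree.postorder()):
        if node is tree or node.is_leaf:
            continue
        if len(node.children) == 1:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            node.parent.children[node.parent.children.index(node)] = child
            child.parent = node.parent
    while len(tree.children) == 1 and not tree.children[0].is_leaf:
        tree = tree.children[0]
        tree.parent = None
        tree.length = None
    return tree


def bipartitions(root: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each as the canonical smaller side."""
    all_leaves = frozenset(root.leaf_names())
    out = set()
    for node in root.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


# ---------------------------------------------------------------------------
# discrete gamma
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaCategories:
    """Equal-probability discretization of a mean-one gamma rate law."""
    shape: float
    rates: tuple[float, ...] = field(default=())

    @property
    def k(self) -> int:
        return len(self.rates)


def discrete_gamma(alpha: float, k: int = 5) -> GammaCategories:
    """Mean-one gamma rates discretized into k equal-probability classes.

    Each class rate is the conditional mean of the gamma density on its
    quantile interval, so the category mean is exactly one after the
    final renormalization.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X ; a < X < b] for X~Gamma(alpha, 1/alpha) is the CDF of
    # Gamma(alpha+1, 1/alpha) evaluated on the interval (mean is 1)
    upper = stats.gamma.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(upper)
    rates = rates / rates.mean()
    return GammaCategories(shape=alpha, rates=tuple(rates))


# ---------------------------------------------------------------------------
# JTT model and ML distances
# ---------------------------------------------------------------------------

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


def _load_jtt_raw():
    with resources.files("chemevol.data").joinpath("jtt.json").open() as fh:
        return json.load(fh)


def jtt_model() -> tuple[np.ndarray, np.ndarray]:
    """JTT generator Q (20x20, mean rate one) and stationary frequencies."""
    raw = _load_jtt_raw()
    tri = raw["lower_triangle_colmajor"]
    freqs = np.asarray(raw["frequencies"], float)
    n = 20
    S = np.zeros((n, n))
    it = iter(tri)
    for j in range(n):
        for i in range(j + 1, n):
            S[i, j] = S[j, i] = next(it)
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(freqs * np.diag(Q)).sum()
    return Q / rate, freqs


def _jtt_eigen():
    Q, pi = jtt_model()
    half = np.sqrt(pi)
    sym = (half[:, None] * Q) / half[None, :]
    vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
    left = vecs.T * half[None, :]
    right = vecs / half[:, None]
    return vals, right, left, pi


_JTT_EIGEN_CACHE: tuple | None = None


def jtt_transition_matrix(t: float) -> np.ndarray:
    global _JTT_EIGEN_CACHE
    if _JTT_EIGEN_CACHE is None:
        _JTT_EIGEN_CACHE = _jtt_eigen()
    vals, right, left, _ = _JTT_EIGEN_CACHE
    return (right * np.exp(vals * t)[None, :]) @ left


def jtt_ml_distance(
    seq_a: str,
    seq_b: str,
    gamma: GammaCategories | None = None,
    max_distance: float = 10.0,
) -> float:
    """One-parameter ML distance between aligned proteins under JTT(+G).

    Gap-containing columns are removed (complete deletion) before
    fitting.  The estimate is capped at ``max_distance``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    idx = {a: i for i, a in enumerate(AA_ORDER)}
    pairs = {}
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in idx and b in idx:
            pairs[(idx[a], idx[b])] = pairs.get((idx[a], idx[b]), 0) + 1
    if not pairs:
        raise ValueError("no shared ungapped columns")
    global _JTT_EIGEN_CACHE
    if _JTT_EIGEN_CACHE is None:
        _JTT_EIGEN_CACHE = _jtt_eigen()
    vals, right, left, pi = _JTT_EIGEN_CACHE
    rates = gamma.rates if gamma is not None else (1.0,)
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    counts = np.array(list(pairs.values()), float)
    if np.all(ii == jj):
        return 0.0

    def neg_loglik(t):
        like = np.zeros(len(counts))
        for r in rates:
            P = (right * np.exp(vals * r * t)[None, :]) @ left
            like += np.maximum(P[ii, jj], 1e-300) / len(rates)
        return -(counts * np.log(pi[ii] * like)).sum()

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(1e-9, max_distance), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(min(res.x, max_distance))


# ---------------------------------------------------------------------------
# neighbor joining and bootstrap
# ---------------------------------------------------------------------------

def nj_tree(distance_matrix: np.ndarray, labels: list[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths are clamped to zero with a warning.  The
    returned tree carries the conventional unrooted representation
    (trifurcating root).
    """
    D = np.asarray(distance_matrix, float)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise ValueError("matrix/labels size mismatch")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    sk = _skbio_nj(DistanceMatrix((D + D.T) / 2.0, ids=list(labels)))
    tree = parse_newick(str(sk))
    clamped = False
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to zero")
    return tree


def bootstrap_support(
    alignment: dict[str, str],
    builder,
    n_reps: int,
    seed: int,
) -> TreeNode:
    """Attach bootstrap supports to the tree built from the full alignment.

    ``builder`` maps an alignment dict to a TreeNode; columns are
    resampled with replacement per replicate and support is the
    fraction of replicates whose tree contains each bipartition.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    names = list(alignment)
    ncol = len(alignment[names[0]])
    if ncol < 2:
        raise ValueError("alignment must have at least two columns")
    tree = builder(alignment)
    target = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_aln = {n: "".join(alignment[n][c] for c in cols) for n in names}
        rep_bps = bipartitions(builder(rep_aln))
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
    all_leaves = frozenset(tree.leaf_names())
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        canon = min(side, all_leaves - side,
                    key=lambda s: (len(s), tuple(sorted(s))))
        if canon in target:
            node.support = target[canon] / n_reps
    return tree


def jtt_distance_matrix(
    alignment: dict[str, str], gamma: GammaCategories | None = None
) -> tuple[np.ndarray, list[str]]:
    """Pairwise JTT(+G) ML distances for a protein alignment."""
    names = list(alignment)
    n = len(names)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = jtt_ml_distance(
            alignment[names[i]], alignment[names[j]], gamma=gamma
        )
    return D, names
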