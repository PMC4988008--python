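"""Parsimony gene-tree / species-tree reconciliation.

LCA mapping gives the unique reconciliation minimizing duplications
and losses simultaneously; with the weighted scheme used here
(duplication 1.5, loss 1.0) it therefore also minimizes total cost.
Weakly supported gene-tree edges (bootstrap below a threshold,
default 0.9) may additionally be rearranged by NNI moves when that
lowers the reconciliation cost - a desk-scale rendition of
rearrangement-mode reconciliation.  Non-binary input trees are
rejected rather than resolved silently.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .trees import TreeNode, sorted_newick


@dataclass(frozen=True)
class CostScheme:
    dup_cost: float = 1.5
    loss_cost: float = 1.0
    support_threshold: float = 0.9

    def __post_init__(self):
        if self.dup_cost <= 0 or self.loss_cost <= 0:
            raise ValueError("costs must be positive")
        if not 0.0 <= self.support_threshold <= 1.0:
            raise ValueError("support threshold must be in [0, 1]")


@dataclass
class ReconciledTree:
    """A gene tree with its species mapping and event annotation."""

    gene_tree: TreeNode
    species_tree: TreeNode
    mapping: dict = field(repr=False, default_factory=dict)
    events: dict = field(repr=False, default_factory=dict)
    losses: dict = field(repr=False, default_factory=dict)  # gene node -> int
    scheme: CostScheme = field(default_factory=CostScheme)

    @property
    def n_duplications(self) -> int:
        return sum(1 for v in self.events.values() if v == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    @property
    def cost(self) -> float:
        return (self.scheme.dup_cost * self.n_duplications
                + self.scheme.loss_cost * self.n_losses)

    def annotated_newick(self) -> str:
        """Newick with NHX-style event comments on internal nodes."""
        def render(node):
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")"
                s += node.label or ""
            if node.length is not None:
                s += f":{node.length:.10g}"
            ev = self.events.get(node)
            if ev:
                s += f"[&&NHX:Ev={'D' if ev == 'duplication' else 'S'}]"
            return s
        return render(self.gene_tree) + ";"


def default_species_map(gene_tree: TreeNode) -> dict[str, str]:
    """Leaf name -> species under the '<species>_<copy>' convention."""
    return {name: name.rsplit("_", 1)[0] for name in gene_tree.leaf_names()}


def _check_binary(tree: TreeNode, what: str) -> None:
    if not tree.is_binary():
        raise ValueError(f"{what} must be binary (no branches are collapsed "
                         "or resolved silently)")


def lca_map(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    leaf_species_map: dict[str, str] | None = None,
) -> dict[TreeNode, TreeNode]:
    """Map every gene-tree node to the LCA of its descendants' species."""
    _check_binary(gene_tree, "gene tree")
    _check_binary(species_tree, "species tree")
    if leaf_species_map is None:
        leaf_species_map = default_species_map(gene_tree)
    sp_by_name = {leaf.label: leaf for leaf in species_tree.leaves()}
    depth: dict[TreeNode, int] = {}
    for node in species_tree.preorder():
        depth[node] = 0 if node.parent is None else depth[node.parent] + 1

    def lca(a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if depth[a] < depth[b]:
                b = b.parent
            elif depth[a] > depth[b]:
                a = a.parent
            else:
                a, b = a.parent, b.parent
        return a

    mapping: dict[TreeNode, TreeNode] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            sp = leaf_species_map.get(node.label)
            if sp is None or sp not in sp_by_name:
                raise ValueError(f"gene leaf {node.label!r} has no species mapping")
            mapping[node] = sp_by_name[sp]
        else:
            m = mapping[node.children[0]]
            for child in node.children[1:]:
                m = lca(m, mapping[child])
            mapping[node] = m
    return mapping


def annotate_events(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    mapping: dict[TreeNode, TreeNode],
    scheme: CostScheme | None = None,
) -> ReconciledTree:
    """Label duplications/speciations and count losses per gene edge.

    A node is a duplication iff it maps to the same species node as one
    of its children.  Losses on the edge (u, v) follow the path-depth
    rule: depth(M(v)) - depth(M(u)), minus one when u is a speciation
    (the speciation itself accounts for one step down).
    """
    scheme = scheme or CostScheme()
    depth: dict[TreeNode, int] = {}
    for node in species_tree.preorder():
        depth[node] = 0 if node.parent is None else depth[node.parent] + 1
    events: dict[TreeNode, str] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        if any(mapping[c] is mapping[node] for c in node.children):
            events[node] = "duplication"
        else:
            events[node] = "speciation"
    losses: dict[TreeNode, int] = {}
    for node in gene_tree.postorder():
        if node.parent is None:
            continue
        d = depth[mapping[node]] - depth[mapping[node.parent]]
        if events[node.parent] == "speciation":
            d -= 1
        if d > 0:
            losses[node] = d
    return ReconciledTree(gene_tree=gene_tree, species_tree=species_tree,
                          mapping=mapping, events=events, losses=losses,
                          scheme=scheme)


def reconcile(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    leaf_species_map: dict[str, str] | None = None,
    scheme: CostScheme | None = None,
) -> ReconciledTree:
    """LCA reconciliation of a gene tree against a species tree."""
    mapping = lca_map(gene_tree, species_tree, leaf_species_map)
    return annotate_events(gene_tree, species_tree, mapping, scheme)


# ---------------------------------------------------------------------------
# NNI rearrangement of weak edges
# ---------------------------------------------------------------------------

def _weak_internal_edges(tree: TreeNode, threshold: float) -> list[TreeNode]:
    """Internal nodes whose parent edge has support below the threshold."""
    out = []
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        sup = node.support
        if sup is not None and sup < threshold:
            out.append(node)
    return out


def _nni_variants(tree: TreeNode, threshold: float):
    """All trees one NNI move away on a weakly supported edge."""
    # identify weak nodes by their postorder index so moves can be
    # replayed on copies
    order = list(tree.postorder())
    weak_idx = [i for i, n in enumerate(order)
                if n in set(_weak_internal_edges(tree, threshold))]
    for idx in weak_idx:
        for variant in (0, 1):
            dup = tree.copy()
            dup_order = list(dup.postorder())
            v = dup_order[idx]
            u = v.parent
            sibling = next(c for c in u.children if c is not v)
            child = v.children[variant]
            # swap sibling <-> child
            u.children[u.children.index(sibling)] = child
            v.children[variant] = sibling
            child.parent, sibling.parent = u, v
            yield dup


def rearrange_weak_edges(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    scheme: CostScheme | None = None,
    leaf_species_map: dict[str, str] | None = None,
    max_trees: int = 500,
) -> tuple[TreeNode, ReconciledTree]:
    """Search NNI moves on weakly supported edges for a cheaper reconciliation.

    Explores topologies reachable through sequences of NNI moves
    restricted to edges with bootstrap support below the scheme's
    threshold (best-first, capped at ``max_trees`` distinct
    topologies).  Returns the minimum-cost tree; ties break on the
    lexicographically smallest sorted newick so re-runs are stable.
    The input tree is returned unchanged when already minimal.
    """
    scheme = scheme or CostScheme()
    if leaf_species_map is None:
        leaf_species_map = default_species_map(gene_tree)

    def cost_of(tree):
        return reconcile(tree, species_tree, leaf_species_map, scheme)

    start_key = sorted_newick(gene_tree)
    best_tree, best_rec = gene_tree, cost_of(gene_tree)
    best_key = start_key
    seen = {start_key}
    frontier = [(best_rec.cost, start_key, gene_tree)]
    while frontier and len(seen) < max_trees:
        _, _, tree = heapq.heappop(frontier)
        for cand in _nni_variants(tree, scheme.support_threshold):
            key = sorted_newick(cand)
            if key in seen:
                continue
            seen.add(key)
            rec = cost_of(cand)
            if (rec.cost, key) < (best_rec.cost, best_key):
                best_tree, best_rec, best_key = cand, rec, key
            heapq.heappush(frontier, (rec.cost, key, cand))
    return best_tree, best_rec


# ---------------------------------------------------------------------------
# ancestral copy numbers
# ---------------------------------------------------------------------------

def infer_gains_losses(
    copy_numbers: dict[str, int],
    species_tree: TreeNode,
) -> tuple[dict[TreeNode, int], dict[TreeNode, int]]:
    """Minimum-change integer ancestral copy numbers (Sankoff, unit cost).

    ``copy_numbers`` maps species leaf name -> observed count.  Returns
    (ancestral count per node, per-branch delta child - parent).  Ties
    resolve to the smallest state, making the output deterministic.
    """
    for leaf in species_tree.leaves():
        if leaf.label not in copy_numbers:
            raise ValueError(f"no copy number for species {leaf.label!r}")
        if copy_numbers[leaf.label] < 0:
            raise ValueError("copy numbers must be non-negative")
    max_state = max(copy_numbers.values())
    states = list(range(max_state + 1))
    INF = float("inf")
    cost: dict[TreeNode, list[float]] = {}
    for node in species_tree.postorder():
        if node.is_leaf:
            obs = copy_numbers[node.label]
            cost[node] = [0.0 if s == obs else INF for s in states]
        else:
            cost[node] = [
                sum(min(cost[c][t] + abs(s - t) for t in states)
                    for c in node.children)
                for s in states
            ]
    assign: dict[TreeNode, int] = {}
    root = species_tree
    assign[root] = min(states, key=lambda s: (cost[root][s], s))
    for node in root.preorder():
        for child in node.children:
            s = assign[node]
            assign[child] = min(
                states, key=lambda t: (cost[child][t] + abs(s - t), t))
    deltas = {node: assign[node] - assign[node.parent]
              for node in root.preorder() if node.parent is not None}
    return assign, deltas
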