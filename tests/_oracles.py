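"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive - exhaustive enumeration, direct
dynamic programming, closed forms - and shares no code with the
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

STOPS = set(standard_dna_table.stop_codons)
AA = dict(standard_dna_table.forward_table)
SENSE = sorted(AA)


# ---------------------------------------------------------------------------
# NG86 by enumeration
# ---------------------------------------------------------------------------

def ng86_sites_enum(codon: str) -> tuple[float, float]:
    """Site counts by explicit neighbour enumeration."""
    s = n = 0.0
    for pos in range(3):
        syn = non = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut in STOPS:
                continue
            if AA[mut] == AA[codon]:
                syn += 1
            else:
                non += 1
        tot = syn + non
        if tot:
            s += syn / tot
            n += non / tot
    return s, n


def ng86_pathways_enum(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged difference counts by explicit path enumeration."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            steps.append(AA[cur] == AA[nxt])
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return float("nan"), float("nan")
    sd = sum(sum(p) for p in paths) / len(paths)
    nd = sum(len(p) - sum(p) for p in paths) / len(paths)
    return sd, nd


# ---------------------------------------------------------------------------
# Wilcoxon by full enumeration
# ---------------------------------------------------------------------------

def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def signed_rank_enum(diffs) -> tuple[float, float]:
    """(W, two-sided p) over all 2^n sign vectors, midranks, zeros dropped."""
    d = [x for x in diffs if x != 0]
    if not d:
        return 0.0, 1.0
    ranks = _midranks([abs(x) for x in d])
    w_plus = sum(r for x, r in zip(d, ranks) if x > 0)
    total = sum(ranks)
    n = len(d)
    lo = hi = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_plus + 1e-9:
            lo += 1
        if w >= w_plus - 1e-9:
            hi += 1
    denom = 2 ** n
    p = min(1.0, 2.0 * min(lo / denom, hi / denom))
    return min(w_plus, total - w_plus), p


def rank_sum_enum(a, b) -> tuple[float, float]:
    """(U, two-sided p) over all C(m+n, m) group assignments."""
    m = len(a)
    combined = list(a) + list(b)
    ranks = _midranks(combined)
    ra = sum(ranks[:m])
    u_a = ra - m * (m + 1) / 2.0
    u_b = m * len(b) - u_a
    lo = hi = tot = 0
    for idx in itertools.combinations(range(len(combined)), m):
        r = sum(ranks[i] for i in idx)
        tot += 1
        if r <= ra + 1e-9:
            lo += 1
        if r >= ra - 1e-9:
            hi += 1
    p = min(1.0, 2.0 * min(lo / tot, hi / tot))
    return min(u_a, u_b), p


# ---------------------------------------------------------------------------
# affine-gap global alignment score by direct DP (Gotoh)
# ---------------------------------------------------------------------------

def global_align_score(a: str, b: str, matrix, open_cost=10.0, extend_cost=1.0):
    """Best global alignment score; first gap position costs ``open_cost``,
    each further position ``extend_cost`` (matching Biopython's
    open/extend convention)."""
    NEG = -1e30
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, lb + 1):
        Y[0][j] = -open_cost - (j - 1) * extend_cost
    for i in range(la + 1):
        for j in range(lb + 1):
            if i > 0 and j > 0:
                s = matrix[a[i - 1], b[j - 1]]
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s
            if i > 0 and (i, j) != (1, 0):
                X[i][j] = max(X[i][j],
                              M[i - 1][j] - open_cost,
                              X[i - 1][j] - extend_cost,
                              Y[i - 1][j] - open_cost)
            if j > 0 and (i, j) != (0, 1):
                Y[i][j] = max(Y[i][j],
                              M[i][j - 1] - open_cost,
                              Y[i][j - 1] - extend_cost,
                              X[i][j - 1] - open_cost)
    return max(M[la][lb], X[la][lb], Y[la][lb])


# ---------------------------------------------------------------------------
# reconciliation by brute force over all valid mappings
# ---------------------------------------------------------------------------

def reconcile_brute_force(gene_tree, species_tree, leaf_map):
    """Minimum (duplications, losses) over all ancestrally consistent maps.

    ``gene_tree``/``species_tree`` are chemevol TreeNodes; ``leaf_map``
    maps gene leaf label -> species leaf label.  For an arbitrary valid
    map, a node is a speciation iff its children map into distinct
    child subtrees of its own image; losses follow the path-depth rule
    per event type.  Returns the (dup + 1e-9-lexicographic) minimum as
    (n_dup, n_loss, weighted_cost_min) with dup cost 1.5 / loss 1.0.
    """
    sp_nodes = list(species_tree.postorder())
    depth = {}
    for node in species_tree.preorder():
        depth[node] = 0 if node.parent is None else depth[node.parent] + 1

    def is_ancestor(a, b):  # a ancestor-or-equal of b
        while b is not None:
            if b is a:
                return True
            b = b.parent
        return False

    def child_subtree(sp, target):
        for c in sp.children:
            if is_ancestor(c, target):
                return c
        return None

    gene_nodes = [n for n in gene_tree.postorder()]
    internals = [n for n in gene_nodes if not n.is_leaf]
    fixed = {}
    sp_by_label = {l.label: l for l in species_tree.leaves()}
    for n in gene_nodes:
        if n.is_leaf:
            fixed[n] = sp_by_label[leaf_map[n.label]]

    best = None
    for combo in itertools.product(sp_nodes, repeat=len(internals)):
        mapping = dict(fixed)
        mapping.update(dict(zip(internals, combo)))
        ok = True
        for n in internals:
            for c in n.children:
                if not is_ancestor(mapping[n], mapping[c]):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        n_dup = n_loss = 0
        for n in internals:
            img = mapping[n]
            subs = [child_subtree(img, mapping[c]) if mapping[c] is not img
                    else None for c in n.children]
            speciation = (None not in subs and subs[0] is not subs[1]
                          if len(subs) == 2 else False)
            if not speciation:
                n_dup += 1
            for c in n.children:
                d = depth[mapping[c]] - depth[img]
                if speciation:
                    d -= 1
                n_loss += max(0, d)
        cost = 1.5 * n_dup + 1.0 * n_loss
        if best is None or cost < best[2]:
            best = (n_dup, n_loss, cost)
    return best


# ---------------------------------------------------------------------------
# pruning likelihood by exhaustive state enumeration
# ---------------------------------------------------------------------------

def loglik_enum(tree, leaf_states_per_site, P_of_node, pi):
    """Log-likelihood by summing over all internal-state combinations.

    ``leaf_states_per_site`` is {leaf label: [state per site]};
    ``P_of_node`` maps each non-root TreeNode to its transition matrix.
    """
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = [n for n in tree.postorder() if n.is_leaf]
    n_states = len(pi)
    n_sites = len(next(iter(leaf_states_per_site.values())))
    total = 0.0
    for site in range(n_sites):
        like = 0.0
        for combo in itertools.product(range(n_states), repeat=len(internals)):
            assign = dict(zip(internals, combo))
            for leaf in leaves:
                assign[leaf] = leaf_states_per_site[leaf.label][site]
            term = pi[assign[tree]]
            for node in tree.postorder():
                if node is tree:
                    continue
                term *= P_of_node[node][assign[node.parent], assign[node]]
            like += term
        total += np.log(like)
    return total


# ---------------------------------------------------------------------------
# multiple-testing corrections by direct formula
# ---------------------------------------------------------------------------

def holm_enum(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def bh_enum(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, m * pvals[i] / (rank + 1))
        adj[i] = min(1.0, running)
    return adj
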