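"""Synthetic gene families with known ground truth.

Three generators, mirroring what a chemoreceptor-family study needs to
exercise downstream code without any genome downloads:

* a Gillespie birth-death-pseudogenization process embedded in a species
  tree (gene trees with duplication/speciation labels, per-edge losses,
  pseudogene leaves);
* codon alignments evolved along those gene trees under MG94xHKY with a
  site-class omega mixture, optionally with an elevated-omega class
  restricted to designated foreground branches (episodic selection);
* disruptive lesions (start-codon loss, premature stops, frameshifts)
  injected into intact coding sequences, with the true fraction of the
  protein lost.

Everything is driven by explicit integer seeds; identical config and
seed give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codonmodel import CodonModel, build_mg94, mg94_flux, validate_codon_freqs
from .codons import SENSE_CODONS, STOP_CODONS
from .trees import TreeNode, parse_newick

#: nine-species melanogaster-group-like framework used throughout the
#: examples and calibration runs: the melanogaster subgroup (Dmel, Dsim,
#: Dsec, Dyak, Dere), the suzukii-takahashii clade (Dsuz, Dbia, Dtak)
#: and Dana as the most distant member; lengths in expected
#: substitutions per codon site
#: lengths are calibrated so the suzukii-melanogaster path is ~0.9
#: expected substitutions per codon, matching the synonymous-rate scale
#: (dS close to 1) typical of chemoreceptor comparisons across the group
DEFAULT_SPECIES_TREE = (
    "((((Dmel:0.18,(Dsim:0.09,Dsec:0.09):0.09):0.12,"
    "(Dyak:0.21,Dere:0.21):0.09):0.15,"
    "((Dsuz:0.21,Dbia:0.21):0.09,Dtak:0.30):0.15):0.30,Dana:0.75);"
)


@dataclass
class SimConfig:
    """Configuration for the family/alignment simulator.

    Rates are events per gene lineage per unit branch length; branch
    lengths are expected substitutions per codon site under the
    branch's own model.  ``site_classes`` is a list of (proportion,
    omega); when ``foreground_branches`` is non-empty the *last* class
    is the elevated one - sites assigned to it evolve with its omega on
    foreground branches and with the first class's omega elsewhere
    (the classic branch-site arrangement).
    """

    seed: int
    species_tree: str = DEFAULT_SPECIES_TREE
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    pseudo_rate: float = 0.0
    n_codons: int = 300
    kappa: float = 2.0
    site_classes: tuple = ((1.0, 0.2),)
    foreground_branches: tuple = ()
    codon_freqs: np.ndarray | None = None

    def __post_init__(self):
        props = [p for p, _ in self.site_classes]
        if abs(sum(props) - 1.0) > 1e-12:
            raise ValueError("site-class proportions must sum to 1")
        if any(p < 0 for p in props):
            raise ValueError("site-class proportions must be non-negative")
        if any(w < 0 for _, w in self.site_classes):
            raise ValueError("omega must be non-negative")
        for r in (self.dup_rate, self.loss_rate, self.pseudo_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.codon_freqs is None:
            self.codon_freqs = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
        self.codon_freqs = validate_codon_freqs(self.codon_freqs)


@dataclass
class GeneFamilyTruth:
    """Ground truth for one simulated gene-family history."""

    gene_tree: TreeNode | None
    species_tree: TreeNode
    events: dict = field(default_factory=dict)  # gene node -> label
    losses: dict = field(default_factory=dict)  # species edge id -> count
    pseudogene_leaves: set = field(default_factory=set)
    #: per gene-tree edge (keyed by child node): list of
    #: (length, neutral) segments from parent to child
    edge_segments: dict = field(default_factory=dict)

    @property
    def n_duplications(self) -> int:
        return sum(1 for v in self.events.values() if v == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    def copies_per_species(self) -> dict[str, int]:
        out: dict[str, int] = {}
        if self.gene_tree is not None:
            for name in self.gene_tree.leaf_names():
                sp = name.rsplit("_", 1)[0]
                out[sp] = out.get(sp, 0) + 1
        return out


def _species_edge_id(node: TreeNode) -> str:
    return node.label or "|".join(sorted(node.leaf_names()))


def simulate_gene_family(
    species_tree: TreeNode | str,
    dup_rate: float,
    loss_rate: float,
    pseudo_rate: float,
    seed: int,
) -> GeneFamilyTruth:
    """Evolve one gene family along a species tree.

    A single gene enters at the root; along every species-tree branch
    each gene lineage duplicates, dies, or pseudogenizes with
    exponential waiting times (Gillespie).  Pseudogenized copies are
    retained as vestiges (neutral evolution thereafter) rather than
    deleted.  Returns the embedded gene tree plus full event truth;
    ``gene_tree`` is None if the family went extinct.
    """
    if isinstance(species_tree, str):
        species_tree = parse_newick(species_tree)
    leaves = species_tree.leaves()
    if len(leaves) < 2:
        raise ValueError("species tree needs at least two leaves")
    if not species_tree.is_binary():
        raise ValueError("species tree must be binary")
    for node in species_tree.postorder():
        if node.parent is not None and (node.length is None or node.length <= 0):
            raise ValueError("species tree branches must have positive lengths")
    for r in (dup_rate, loss_rate, pseudo_rate):
        if r < 0:
            raise ValueError("rates must be non-negative")

    rng = np.random.default_rng(seed)
    truth = GeneFamilyTruth(gene_tree=None, species_tree=species_tree)
    segments: dict[TreeNode, list] = {}

    def descend(parent_gnode: TreeNode, species_node: TreeNode,
                t_left: float, pseudo: bool) -> None:
        """Run one gene lineage down a species branch from a parent node."""
        gnode = parent_gnode.add_child(TreeNode(length=0.0))
        segs: list[list] = []

        def push(length, is_neutral):
            if length <= 0:
                return
            if segs and segs[-1][1] == is_neutral:
                segs[-1][0] += length
            else:
                segs.append([length, is_neutral])
            gnode.length += length

        while True:
            rate = dup_rate + loss_rate + (0.0 if pseudo else pseudo_rate)
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if wait >= t_left:
                push(t_left, pseudo)
                segments[gnode] = segs
                if species_node.is_leaf:
                    gnode.label = f"__leaf__{species_node.label}"
                    if pseudo:
                        truth.pseudogene_leaves.add(gnode)
                else:
                    truth.events[gnode] = "speciation"
                    for child_sp in species_node.children:
                        descend(gnode, child_sp, child_sp.length, pseudo)
                return
            push(wait, pseudo)
            t_left -= wait
            p_stop = 0.0 if pseudo else pseudo_rate
            u = rng.random() * (dup_rate + loss_rate + p_stop)
            if u < dup_rate:
                truth.events[gnode] = "duplication"
                segments[gnode] = segs
                descend(gnode, species_node, t_left, pseudo)
                descend(gnode, species_node, t_left, pseudo)
                return
            if u < dup_rate + loss_rate:
                eid = _species_edge_id(species_node)
                truth.losses[eid] = truth.losses.get(eid, 0) + 1
                segments[gnode] = segs
                parent_gnode.children.remove(gnode)
                return
            pseudo = True

    root = TreeNode()
    if species_tree.children:
        truth.events[root] = "speciation"
        for child_sp in species_tree.children:
            descend(root, child_sp, child_sp.length, False)

    # prune lineages that left no descendants, then suppress unary nodes
    changed = True
    while changed:
        changed = False
        for node in list(root.postorder()):
            if node is root:
                continue
            if not node.is_leaf and not node.children:
                node.parent.children.remove(node)
                truth.events.pop(node, None)
                changed = True
    for node in list(root.postorder()):
        if node is root or node.is_leaf:
            continue
        if len(node.children) == 1:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            segments[child] = segments.get(node, []) + segments.get(child, [])
            node.parent.children[node.parent.children.index(node)] = child
            child.parent = node.parent
            truth.events.pop(node, None)
    while len(root.children) == 1 and not root.children[0].is_leaf:
        old = root.children[0]
        segments.pop(old, None)
        old.parent = None
        old.length = None
        root = old

    if not root.children and root.label is None:
        return truth  # extinct family

    # name leaves <species>_<copy#> in deterministic traversal order
    counters: dict[str, int] = {}
    pseudo_names = set()
    for leaf in root.leaves():
        sp = (leaf.label or "").replace("__leaf__", "")
        counters[sp] = counters.get(sp, 0) + 1
        leaf.label = f"{sp}_{counters[sp]}"
        if leaf in truth.pseudogene_leaves:
            pseudo_names.add(leaf.label)
    truth.pseudogene_leaves = pseudo_names
    truth.gene_tree = root
    truth.edge_segments = {
        n: [tuple(s) for s in segments.get(n, [[n.length or 0.0, False]])]
        for n in root.postorder() if n is not root
    }
    return truth


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

def _sample_children(P: np.ndarray, parents: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw one child state per site from the rows of P given parents."""
    probs = P[parents]
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random((len(parents), 1))
    return (probs.cumsum(axis=1) < u).sum(axis=1).astype(np.int64)


def evolve_codons(
    gene_tree: TreeNode,
    config: SimConfig,
    truth: GeneFamilyTruth | None = None,
    seed: int | None = None,
) -> tuple[dict[str, str], np.ndarray]:
    """Evolve a gap-free codon alignment along a gene tree.

    Returns (alignment, site_class): one row per leaf, plus the true
    class index of every codon site.  Sites in the elevated (last)
    class use its omega only on branches named in
    ``config.foreground_branches`` (branch = label of its child node);
    elsewhere they fall back to the first class's omega.  Edges of
    pseudogenized lineages (from ``truth.edge_segments``) evolve
    neutrally (omega = 1) over their neutral segments.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_sites = config.n_codons
    classes = list(config.site_classes)
    props = np.array([p for p, _ in classes])
    omegas = [w for _, w in classes]
    has_fg = bool(config.foreground_branches) and len(classes) > 1
    site_class = rng.choice(len(classes), size=n_sites, p=props / props.sum())

    # shared clock: every constrained class is normalized by the flux of
    # the *background* mixture, so branch lengths are expected
    # substitutions per codon on background branches and elevated-omega
    # sites evolve proportionally faster on foreground branches
    bg_omegas = [omegas[0] if (has_fg and ci == len(classes) - 1) else omegas[ci]
                 for ci in range(len(classes))]
    flux_bg = sum(p * mg94_flux(config.kappa, w, config.codon_freqs)
                  for (p, _), w in zip(classes, bg_omegas))
    models: dict[tuple, CodonModel] = {}

    def model_for(w: float, neutral: bool = False) -> CodonModel:
        key = (w, neutral)
        if key not in models:
            models[key] = build_mg94(
                config.kappa, w, config.codon_freqs,
                rate_scale=None if neutral else flux_bg)
        return models[key]

    root_state = rng.choice(len(SENSE_CODONS), size=n_sites, p=config.codon_freqs)
    states: dict[TreeNode, np.ndarray] = {gene_tree: root_state}
    fg = set(config.foreground_branches)

    for node in gene_tree.preorder():
        if node is gene_tree:
            continue
        parent_state = states[node.parent]
        branch_is_fg = (
            (node.label in fg) or (_branch_name(node) in fg)
            or (node.is_leaf and node.label
                and node.label.rsplit("_", 1)[0] in fg))
        if truth is not None and node in truth.edge_segments:
            segs = truth.edge_segments[node]
        else:
            segs = [(node.length or 0.0, False)]
        state = parent_state
        for seg_len, neutral in segs:
            if seg_len <= 0:
                continue
            state = state.copy()
            for ci in range(len(classes)):
                sites = np.nonzero(site_class == ci)[0]
                if not len(sites):
                    continue
                if neutral:
                    w = 1.0
                elif has_fg and ci == len(classes) - 1 and not branch_is_fg:
                    w = omegas[0]
                else:
                    w = omegas[ci]
                P = model_for(w, neutral=neutral).transition_matrix(seg_len)
                state[sites] = _sample_children(P, state[sites], rng)
        states[node] = state

    alignment = {
        leaf.label: "".join(SENSE_CODONS[s] for s in states[leaf])
        for leaf in gene_tree.leaves()
    }
    return alignment, site_class


def _branch_name(node: TreeNode) -> str:
    return node.label or "|".join(sorted(node.leaf_names()))


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionTruth:
    kind: str
    position: int  # codon index
    fraction_lost: float


_LESION_KINDS = ("start_loss", "premature_stop", "frameshift")


def inject_lesion(
    cds: str, kind: str, position: int, seed: int = 0
) -> tuple[str, LesionTruth]:
    """Disable an intact CDS with one lesion and report the truth.

    ``fraction_lost`` is the fraction of the reference protein missing
    after translating the lesioned sequence to its first stop, using
    the same next-in-frame-ATG rescue convention as the classifier.
    """
    cds = cds.upper()
    if kind not in _LESION_KINDS:
        raise ValueError(f"unknown lesion kind {kind!r}")
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons[0] != "ATG":
        raise ValueError("CDS must begin with ATG")
    if codons[-1] not in STOP_CODONS:
        raise ValueError("CDS must end with a stop codon")
    if any(c in STOP_CODONS for c in codons[:-1]):
        raise ValueError("CDS has an internal stop codon")
    n_codons = len(codons) - 1  # coding codons, excluding the stop
    if not (0 <= position < n_codons):
        raise ValueError("lesion position outside the CDS")

    rng = np.random.default_rng(seed)
    if kind == "premature_stop":
        if position == 0:
            raise ValueError("cannot replace the start codon with a stop")
        codons[position] = str(rng.choice(list(STOP_CODONS)))
        lesioned = "".join(codons)
    elif kind == "start_loss":
        choices = [c for c in SENSE_CODONS if c != "ATG"]
        codons[0] = str(rng.choice(choices))
        lesioned = "".join(codons)
    else:  # frameshift: delete one nucleotide at the codon start
        nt_pos = position * 3
        lesioned = cds[:nt_pos] + cds[nt_pos + 1:]

    from .annotate import translate_to_first_stop  # shared convention

    ref_len = n_codons
    retained = len(translate_to_first_stop(lesioned, rescue_start=True))
    fraction_lost = max(0.0, 1.0 - retained / ref_len)
    return lesioned, LesionTruth(kind=kind, position=position,
                                 fraction_lost=fraction_lost)


def random_intact_cds(n_codons: int, seed: int) -> str:
    """A random intact CDS: ATG, sense codons, single trailing stop."""
    if n_codons < 3:
        raise ValueError("need at least three codons")
    rng = np.random.default_rng(seed)
    body = [str(c) for c in rng.choice(
        [c for c in SENSE_CODONS if c != "ATG"], size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"
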