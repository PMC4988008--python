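"""End-to-end orchestration of the synthetic comparative analysis.

Stages run in dependency order
(simulate -> annotate -> divergence -> trees -> reconcile -> selection
-> report); each stage reads only the outputs of earlier stages plus
the config, and every random choice derives from the config seed, so a
re-run with an unchanged config is byte-identical.  A run manifest
(config echo, seeds, package version, produced files) is written next
to the outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    GeneModel,
    classify_gene_model,
    name_gene,
    summarize_repertoire,
    translate_cds,
)
from .divergence import diverge_pair, divergence_summary, records_to_frame
from .io import read_tree, write_fasta, write_tree, read_fasta
from .reconcile import CostScheme, infer_gains_losses, reconcile
from .selection import scan_gene_sets
from .simulate import (
    DEFAULT_SPECIES_TREE,
    SimConfig,
    evolve_codons,
    inject_lesion,
    simulate_gene_family,
)
from .trees import (
    bootstrap_support,
    discrete_gamma,
    jtt_distance_matrix,
    nj_tree,
    parse_newick,
    prune_to_leaves,
)

log = logging.getLogger("chemevol.pipeline")

STAGES = ("simulate", "annotate", "divergence", "trees", "reconcile",
          "selection", "report")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-friendly)."""

    seed: int = 1
    outdir: str = "chemevol_out"
    species_tree: str = DEFAULT_SPECIES_TREE
    n_families: int = 4
    n_codons: int = 200
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    pseudo_rate: float = 0.1
    kappa: float = 2.0
    site_classes: list = field(default_factory=lambda: [[0.9, 0.2], [0.1, 5.0]])
    foreground_branches: list = field(default_factory=list)
    splice_table: dict = field(default_factory=dict)
    outgroup_species: str = "Dmel"
    bootstrap_reps: int = 50
    gamma_shape: float = 1.0
    dup_cost: float = 1.5
    loss_cost: float = 1.0
    support_threshold: float = 0.9
    beb_threshold: float = 0.95
    pseudogene_fraction: float = 0.20
    tm_threshold: int = 1
    selection_branches: list | None = None  # None -> all branches

    def __post_init__(self):
        if not 0 < self.pseudogene_fraction < 1:
            raise ValueError("pseudogene fraction must be in (0, 1)")
        if not 0 <= self.support_threshold <= 1:
            raise ValueError("support threshold must be in [0, 1]")
        if not 0 < self.beb_threshold < 1:
            raise ValueError("BEB threshold must be in (0, 1)")
        parse_newick(self.species_tree)  # validates

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        tree = raw.get("species_tree")
        if tree and not tree.strip().endswith(";"):
            raw["species_tree"] = Path(tree).read_text().strip()
        return cls(**raw)


def _family_seed(config: PipelineConfig, index: int) -> int:
    return int(np.random.SeedSequence(
        [config.seed, index]).generate_state(1)[0] % (2 ** 31))


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "pipeline.log", mode="a")):
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(handler)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    species_tree = parse_newick(config.species_tree)
    rows = []
    for i in range(config.n_families):
        fam = f"fam{i + 1:02d}"
        seed = _family_seed(config, i)
        truth = simulate_gene_family(
            species_tree, config.dup_rate, config.loss_rate,
            config.pseudo_rate, seed)
        if truth.gene_tree is None:
            log.info("simulate: %s extinct (seed %d)", fam, seed)
            rows.append({"family": fam, "seed": seed, "extinct": True,
                         "n_genes": 0, "n_duplications": 0,
                         "n_losses": truth.n_losses, "n_pseudogenes": 0})
            continue
        sim = SimConfig(
            seed=seed + 1, species_tree=config.species_tree,
            n_codons=config.n_codons, kappa=config.kappa,
            site_classes=tuple(tuple(c) for c in config.site_classes),
            foreground_branches=tuple(config.foreground_branches))
        aln, site_class = evolve_codons(truth.gene_tree, sim, truth=truth)
        write_fasta(aln, outdir / f"{fam}.codon.fasta")
        write_tree(truth.gene_tree, outdir / f"{fam}.genetree.nwk")
        pd.DataFrame({"site": np.arange(len(site_class)),
                      "class": site_class}).to_csv(
            outdir / f"{fam}.sites.tsv", sep="\t", index=False)
        rows.append({
            "family": fam, "seed": seed, "extinct": False,
            "n_genes": len(aln), "n_duplications": truth.n_duplications,
            "n_losses": truth.n_losses,
            "n_pseudogenes": len(truth.pseudogene_leaves)})
        pd.DataFrame({"pseudogene": sorted(truth.pseudogene_leaves)}).to_csv(
            outdir / f"{fam}.pseudo.tsv", sep="\t", index=False)
    pd.DataFrame(rows).to_csv(outdir / "families.tsv", sep="\t", index=False)
    write_tree(species_tree, outdir / "species.nwk")


def _load_families(outdir: Path):
    fams = pd.read_csv(outdir / "families.tsv", sep="\t")
    out = []
    for r in fams.itertuples():
        if r.extinct:
            continue
        aln = read_fasta(outdir / f"{r.family}.codon.fasta")
        tree = read_tree(outdir / f"{r.family}.genetree.nwk")
        pseudo = set(pd.read_csv(outdir / f"{r.family}.pseudo.tsv",
                                 sep="\t")["pseudogene"].astype(str))
        out.append((r.family, aln, tree, pseudo))
    return out


def _gene_models(config: PipelineConfig, outdir: Path):
    """Turn simulated rows into classified gene models.

    Rows become CDSs (ATG + codons + stop); truth-pseudogene copies get
    a concrete lesion before classification so the classifier sees an
    actual disruption, as it would in annotation practice.
    """
    models, refs = [], {}
    for fam_i, (fam, aln, tree, pseudo) in enumerate(_load_families(outdir)):
        homolog = f"Or{fam_i + 22}a"
        ref_name = next((n for n in aln if n.startswith(config.outgroup_species)
                         and n not in pseudo), sorted(aln)[0])
        ref_protein = translate_cds("ATG" + aln[ref_name] + "TAA").protein
        refs[fam] = (ref_name, ref_protein)
        per_species: dict[str, int] = {}
        for name in sorted(aln):
            sp = name.rsplit("_", 1)[0]
            per_species[sp] = per_species.get(sp, 0) + 1
        counters: dict[str, int] = {}
        for name in sorted(aln):
            sp = name.rsplit("_", 1)[0]
            counters[sp] = counters.get(sp, 0) + 1
            cds = "ATG" + aln[name] + "TAA"
            if name in pseudo:
                lesion_seed = _family_seed(config, 1000 + fam_i)
                n_cod = len(cds) // 3
                cds, _ = inject_lesion(cds, "premature_stop",
                                       max(1, n_cod // 3), seed=lesion_seed)
            cls = classify_gene_model(
                cds, ref_protein,
                fraction_threshold=config.pseudogene_fraction,
                tm_threshold=config.tm_threshold)
            copy_index = counters[sp] if per_species[sp] > 1 else None
            gid = name_gene(homolog, sp, copy_index,
                            is_pseudo=cls.status == "pseudogene")
            models.append(GeneModel(
                id=gid, species=sp, cds=cds, status=cls.status,
                lesions=cls.lesions))
    return models, refs


def stage_annotate(config: PipelineConfig, outdir: Path) -> None:
    models, _ = _gene_models(config, outdir)
    table = summarize_repertoire(models, config.splice_table)
    table.to_csv(outdir / "repertoire.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "id": m.id, "species": m.species, "status": m.status,
        "n_lesions": len(m.lesions),
        "lesions": ";".join(l.kind for l in m.lesions),
    } for m in models]).to_csv(outdir / "gene_models.tsv", sep="\t",
                               index=False)


def stage_divergence(config: PipelineConfig, outdir: Path) -> None:
    records = []
    for fam_i, (fam, aln, tree, pseudo) in enumerate(_load_families(outdir)):
        out_name = next((n for n in sorted(aln)
                         if n.startswith(config.outgroup_species)
                         and n not in pseudo), None)
        if out_name is None:
            continue
        out_cds = "ATG" + aln[out_name] + "TAA"
        family = "Or" if fam_i % 2 == 0 else "Gr"
        homolog = f"{family}{fam_i + 22}a"
        for name in sorted(aln):
            sp = name.rsplit("_", 1)[0]
            if sp == config.outgroup_species or name in pseudo:
                continue
            records.append(diverge_pair(
                gene=name, homolog=homolog, species=sp, family=family,
                cds="ATG" + aln[name] + "TAA", outgroup_cds=out_cds))
    records_to_frame(records).to_csv(outdir / "divergence.tsv", sep="\t",
                                     index=False)
    summary = divergence_summary(records)
    for key, df in summary.items():
        df.to_csv(outdir / f"divergence_{key}.tsv", sep="\t", index=False)


def stage_trees(config: PipelineConfig, outdir: Path) -> None:
    gamma = discrete_gamma(config.gamma_shape, 5)
    for fam, aln, tree, pseudo in _load_families(outdir):
        prots = {n: translate_cds("ATG" + s + "TAA").protein
                 for n, s in aln.items()}
        if len(prots) < 4:
            log.info("trees: %s has <4 genes, skipping inference", fam)
            continue

        def build(a, gamma=gamma):
            D, names = jtt_distance_matrix(a, gamma=gamma)
            return nj_tree(D, names)

        est = bootstrap_support(prots, build, config.bootstrap_reps,
                                seed=_family_seed(config, 2000))
        write_tree(est, outdir / f"{fam}.njtree.nwk")


def stage_reconcile(config: PipelineConfig, outdir: Path) -> None:
    species_tree = read_tree(outdir / "species.nwk")
    scheme = CostScheme(dup_cost=config.dup_cost, loss_cost=config.loss_cost,
                        support_threshold=config.support_threshold)
    rows = []
    copy_rows = []
    for fam, aln, tree, pseudo in _load_families(outdir):
        rec = reconcile(tree, species_tree, scheme=scheme)
        rows.append({"family": fam, "n_duplications": rec.n_duplications,
                     "n_losses": rec.n_losses, "cost": rec.cost})
        (outdir / f"{fam}.reconciled.nwk").write_text(
            rec.annotated_newick() + "\n")
        counts = {leaf.label: 0 for leaf in species_tree.leaves()}
        for name in aln:
            counts[name.rsplit("_", 1)[0]] += 1
        ancestral, deltas = infer_gains_losses(counts, species_tree)
        for node, delta in deltas.items():
            label = node.label or "|".join(sorted(node.leaf_names()))
            copy_rows.append({"family": fam, "branch": label,
                              "parent_count": ancestral[node.parent],
                              "count": ancestral[node], "delta": delta})
    pd.DataFrame(rows).to_csv(outdir / "reconciliation.tsv", sep="\t",
                              index=False)
    pd.DataFrame(copy_rows).to_csv(outdir / "copy_number_events.tsv",
                                   sep="\t", index=False)


def stage_selection(config: PipelineConfig, outdir: Path) -> None:
    gene_sets = []
    for fam, aln, tree, pseudo in _load_families(outdir):
        intact = {n: s for n, s in aln.items() if n not in pseudo}
        if len(intact) < 3:
            log.info("selection: %s has <3 intact genes, skipped", fam)
            continue
        pruned = prune_to_leaves(tree, set(intact))
        gene_sets.append({"name": fam, "alignment": intact, "tree": pruned})
    branches = ({None: config.selection_branches}
                if config.selection_branches else None)
    table = scan_gene_sets(gene_sets, branches=branches,
                           beb_threshold=config.beb_threshold)
    table.to_csv(outdir / "selection.tsv", sep="\t", index=False)
    if table.attrs.get("skipped"):
        pd.DataFrame(table.attrs["skipped"]).to_csv(
            outdir / "selection_skipped.tsv", sep="\t", index=False)


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    parts = []
    for name in ("families", "repertoire", "divergence_means",
                 "reconciliation", "selection"):
        path = outdir / f"{name}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            parts.append(f"## {name}\n{df.to_string(index=False)}\n")
    (outdir / "report.txt").write_text("\n".join(parts))


_STAGE_FUNCS = {
    "simulate": stage_simulate, "annotate": stage_annotate,
    "divergence": stage_divergence, "trees": stage_trees,
    "reconcile": stage_reconcile, "selection": stage_selection,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Run the requested stages in dependency order; returns the outdir."""
    stages = list(STAGES) if stages is None else [
        s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    produced = []
    for stage in stages:
        t0 = time.time()
        log.info("stage %s: start (seed %d)", stage, config.seed)
        before = set(outdir.iterdir())
        _STAGE_FUNCS[stage](config, outdir)
        produced.extend(sorted(str(p.name) for p in set(outdir.iterdir()) - before))
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    manifest = {
        "package": "chemevol", "version": __version__,
        "seed": config.seed, "stages": stages,
        "config": asdict(config), "new_files": produced,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return outdir
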