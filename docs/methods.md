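# Methods

This note records the models, conventions and numerical choices behind
`chemevol`, in the order the pipeline runs them.

## Gene-family simulator

Families evolve along a rooted binary species tree by a Gillespie
process: each gene lineage on a branch draws exponential waiting times
at total rate λ_dup + λ_loss + λ_pseudo (events per lineage per unit
branch length). Duplications split the lineage in place, losses remove
it (and are recorded on the species edge), and pseudogenization marks
the lineage dead-but-present: the copy is retained as a vestige and
evolves neutrally (ω = 1) from the event time onward, which is the
standard reading of relaxed constraint after loss of function.
Speciation nodes with a single surviving descendant are suppressed
(lengths summed) when the gene tree is exported. Leaves are named
`<species>_<copy#>` in deterministic traversal order. All randomness
flows from one explicit integer seed; there is no global RNG state,
and identical configuration plus seed reproduces every output
bytewise.

The default species tree is a nine-taxon melanogaster-group-like
topology (melanogaster subgroup, the suzukii–takahashii clade, and
D. ananassae as the distant member). Branch lengths are calibrated so
the suzukii–melanogaster path is ≈ 0.9 expected substitutions per
codon, the divergence scale at which synonymous distances between
these species sit near saturation onset (dS close to 1) — the regime
chemoreceptor comparisons in this group actually occupy.

### Codon process and the shared clock

Sequences evolve under MG94×HKY over the 61 sense codons: a
single-nucleotide change i→j has rate π_j · κ^[transition] ·
ω^[nonsynonymous]; multi-nucleotide changes have rate zero, and stop
codons are excluded from the state space, so disrupted sequences can
never arise from the substitution process itself. Site classes are a
mixture of (proportion, ω) pairs; when foreground branches are
designated, the last class is the elevated one, and sites assigned to
it use its ω only on foreground branches (falling back to the first
class's ω elsewhere) — the classic branch-site arrangement.

All constrained classes share one clock: each class generator is
normalized by the flux of the *background* mixture rather than by its
own flux. Branch lengths therefore mean expected substitutions per
codon on background branches exactly (a single-class simulation at
t = 0.3 produces ≈ 0.3 changes per codon), while elevated-ω sites on
foreground branches substitute proportionally faster. Self-normalizing
every class instead would make ω₂ alter only the *composition* of
substitutions, not their number, and the branch-site test would be
left with almost no signal; the shared clock is also what standard
branch-site software effectively assumes. Neutral (pseudogenized)
segments are self-normalized at ω = 1.

### Lesions

`inject_lesion` disables an intact CDS with one of three events:
premature stop (codon replaced by a random stop), start loss (ATG
mutated to a random sense codon), or frameshift (single-nucleotide
deletion). The reported truth is the fraction of the reference protein
missing after translating the lesioned sequence to its first stop,
using the same conventions as the classifier (below), so classifier
fidelity can be scored against an internally consistent ground truth.

## Classification and bookkeeping

Translation follows the standard nuclear code; a mutated start is
rescued at the next in-frame ATG (the least destructive reading — the
alternative, declaring the whole protein lost, would make every start
lesion a pseudogene call regardless of position). Transmembrane
segments come from a Kyte–Doolittle sliding-window scan: window 19,
mean-hydropathy threshold 1.6, flagged window centres extended to the
window extent, segments merged when separated by fewer than 5 residues
and discarded below 15 residues. The parameters are the common
textbook choices for membrane-span detection; the procedure is
deterministic, so every fixture is decidable by hand.

A model is a **pseudogene** when some lesion loses ≥ 20 % of the
reference protein AND ≥ 1 TM segment (conjunctive, following the
sentence structure of the rule as usually stated; `conjunctive=False`
switches to either-sufficient). A model shortened by ≥ 20 % with *no*
lesion is **partial** — assembly truncation — and is excluded from
both the locus and functional counts, which is the only reading under
which the table identity `functional = loci − pseudogenes` holds.
Splice-isoform counts are supplied as a table (gene → isoforms); no
mechanistic splice simulation is attempted.

Orthogroups are reciprocal best hits on affine-gap global alignment
scores (BLOSUM62, open 10, extend 1; ties broken by lexicographic gene
id), with connected components of the RBH graph as groups. A lineage
is *lost* in a species when the species has no intact member of the
orthogroup — vestiges (pseudogenes, partials) do not rescue it, and
any intact member does.

## Divergence

%ID divides identical columns by the full alignment length including
gap columns (the denominator convention is switchable and documented
because alignment tools differ). NG86 site counts are per-position
synonymous fractions among single-nucleotide neighbours with mutations
to stops excluded from the denominator; multi-difference codons
average uniformly over the stop-free orderings of the differing
positions. Saturated proportions (p ≥ 3/4) make the Jukes–Cantor
correction undefined and are flagged rather than dropped. Note the
estimator's known behaviour: under transition bias (κ > 1) NG86
underestimates ω even for neutral data, so estimator-consistency
checks simulate at κ = 1.

Both Wilcoxon tests use exact null distributions (dynamic programming
over doubled midranks — doubling makes tied ranks integer weights) for
n ≤ 25 (signed-rank) or m + n ≤ 20 (rank-sum), with zeros dropped and
two-sided p = 2·min(lower tail, upper tail) capped at 1, which is
identical to full enumeration. Larger samples use the normal
approximation with continuity and tie corrections.

## Trees

Newick parsing preserves internal-node labels verbatim; numeric labels
double as bootstrap supports. Discrete-gamma rates are the conditional
means of k equal-probability quantile intervals, renormalized to mean
one. JTT distances maximize the one-parameter likelihood under the
shipped JTT exchangeabilities and stationary frequencies (versioned
data file), optionally gamma-mixed, after complete deletion of gapped
columns, capped at 10 substitutions/site. Tree search is neighbor
joining on those distances (negative branch lengths clamped to zero
with a warning) with bipartition-frequency bootstrap; full
maximum-likelihood topology search is deliberately out of scope, and
user-supplied trees are accepted by every downstream stage.

## Reconciliation

LCA mapping (each gene node → LCA of its descendants' species) is the
simultaneous minimizer of duplications and losses, hence also of any
positively weighted cost; the default scheme is duplication 1.5, loss
1.0. A node is a duplication iff it maps to the same species node as
one of its children; losses on edge (u, v) are
depth(M(v)) − depth(M(u)), minus one when u is a speciation. The loss
formula is verified exclusively against a brute-force search over all
ancestrally consistent mappings so the implementation cannot drift
from the definition. Non-binary trees are rejected, never resolved
silently.

Edges with bootstrap support below 0.9 may be rearranged: a best-first
search over topologies reachable by NNI moves restricted to weak
edges (capped at 500 distinct topologies) keeps the cheapest
reconciliation, with ties broken by the lexicographically smallest
sorted newick so reruns are stable. Rerooting is not part of the
search. Ancestral copy numbers use Sankoff minimum-change integer
states with unit cost per copy, ties resolved to the smallest state.

## Branch-site selection machinery

The likelihood engine is Felsenstein pruning over 61 codon states with
site patterns compressed once per alignment; transition matrices come
from a symmetrized eigendecomposition (√π similarity transform), which
is exact for these reversible generators and cheap enough to recompute
at every ω proposal. Codon frequencies default to F3x4 (position-
specific nucleotide frequencies, stops removed, renormalized; zero
counts get a pseudocount with a warning).

The test is the fixed two-class arrangement: background sites at ω₁
(bounded to [0, 1] by default), a fraction p₂ of sites at ω₂ ∈ [1, 50]
on the foreground branch only, with the foreground elevated class
normalized by the ω₁ clock (matching the simulator). The null pins
ω₂ = 1 with proportions free. Fitting is two-stage: a baseline
single-ω fit of (κ, ω, tree scale) by L-BFGS-B on log parameters, then
class-parameter optimization with branch lengths and κ fixed at the
baseline estimates — the same nuisance-parameter treatment practical
branch-site pipelines use, chosen over full joint optimization for
desk-scale runtime. Class fits use three deterministic multistarts
plus a start at the null solution, which guarantees
lnL_alt ≥ lnL_null; only the root-path partials are recomputed for the
second class, roughly halving the cost per evaluation. Convergence
failures are flagged on the result, never raised.

LR = 2(lnL_alt − lnL_null) is referred to the 50:50 mixture of a point
mass at zero and χ²₁ (the boundary null for ω₂ = 1); plain χ²₁ is
available as a conservative switch. Holm–Bonferroni controls the
familywise error over the branches tested within a gene set;
Benjamini–Hochberg controls FDR across sets. Site posteriors are
empirical Bayes at the MLEs (NEB), with an optional coarse
Bayes-empirical-Bayes analogue that averages the posterior over a
uniform 10×10 grid on (p₂, ω₂ ∈ [1, 50]) weighted by each grid point's
data likelihood; sites above 0.95 are flagged.

## Calibration experiments and what they show

`chemevol.calibration` runs two standard experiments on the
nine-species framework. The null sweep simulates 300 gene sets of 200
codons with a single uniform ω drawn from U(0.05, 0.8) per set and
records the raw branch-site p-value on a designated branch; because
the chi-bar null is conservative and nuisance parameters are fixed
from a baseline fit, the observed rejection rate at 0.05 sits well
below nominal. The power run simulates 50 sets of 500 codons with
p₂ = 0.1 of sites at ω₂ = 5 on the Dsuz branch, tests the foreground
plus two background branches, and applies Holm within each set; at
these settings detection is essentially certain and the median
(ω̂₂, p̂₂) land within 25 % of truth. Problem sizes (200/500 codons,
300/50 replicates, three branches per power set) are the package's
reference configuration; all are arguments.

Because the simulator is gap-free, lesion truth is self-consistent
with the classifier's conventions, and alignments are known rather
than estimated, passing these experiments shows the *inference
machinery* is correct and calibrated — it does not exercise alignment
error, assembly gaps, annotation ambiguity, or model misspecification
beyond the ω-mixture family, all of which affect real repertoire
studies.

## Known limitations

* No indel or splice-site simulation; alignments are gap-free by
  construction, and gapped real alignments are accepted but columns
  with gaps are skipped in codon-level statistics.
* The branch-site model uses a fixed two-class mixture per foreground
  branch; adaptive class counts and synonymous rate variation are out
  of scope.
* Site-model (M1a/M2a-style) tests are not provided; the branch-site
  machinery is the only selection test.
* The frameshift truth measures retained protein up to the first stop
  in the shifted frame, which slightly overstates the retained
  fraction when the garbled tail translates for a while; fixtures
  avoid the 0.18–0.22 band where this could flip a call.
* Reconciliation assumes rooted binary trees and duplication/loss
  events only (no transfers, no probabilistic reconciliation).
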