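# Methods

## The problem

Large-scale duplication events (whole-genome or segmental) leave a
characteristic footprint in transcriptome data even when gene order is
unknown: many paralog pairs of similar age. Age is proxied by the
synonymous distance dS between paralogs — synonymous changes are nearly
neutral, so dS accumulates roughly clock-like. A burst of duplication
appears as a secondary peak in the distribution of duplication-node ages,
separable from the steady background of recent single-gene duplicates
which, because young duplicates are usually lost quickly, concentrates
near dS ≈ 0.

`dupscape` implements this analysis end to end for a set of arachnid
transcriptomes (three cobweb-weaver species plus progressively more
distant relatives out to a scorpion and a tick), together with a
synthetic-evolution module that generates data with exactly the
statistical structure the analysis assumes. Every stage can therefore be
exercised, and its recovery quantified, without any external download.

## Pipeline stages

1. **Transcript preparation** (`transcript_prep`). Longest-ORF
   translation over 6 frames (ties to the earlier frame, then the 5'-most
   start); records whose ORF is stop-bounded at both ends and whose
   post-first-methionine stretch is ≥ 75% of the ORF are trimmed to that
   M. Within-species redundancy is merged by single linkage over pairs at
   ≥ 98% identity on a local alignment of ≥ 50 bp, keeping the longest
   member. Cross-species contaminants are members of 99%-identity /
   99%-coverage cross-species clusters whose species-summed abundance is
   below 1% of the cluster maximum.
2. **Family building** (`family_builder`). Single-linkage homolog
   clustering at 70% amino-acid identity and 60% coverage (built-in exact
   local alignment with BLOSUM62, affine gaps −11/−1; an imported
   pair-score table can replace it at scale). Outgroup sequences attach
   only when their best match in *every* focal species lies in the same
   cluster. Alignments are trimmed to the window bounded by the shortest
   of the per-species longest members; sequences with > 25% gaps over the
   retained columns are removed; a column filter then drops columns with
   > 20% gaps unless all residues in the column are a single state.
3. **Trees** (`tree_toolkit`). Neighbor joining (Saitou–Nei, deterministic
   tie-breaks, negative branches clamped with the deficit moved to the
   sibling) on pairwise distances; the default feed is the NG86
   synonymous distance, which resolves shallow splits far better than
   amino-acid distance under strong purifying selection
   (amino-acid Poisson distance is available as an option). The unrooted
   tree is rooted by evaluating every edge and minimizing implied
   duplications (ties: fewer losses, then the most recent root mapping,
   then the smallest edge index), followed by standard LCA reconciliation:
   a node is a duplication iff it maps to the same species-tree node as
   one of its children; losses are counted as path-length excess. Families
   are delineated by splitting labeled trees at a designated speciation
   node and requiring a chosen species set.
4. **Dating** (`molecular_rates`). NG86 counting: per-codon synonymous
   sites from the 9 single-nucleotide neighbors with stop mutations
   excluded from the denominator; observed differences resolved by
   averaging over minimal substitution pathways that avoid stops;
   Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)·p). A duplication node's
   age is the mean pairwise dS over conspecific leaf pairs whose LCA is
   that node; a speciation node's age uses the cross-species pairs.
   Saturated pairs (1 − 4p/3 ≤ 0) are excluded from node means; a node
   with no usable pair is undated. Duplication ages are filtered to
   0.01 ≤ dS < 2: below, likely alleles/isoforms; above, saturation.
   Family-wide ω is mean pairwise dN over mean pairwise dS — a counting
   substitute for codon-ML ω, adequate in the dS < 2 regime and exactly
   testable by enumeration; the interface permits drop-in replacement.
5. **Mixtures and statistics** (`mixture_stats`). A K-component univariate
   Gaussian mixture is fitted by EM with deterministic quantile
   initialization (component k at the (k+0.5)/K quantile, equal weights,
   pooled ML sd), σ floored at 1e-4 to prevent collapse, convergence at a
   log-likelihood gain < 1e-8. K = 2 is the headline decomposition;
   log-likelihood and BIC for other K are available, and in both the
   empirical and simulated settings extra components refine only the young
   side. Nodes are assigned to a component when its posterior
   responsibility is ≥ 0.95 (boundary assigned). The "older" component is
   the one with the larger mean; its median age is placed among the
   per-speciation-node median ages. The comparative battery (Kruskal–
   Wallis with tie correction, Welch's t, per-category OLS of ω on
   additional-member count, type-II two-way ANOVA, 2×2 chi-square/Fisher)
   delegates to scipy/statsmodels behind the module surface, with
   degenerate designs guarded (exact separation, zero residual variance,
   zero design variance are flagged rather than returned as raw
   infinities).

A filtered duplication node's expression class follows its descendant
leaves: SST (silk-specific transcript) with at least one silk-specific
descendant, non-SST with at least one significantly expressed descendant,
otherwise low. Family-level classification (any SST member → SST family)
is used for the ω and size contrasts. Deep nodes span many genes and so
are likelier to contain an SST descendant than two-gene cherries — this
asymmetry is part of why older-peak enrichment separates so cleanly.

## The synthetic generator

Families evolve along a dated nine-taxon arachnid species tree (three
theridiid cobweb weavers, a fourth theridiid, an araneoid, an eresid, a
mygalomorph, a scorpion, a tick). Node dates are in **pairwise-dS units**:
a node of date d produces extant descendant pairs at expected dS ≈ d, so
simulated depths compare directly to NG86 estimates. The speciation
depths are 0.10, 0.18, 0.25, 0.33, 0.41 (eresid split), 0.59
(Mygalomorphae–Araneomorphae), 0.72 (spider–scorpion) and 0.90
(tick–spider).

* **Large-scale duplication.** One optional event at a fixed date on a
  chosen branch (default: dS 0.5 on the branch between the 0.41 and 0.59
  nodes). Every lineage crossing the date duplicates; both copies survive
  with the retention probability of the family's expression category
  (defaults 0.9 for SST families, 0.6 otherwise — free parameters
  encoding the retention-bias hypothesis, not empirical estimates).
* **Small duplications.** A Poisson birth process (0.3 events per unit
  dS) whose extra-copy lineages die at rate 10 per unit dS. The high
  turnover makes surviving single-gene duplicates young, reproducing the
  empirical shape of paralog-age distributions (a peak below dS ≈ 0.1,
  then a valley). Loss is restricted to the extra copies: applying it to
  the speciation backbone would also purge species coverage, which is not
  the structure the analysis assumes; this is the one deliberate
  departure from a fully symmetric birth–death process.
* **Rates.** Per-family lognormal rate multipliers with mean 1 and CV 0.2
  spread node ages and hence mixture widths. Per-family ω is lognormal
  around the category mean (0.10 SST / 0.05 other, CV 0.2).
* **Sequences.** A simplified codon process: from codon c, total
  synonymous rate equals its NG86 synonymous site count (so branch
  lengths are expected synonymous substitutions per synonymous site) and
  nonsynonymous rate is ω times the nonsynonymous site count; targets are
  uniform among eligible neighbors and stops are forbidden. No
  transition/transversion bias (the downstream NG86 estimator does not
  require it) and no indels by default. Estimator-vs-generator agreement
  is within ~2–3% relative at dS 0.5–0.7 with 2,000 codons.
* **Expression.** SST families mark a minority (~25%, at least one) of
  their genes silk-specific, with silk-library abundance ≥ 1 and dominant;
  "expressed" genes get ≥ 1 somewhere; "low" genes stay < 1 everywhere.
  Planted cross-species contaminants copy a donor sequence into another
  species at 0.1% of the donor's species-summed abundance.

What the generator does **not** emulate: assembly artifacts and chimeras,
isoforms, codon-usage and amino-acid composition bias, indels (an
optional gap mode exists only to exercise the gap filters), spidroin-like
repetitive-region evolution, and any correlation between ω and family
size (the omega-vs-size regression therefore recovers near-zero slopes
with category-separated intercepts — the intercept difference, not the
slope, is the simulated signal). Passing recovery tests shows the
pipeline's inference machinery is correct under the assumed structure,
not that real transcriptome noise is handled.

## Problem sizes and numerical choices

The canonical simulated studies are 300 families × 2,000 codons for
duplication-event recovery and 200 families × 2,000 codons for the
expression contrast — sizes at which mixture means stabilize within a few
hundredths of a dS unit while a full analysis completes in well under a
minute on one core. Determinism: every stochastic step draws from a
single seeded generator; EM initialization is seed-free and quantile
based; NJ and rooting tie-breaks are lexicographic. Saturated distance
pairs feeding NJ are imputed with the matrix maximum (logged); families
with fewer than three sequences are skipped by tree inference. True
event nodes are scored against inferred trees by exact descendant
leaf-set match.

## Known limitations

* NG86+JC undercorrects multiple hits near saturation; this is why ages
  are filtered at dS < 2 and why the tick-depth (0.9) estimates carry the
  largest relative error.
* LCA reconciliation cannot see duplications hidden by loss; with the
  generator's loss confined to small-duplication extras this is rare in
  simulation but real data would undercount.
* The built-in all-vs-all aligner in family building is quadratic and
  meant for desk scale; large datasets should import a pair-score table
  from an external search tool.
* ω from pairwise counting averages over branches; episodic selection on
  single branches is invisible.
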