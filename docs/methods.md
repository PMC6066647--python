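# Methods

## Scope and data model

`motudelim` analyses an *aligned* COI barcode library: a FASTA alignment
plus a specimen metadata table (morphospecies label, genus, family, site,
basin, voucher).  Alignment itself is out of scope — the pipeline consumes
what an aligner produces.  IUPAC ambiguity codes and gaps are kept at load
time and handled at distance time by pairwise deletion: for each pair,
only columns where both sequences carry an unambiguous A/C/G/T are
compared (the default behaviour of the standard barcode toolchains).

Morphospecies labels are parsed for open nomenclature: `sp.` and
suprageneric names (e.g. subfamily `-inae`) mark undescribed taxa, while
`aff.`, `cf.` and `gr.` mark uncertain identifications anchored to a
nominal species.  This routing matters downstream: anchored labels are
judged by the described-species rule, unanchored ones by the
undescribed-taxon rule (the survey tables the package transcribes follow
exactly this split).

A NUMT screen guards against nuclear pseudogene artefacts: each sequence
is checked for internal alignment gaps (indels are not expected in a
protein-coding mitochondrial fragment) and translated in all three forward
frames under the vertebrate mitochondrial code (stops TAA/TAG/AGA/AGG);
the frame minimising stop codons must be stop-free.

## Distances

Kimura 2-parameter is the working model, d = −½ ln[(1 − 2P − Q)√(1 − 2Q)];
JC69 and raw p-distance are available.  Non-positive log arguments are
flagged saturated and reported as +inf.  Summaries follow barcoding
convention: intraspecific statistics pool conspecific pairs (species with
fewer than 3 specimens are excluded, threshold configurable), the genus
rank pools congeneric heterospecific pairs and the family rank confamilial
heterogeneric pairs.  Per-species reports include the nearest-neighbour
(NN) species and distance, the barcode gap (NN distance − max intra) and a
"maximum similarity" defined as 100 × (1 − minimum p-distance to any
heterospecific specimen) — reference databases report similarity on the
p-distance scale, and the exact metric they use is unpublished, so this
definition is fixed here and documented.

## Neighbour joining

Standard Q-criterion agglomeration.  Determinism is guaranteed by breaking
Q ties in favour of the lexicographically smallest pair of cluster keys (a
cluster's key is its smallest specimen id).  Negative branch-length
estimates are clamped to zero with the deficit moved to the sibling
branch.  Clade exclusivity asks, per morphospecies, whether any edge
bipartition isolates exactly its specimens; both sides of every split are
tested, so the verdict is rooting-invariant, and singletons are exclusive
by definition.

## ABGD-style gap partitioning

For each prior P (20 log-spaced values in [0.001, 0.1] by default):

1. rank all pairwise distances; distances ≤ P form the candidate
   intraspecific region;
2. scan upward (including the gap out of the prior region) for the first
   *significant* gap between consecutive ranked distances;
3. set the threshold at the gap midpoint; groups are connected components
   of the graph linking pairs at or below it;
4. recurse inside each group until no gap is found (groups whose diameter
   is within the prior are left alone).

A gap g at distance d counts as significant when it exceeds X times both
the mean gap in a sliding window of the preceding W = 10 ranked distances
and d itself, and is at least 2/median(compared sites) wide.  The second
and third conditions are deliberate additions to the window heuristic:
distances move in quanta of roughly one substitution (≈ 1/650 for full
barcodes), and the slight convexity of the K2P transform makes the gap
between the one- and two-substitution values marginally wider than the
one-substitution value itself — a window mean alone would hence "detect" a
gap at the very bottom of the intraspecific cloud.  Requiring the gap to
exceed the current distance (a relative-width requirement, X = 1.0) and
the sampling resolution removes that artefact without affecting genuine
barcode gaps, which at the survey's scales are several times wider than
the distances below them.  All three constants are config-exposed.

Because a sweep produces many partitions, `select_partition` mirrors the
field's practice of reconciling ABGD with an independent clustering: it
returns the sweep partition with the highest Rand index against a
companion partition (ties to the smaller prior).

## PTP (maximum likelihood and Bayesian)

The Poisson tree processes model assigns every branch of a rooted tree to
a speciation or a coalescent exponential class; a configuration is an
antichain of "MOTU root" nodes covering all tips, with all edges strictly
inside a MOTU subtree coalescent and everything above speciation.  Class
rates are profiled out at their MLEs (count/sum of class branch lengths).

*Input tree.*  The NJ tree is the default PTP input (midpoint-rooted when
unrooted); a user-supplied Newick tree can replace it.  Bayesian tree
inference is deliberately out of scope — PTP operates on any tree with
branch lengths in substitutions/site.

*Branch-length floor.*  The profile likelihood is unbounded as a class's
branch-length sum approaches zero (its rate MLE diverges), which in
practice drives the search towards all-singleton partitions on trees full
of near-zero branches — exactly what barcode libraries of haplotype
clusters produce.  Pipelines therefore floor every branch at half a
substitution over the alignment length (0.5/L), the resolution below
which the tree cannot distinguish a branch from zero; the same device is
used by modern PTP implementations.  The direct function interface keeps a
bare 1e−8 floor for callers who want the unregularised model.

*ML search.*  Greedy boundary descent (split one MOTU root into its
children, or merge a complete sibling set) from a battery of starts: all
tips, the root, 19 deterministic states obtained by thresholding edge
lengths at quantile cutoffs, and 20 seeded random antichains.  The
returned likelihood always dominates the one-MOTU and all-singleton
configurations.  A tree whose branch lengths are all equal has no
two-class signal; it yields a single MOTU flagged low-confidence.

*Bayesian flavour.*  Metropolis–Hastings over the same state space with a
flat prior: propose one uniformly chosen split/merge move, accept with the
likelihood ratio times the Hastings factor |moves(x)|/|moves(x′)|.
Defaults follow common practice (500 000 generations, thinning 100, 10%
burn-in); the chain starts at the greedy mode to shorten burn-in (the
stationary distribution is unaffected).  Support of a MOTU is the
posterior frequency of its exact tip set.  The returned partition is the
*modal sampled configuration*: a greedy cover by per-MOTU support was
rejected because singleton tip sets accumulate support across many
distinct configurations and would systematically oversplit.  On trees
small enough to enumerate, the sampled state frequencies match the
brute-force posterior (this is tested).

## BIN-style surrogate

BOLD's RESL algorithm is proprietary-adjacent and not published in
implementable detail, so the package ships a stated surrogate: (1) single
linkage at 2.2% (the conventional BIN seed threshold) via connected
components; (2) within each cluster, rescan the ranked distances for a gap
of width ≥ 2.2%; when found, cut at its midpoint — and if a single
chaining link keeps the cluster connected, lower the cut through the
distinct values below the gap, accepting the first split whose
between-component distances are all ≥ 2.2%.  The acceptance guard is what
prevents the refinement from shattering genuinely chained clusters while
still realising deep internal divergences.  The procedure is deterministic
and invariant to specimen order.

## Congruence rules and the cryptic tally

Evidence per morphospecies: max/mean intraspecific divergence, NJ clade
count, cluster counts under the BIN-surrogate, selected-ABGD and Bayesian
PTP partitions, whether any cluster is shared with another nominal
species, the number of *exclusive* clusters (containing only this label)
that are not assignable by similarity (≥ 98%, i.e. < 2% divergent) to a
described neighbour, and NN/similarity statistics.

*Described rule.*  max intra ≤ 2% → assigned to the nominal species.
Deep divergence with a shared cluster → misidentification/hybridisation
suspect (COI cannot tell these apart; one verdict covers both).  Deep
divergence with congruent method support for k ≥ 2 clusters, none shared
→ cryptic candidate with k − (labels in the row) extra MOTUs.  Deep
divergence without congruent support → unresolved.

*Undescribed rule.*  No exclusive unassignable cluster → assigned to the
nearest nominal species.  Otherwise the taxon is a new MOTU; its *cryptic*
count is the number of exclusive clusters beyond the one that simply *is*
the taxon — all of them when the label is also anchored elsewhere (shared
or similarity-assigned clusters) and shows an internal split (max intra
above threshold, or ≥ 2 exclusive clusters), else one fewer.  This single
formula reproduces, without per-taxon special-casing, every per-taxon
outcome printed in the survey the fixtures transcribe.

*Congruence strictness.*  `strict` requires all three cluster counts
equal; `majority` accepts agreement between any two.  Real data motivates
the relaxed mode (the survey itself flagged taxa where the Bayesian PTP
disagreed with the two distance-based methods), and the synthetic
end-to-end analyses use it for a structural reason: within-species
genealogies are stars, so NJ resolves the intraspecific polytomy
arbitrarily and an injected cryptic clade attaches at a random position
inside its sister lineage — that lineage is then usually not a clade and
no tree-based method can return it as a single MOTU, while both
distance-based methods do.

The tally sums cryptic MOTUs over flagged described species and
open-nomenclature taxa, and counts taxa per verdict.  Raising the
intraspecific threshold can only shrink the cryptic tally (tested at 1%,
2%, 5%).

## Synthetic libraries

The generator emulates the statistical structure the analysis assumes:

* a star species tree with stem lengths uniform in [m/2, 3m/2]
  (m = `min_inter`, default 5%), so interspecific distances fall in
  [m, 3m] ≈ 5–15%, plus within-species noise — commensurate with the
  intergeneric divergences barcode surveys report;
* star genealogies within species, each specimen on a branch of
  `expected_intra`/2 (default pairwise intraspecific divergence 0.5%);
  stars keep the expected divergence closed-form, at the cost of zero
  intraspecific topological signal (see the strictness note above);
* a two-rate substitution process (transition:transversion rate ratio
  κ = 4) over a stop-free coding scaffold of 658 nt; substitutions that
  would create an in-frame stop are redrawn, so simulated sequences always
  pass the NUMT screen — the generating process is exactly the K2P model
  the distance estimator assumes;
* sampling defaults: 10 species, a mean of ≈ 4.5 specimens per species
  (exact when an integer is given), matching the sampling depth of the
  motivating survey;
* optional injections, each logged in a truth table: cryptic lineages
  (extra within-label split at depth 8%), label swaps (misidentification)
  and shared haplotypes (introgression mimic).

What the generator does *not* emulate: indels, sequencing error,
ambiguity codes, population structure within species, rate variation
across sites or lineages, and non-star species trees.  Passing tests on
synthetic libraries therefore demonstrate correctness of the algorithms
under the model's own assumptions, not robustness to every artefact of
real barcode data.

## Packaged fixtures

Two TSVs under `motudelim/data/` transcribe the motivating survey's
evidence tables: described species with deep (> 2%) intraspecific
divergence (max/mean distance, clade and per-method cluster counts), and
undescribed taxa with their per-cluster nearest-neighbour survey
(cluster id, concordance classification, similarity).  A third file
carries per-taxon cluster counts compiled from the survey's text for the
undescribed taxa.  Annotation columns (cluster sharing, label counts per
row) encode statements made in the survey's prose rather than its tables
and are marked as such in the file headers.  One taxon appears in both
tables and is judged once, through the described-species route.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (default 42).  The test
suite and worked examples run the Bayesian sampler at 3 000–40 000
generations on 25–50-tip trees — posterior mass on these clean libraries
is concentrated enough that longer chains do not change the modal
partition, and two independent seeds are checked to agree — while the
library default remains 500 000 generations for survey-scale use.  Report
files embed the package version, seed and a configuration hash; identical
configurations produce byte-identical outputs.

## Known limitations

* The BIN surrogate approximates BOLD's unpublished clustering; cluster
  counts can differ from true BINs on borderline (≈ 2.2%) divergences.
* PTP inherits its known sensitivities: non-clade species (hybridisation,
  introgression, misidentified tips) cannot be delimited correctly on any
  tree, and delimitation quality is bounded by the input tree.
* Singleton morphospecies carry no intraspecific signal; they can be
  flagged as new MOTUs but never as cryptic.
* The decision layer is a formalisation of a survey workflow, not a
  statistical test; verdicts are evidence summaries with explicit
  rationale codes, intended for expert review.
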