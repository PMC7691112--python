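# Methods

## The simulation model

`corephylo.simulate.evolve` implements a forward-in-time model of
core-genome evolution with homologous recombination, of the
gene-conversion kind: a donor tract replaces the homologous recipient
tract, with no reciprocal exchange and no indels, so the alignment stays
column-correct throughout.

**Time axis and contemporaneity.** Branch lengths (expected substitutions
per site) are used directly as the time axis, with depth measured from the
root.  The tree is cut at every distinct node depth into intervals; an
edge is alive on `[depth(parent), depth(child))`.  This definition also
covers non-ultrametric trees: a lineage whose leaf sits at a shallow depth
simply stops being a donor or recipient after its endpoint.  Within an
interval, all lineages' events (substitutions and recombination events of
every alive lineage) are pooled into a single queue, shuffled globally,
and applied sequentially — so a recipient can receive alleles that the
donor itself acquired moments earlier in the same interval.

**Substitutions.** For a lineage segment of duration `l` the substitution
count is Poisson with mean `l·L`; the codon-position rates only reweight
*where* substitutions land (site picked with probability proportional to
its position's rate), leaving the overall rate intact.  Each substitution
replaces the current base by its transition partner with probability
`κ/(κ+2)` and by each of the two transversion partners with probability
`1/(κ+2)` — the K80 convention in which `κ` is the transition rate over
each single transversion rate.  A consequence worth remembering: at low
divergence the *count* ratio of transition to transversion differences
between two sequences is `κ/2`, because there are two transversion
targets.  `estimate_kappa` therefore returns the raw count ratio by
default and the doubled, K80-style rate ratio with `rate_ratio=True`; the
simulator consumes the rate ratio, and the generator–estimator round trip
is calibrated accordingly.

**Recombination.** Per segment the event count is Poisson with mean
`ρ·l·L`, where the mean uses the *expected* substitution count (the branch
parameter), not the realized draw.  Each event draws a uniform tract
start, a tract length from a geometric law with mean `δ` (support ≥ 1;
default `δ` = 100 bp, the mid-range of reported bacterial gene-conversion
tract sizes), and a donor uniformly among the *other* lineages alive in
the interval.  Tracts overrunning the sequence end are truncated — the
genome is a linear concatenate, not a circular chromosome — and the
realized length recorded.  The number of donor–recipient differences
inside the tract is counted *before* copying; an event whose only possible
donor is the recipient itself (single alive lineage) is discarded and not
counted.  Coordinates are 0-based, half-open.

**Accounting.** A run records `m` (substitutions applied), the event list,
`r` (total alleles transferred), and total realized tract length.  The
effective recombination rate is `r/m`; with `ν = r / (total tract bp)` the
identity `r/m = (events/m) · (mean realized tract) · ν` holds exactly by
construction, and the test suite asserts it to 10⁻⁶.  Note that `ν` is a
per-site density within tracts; `r/m` values saturate well below `ρ` once
tracts start re-exchanging already-transferred alleles.

**Known limitations.** The substitution process is base-symmetric, so GC
content enters only through the root genome and erodes toward 0.5 on long
trees; at the intra-species divergences simulated here (mean root-to-tip
depth ≤ 0.05) the erosion is negligible.  There is no selection, no
rate heterogeneity beyond codon position, no indels or gene content
change, no external donor pool, and no recombination hotspots — every
site has the same probability to recombine.

## Parameter estimation

`estimate_gc` is the unambiguous-base G+C fraction.  `estimate_kappa`
counts pairwise transition and transversion differences with no
multiple-hit correction — adequate at intra-species divergence, and
consistent with the simulator's conventions as described above.
`estimate_codon_rates` uses the fraction of polymorphic columns
(≥ 2 distinct unambiguous bases, singletons included) at each codon
position, normalised to mean 1.  The polymorphic fraction is a saturating
function of rate, so this estimator is accurate only at low divergence;
recovery tests run at mean root-to-tip depth 0.008 on 100 kb genomes,
where all three rates return within a few percent.  The codon frame is
assumed to start at alignment position 1 (in-frame gene concatenates).

## Tree comparison and site congruence

Trees are compared unrooted, through nontrivial bipartitions (both sides
≥ 2 leaves), canonicalised by the side not containing the smallest leaf
label.  The tree topology score of a test tree against a reference is
100 × (shared nontrivial bipartitions) / (reference's nontrivial
bipartitions); for binary trees it is symmetric, and an unresolved test
tree can only lose points — a conservative treatment of poorly resolved
nodes.  The random-topology baseline inserts leaves sequentially at
uniformly chosen edges, which yields the uniform distribution over
unrooted binary labelled topologies; against a 30-leaf reference its
expected score is a few percent.

A column is *congruent* with a tree when all its allele classes can
simultaneously be connected subtrees, i.e. when it is homoplasy-free.
This is evaluated as parsimony score = (number of states − 1), computed
by a unit-cost Sankoff dynamic program vectorised across sites (exact on
multifurcating trees, missing bases contribute no cost).  For biallelic
columns this reduces to the familiar rule: the split matches an edge
bipartition or one class is a singleton.

## Tree inference

Distances default to JC69-corrected p-distances, the minimal multiple-hit
correction consistent with the simulator's symmetric model; saturated
pairs (p ≥ 0.74) are capped at the p = 0.74 value with a logged warning so
that high-`ρ` replicates stay buildable (such trees are garbage either
way, which is the point being measured).  The distance tree builder is
BIONJ — neighbor joining with variance-weighted distance updates
(`λ` chosen per merge to minimise the variance of the new distances, with
first-order variances initialised to the distances themselves).  Ties in
the Q criterion break on the lowest (row, column) pair; negative branch
estimates are clamped to zero without affecting topology.  On additive
matrices the builder recovers topology and branch lengths exactly, which
the tests check against hand-solved matrices, exhaustively over all 15
five-taxon topologies, and against an independent neighbor-joining
implementation.

Bootstrap supports follow Felsenstein's recipe (resample columns with
replacement to the original length, rebuild, count bipartitions), with
the per-replicate RNG stream indexed by replicate number so supports are
invariant to taxon order.  A tree's mean support is the unweighted mean
over its nontrivial bipartitions.

Maximum-likelihood inference is deliberately an *adapter*, not a
re-implementation: `external_ml_adapter` drives an external GTR+Gamma
program (FastTree by default) and parses its Newick output, reporting a
distinct, explicit error when the backend is absent.  Every pipeline
stage accepts either builder.

## The one-event-per-site experiment

From a clonal (mutation-only) simulation, every informative site — a
column with ≥ 2 alleles each carried by ≥ 2 strains — is disturbed
exactly once: a strain is picked uniformly among all strains and
reassigned to a different allele present at the site (uniform among the
others when multi-allelic).  Picking among *all* strains, rather than
only carriers of one allele, is the simplest reading of "pick one of
these strains"; the experiment's headline behaviour is insensitive to
this choice because either rule changes exactly one cell per site.
Congruence is measured against the generating tree on the pre-shuffle
informative-site set, before and after.  At desk scale (20 taxa, 200 kb,
internal branches ≥ 0.005 subs/site) roughly 92–93% of informative sites
become incongruent, yet the re-inferred tree recovers the generating
topology — each disturbed column still groups all but one strain
correctly, and the signal accumulates across tens of thousands of sites.

## Robustness sweep and statistics

`run_grid` runs one simulate → infer → score cycle per requested `ρ`
(study default 0–10 in steps of 0.1, i.e. 101 points), deriving each
cell's RNG stream from the master seed and the cell index, recording both
the configured `ρ` and the realized `r/m`, and recording failed cells as
missing rather than aborting.  `spearman` uses average ranks with an
exact permutation p-value for n ≤ 9 and the t-approximation beyond;
`wilcoxon_signed_rank` drops zero differences and uses an exact,
tie-aware signed-rank distribution (dynamic-programming convolution over
doubled ranks) up to 25 pairs, then a normal approximation with
continuity and tie corrections.  Both are checked against brute-force
enumerations.  `correlate_robustness` correlates per-species mean TTS
with bootstrap support of the true tree, mean branch length, dN/dS, GC
and taxon count, skipping absent or constant covariates and excluding
missing values pairwise.  dN/dS is consumed as an externally provided
covariate; the simulator is neutral, so selection-linked correlations are
exercised on constructed monotone fixtures rather than simulated
mechanistically.

## Synthetic species

The generator draws pure-birth (Yule) topologies with 13–55 taxa and
rescales branch lengths so the mean root-to-tip depth hits a target
divergence drawn log-uniformly from 0.005–0.05 subs/site; GC ∈
[0.25, 0.70], `κ` ∈ [1, 4], codon rates with the third position fastest,
dN/dS log-uniform in [0.04, 0.4] as a label.  Genome length defaults to
100 kb; tests use 4–200 kb.  These choices emulate the statistical spread
of real bacterial core-genome panels, not any particular species; what
passing tests show is that the *pipeline* behaves as designed under
realistic parameter ranges, not that any given real species behaves
identically — real core genomes add rate heterogeneity, selection,
biased gene conversion and population structure that the model omits.
`unresolved_variant` shrinks a chosen fraction of the shortest internal
branches toward zero to create the poorly-resolved regime;
`fixture_panel` spreads a small panel across the ranges with a Latin
hypercube (taxon counts on an even grid so panel members have distinct
sizes).

## Numerical and scale choices

All randomness flows from a single integer seed per operation
(`numpy.random.default_rng`; derived streams use `[seed, index]` keys);
identical seeds give bit-identical results, including the full event log.
Node depths are rounded to 12 decimals when building time intervals so
that equal depths (ultrametric nodes) coincide exactly.  Problem sizes in
the tests — 13–20 taxa, 4–200 kb genomes, 5–20 seeds per claim — are
chosen so each claim is decided by thousands of informative sites or
events while the whole suite stays interactive; the qualitative
behaviours being asserted (perfect clonal recovery, monotone degradation,
near-total incongruence with recovered topology) are insensitive to
further scaling up, which the generator supports directly.
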