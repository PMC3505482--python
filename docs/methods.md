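# Methods

`cypclass` classifies cytochrome P450 (CYP) proteins the way large fungal
CYPome databases are built: candidate selection by domain evidence, an
all-vs-all similarity graph filtered on E-value and query coverage, Markov
clustering (MCL), identity-threshold nomenclature, clan inference from
cluster co-membership, and functional-category transfer from characterized
proteins. This note records the model choices, parameter meanings, numerical
details and known limitations.

## Candidate selection

A protein enters the CYPome when at least one of its domain-scanner hits to
an accepted P450 accession spans 25 residues or more. Shorter hits are
labelled *questionable*: they frequently arise from spurious partial matches,
so proteins supported only by questionable hits are reported for manual
review rather than accepted or silently discarded. Review decisions are an
explicit allowlist (`promote`); no heuristic auto-promotion exists. The
shipped accession list (`DEFAULT_P450_DOMAINS`, 16 InterPro entries) is
configuration — domain-database releases reorganize P450 entries over time,
and the list should track the scanner actually used.

## Similarity graph

For each directed (query, subject) pair, HSPs are pooled: the pair's E-value
is the best over its HSPs, and its *query coverage* is the length of the
merged union of the query-side HSP intervals divided by the query length.
Merging (rather than summing raw HSP lengths) keeps coverage in [0, 100] and
makes it a true "fraction of the query matched" — the quantity the coverage
filter is meant to bound. Coverage is query-side only; subject-side coverage
is deliberately out of scope.

A directed pair survives when E-value <= `e_max` and coverage >= `cov_min`
(defaults 1e-50 and 60%, the optimized combination; see the sweep below).
An undirected edge requires *both* directions to survive — the reciprocal
search contract — and is weighted by the mean of the two directions'
`-log10(E)`, with E = 0 mapped to a cap of 200. The cap and transform are the
classic Tribe-MCL convention; the mean (rather than max) keeps the weight
symmetric in contract, not just in storage. Every node carries a self-loop
weighted by its strongest incident edge (1.0 when isolated), added before
normalization; self-loops damp MCL's period-two oscillations on bipartite-ish
structures and guarantee nonzero columns.

## Markov clustering

MCL alternates expansion (`M @ M`) and inflation (entrywise power `r`
followed by column renormalization) on the column-stochastic transition
matrix. Flow concentrates within dense regions; the limit matrix is
essentially idempotent and is read as a partition: rows with positive
diagonal (attractors) seed clusters over their positively-weighted columns.
MCL can in principle emit overlapping clusters; because the classification
requires a disjoint partition, a node claimed by several attractors goes to
the cluster where its mass is largest, ties breaking to the lowest cluster
index, and duplicate attractor rows therefore collapse to one cluster.
Unclaimed nodes become singletons.

Numerical choices: pruning threshold 1e-5 (entries below it are dropped
after inflation, then columns renormalized), convergence when the maximum
absolute entry change falls below 1e-8, iteration cap 200 (hitting it warns
and flags the clustering's provenance rather than failing). These are common
MCL practice and are exposed as `MclParams`; none is sensitive on the graphs
this package targets, where edge weights within families saturate at the cap
and convergence typically takes a handful of iterations.

The inflation factor tunes granularity: higher inflation cuts weaker
flow paths, giving tighter clusters. Inflation 1 is rejected as degenerate
(no inflation means no clustering). The test suite cross-checks the sparse
implementation against an independently written dense-arithmetic MCL on
random graphs across inflation 1.5–5.

## Parameter sweep

Clusterings are scored by the fraction of singlet clusters plus the fraction
of mega clusters (> 100 members), both over cluster counts; equal weights by
default with configurable weights, and a protein-mass variant behind a flag.
This objective formalizes the empirical goal of uniform grouping: a loose
graph collapses into mega clusters, an over-stringent one shatters into
singlets, and the optimum plane lies between. The sweep enumerates the grid
lexicographically (E-value decades 1e-10..1e-100, coverages 20–100% by 10,
integer inflations 2–5 → 360 combinations on the full grid), rebuilding the
graph per (E-value, coverage) and re-running MCL per inflation. Ties on the
objective break deterministically: lower mega fraction, then higher coverage,
then lower E-value ceiling, then higher inflation — preferring the more
conservative graph.

## Nomenclature

Family membership follows the classical identity thresholds: strictly
greater than 40% pairwise identity for a family, strictly greater than 55%
for a subfamily. Identity is computed from a Needleman–Wunsch global
alignment (BLOSUM62, gap open 10, gap extend 0.5) as identical columns over
the full alignment length, counting gap columns in the denominator (a
gapless-columns mode exists). Selenocysteine is scored as X because BLOSUM62
carries no U row. Assignment is best-hit, not single-linkage: identity is
not transitive, and best-hit matches nomenclature-database practice. Ties
break to the lexicographically smallest reference id; when the best hit from
a different family trails the winner by at most 2 identity points, that
family is reported as runner-up rather than silently dropped.

Clans are inferred per cluster from the known clans of member families:
none known → a novel clan (`CLAN_<cluster_id>`) for multi-member or
multi-family clusters, or an orphan clan named after the family for singlet
clusters; exactly one known → that clan absorbs the cluster's clanless
families; two or more → a merge *proposal* listing all of them, never
auto-applied (merging named clans is a curation decision). Each family
appears in exactly one clan record; clusters are processed in cluster-id
order and a family already claimed by an earlier cluster is not re-listed.
Clusters containing no named families produce no clan record.

## Functional transfer

Characterized proteins carry one of three categories: primary metabolism
(housekeeping biosynthesis such as sterol pathways), secondary metabolism
(natural-product pathways), and xenobiotic metabolism (detoxification).
Queries inherit the union of categories of every curated reference they hit
at E <= 1e-100 — any-hit union semantics, because genuinely multi-functional
matches occur and are informative. Families take the union over members;
only single-category ("uniquely annotated") families vote at the clan
level, so a family spanning secondary and xenobiotic metabolism is flagged
non-unique and excluded from clan assignment. Propagation is idempotent and
monotone in both the curated set and the E-value cutoff.

## CYPome statistics

Cluster-size histograms satisfy the conservation identities (sizes sum to
node count, counts to cluster count). The power-law exponent of the size
distribution is estimated by ordinary least squares on (log10 size,
log10 count) over sizes with positive counts. This estimator is simple and
matches how such distributions are usually displayed, but it is only
consistent where per-size counts are large: a long tail of count-one sizes
flattens the slope. The built-in partition sampler used for self-testing
therefore truncates its support to sizes the sample can populate (default
max size 20, where 5,000 draws at exponent 2.5 still expect ~2 clusters per
size); maximum-likelihood exponent estimation is the noted alternative for
real, heavy-tailed data. CYPome fractions are plain percentages of proteome
size; phyletic profiles are family × species count matrices with taxon
roll-ups, and conserved families are those with at least one member in every
listed species.

## Synthetic study conditions

The generator plants disjoint families: one independent random ancestor per
family, members derived by i.i.d. substitutions (uniform over the 19
alternative residues) at per-site rate r = 1 − sqrt(target identity), since
two independently mutated copies agree at a site with probability
(1 − r)² + r²/19 ≈ target. Realized mean within-family identity is measured
after generation and must land within ±5 points of the target. Members are
assigned round-robin to species, species cycle through three fungal subphylum
labels. Defaults: five families of ten, 450-residue sequences (typical P450
length), 80% within-family identity against a 25% between-family ceiling —
between-family identity is chance-level (~6%) because ancestors are
independent.

Hit tables are emulated, not searched: every pair is Smith–Waterman-scored
(BLOSUM62, 10/0.5) and the score converted via the Karlin–Altschul formula
E = k·m·n·exp(−λS) with standard gapped-BLOSUM62 constants (λ = 0.267,
k = 0.041), computed in log space so extreme scores underflow to an exact
zero. The constants need only rank pairs plausibly — they are not a model of
any particular search tool's composition-based statistics. By default
members carry no indels, so coverage sits near 100%; an optional deletion
mode exercises the coverage filter.

What the generator does *not* emulate: phylogenetic rate heterogeneity,
domain architecture, alignment-dependent E-value corrections, paralog
gradients between the family thresholds, or assembly artifacts. Passing the
planted-recovery tests therefore demonstrates the pipeline's correctness and
determinism, not its behavior on the continuous similarity structure of real
proteomes, where parameter choice genuinely matters.

Acceptance-level checks run at reduced scale — e.g. twenty replicates of
four planted families of five members at 300 residues — chosen as the
smallest problems that still exercise every filter and the reciprocity,
clustering and recovery behavior end to end.

## Pipeline and reproducibility

The `run` command wires filter → graph → cluster → (nomenclature, function,
stats) from a flat YAML config validated against each module's invariants
before any stage runs. Output tables carry provenance headers (tool version
and parameters; no timestamps), so identical config and inputs yield
byte-identical artifacts; `--resume-from` restarts at a named stage reusing
earlier artifacts. Any stage failure aborts naming the stage and the
offending input.

## Known limitations

- Family assignment approximates search-tool identities with global
  alignment; near-threshold cases (a fraction of a percent around 40/55)
  can differ from a BLAST-derived identity.
- Clan inference trusts cluster co-membership as a proxy for monophyly;
  phylogenetic validation of clans is out of scope.
- The emulated E-values share one (λ, k) pair across all pairs; real
  search tools adjust for composition and gapping.
- The OLS power-law fit is descriptive, not a model-comparison test against
  lognormal or stretched-exponential alternatives.
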