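# cypclass

A classification toolkit for cytochrome P450 (CYP) superfamilies, built for
comparative genomicists assembling and curating CYPomes — the full P450
complement of a genome — across many species at once. It reimplements, as a
reusable library plus CLI, the pipeline used by large fungal/oomycete CYP
databases: select candidate P450s by domain evidence, build a filtered
reciprocal similarity graph from all-vs-all search hits, cluster it with
Markov clustering, tune the clustering parameters, name families and clans,
transfer functional categories from characterized proteins, and summarize
CYPome statistics.

## The method

**Graph.** From directed pairwise hits, a pair (q, s) is kept when its best
E-value ≤ `e_max` and its *query coverage* — the merged union of query-side
HSP intervals over the query length — is ≥ `cov_min`. An undirected edge
requires both directions to survive (reciprocal-search contract) and is
weighted w(q,s) = ½(−log₁₀E(q→s) − log₁₀E(s→q)), with E = 0 capped at 200.

**Clustering.** Markov clustering (MCL) on the column-stochastic matrix M:
repeat *expansion* M ← M·M and *inflation* M_ij ← M_ij^r / Σ_k M_kj^r until
convergence, then read clusters off the attractor rows. The inflation factor
r controls granularity. The optimized defaults are E-value ≤ 1e-50, coverage
≥ 60%, inflation 5; a sweep module scores any grid by the fraction of
singlet clusters plus the fraction of mega clusters (> 100 members) and
selects the minimizing combination.

**Nomenclature.** Pairwise identity from global alignment (BLOSUM62, gap
10/0.5): > 40% to a named reference assigns its family, > 55% also its
subfamily (both strict); anything else is a novel-family candidate. Clans —
presumed-monophyletic groups of families — are inferred from cluster
co-membership, producing known-clan extensions, novel clans, orphan clans,
and merge proposals.

**Function.** Proteins inherit the union of categories (primary / secondary
/ xenobiotic metabolism) of characterized references hit at E ≤ 1e-100;
families with a single category propagate it to their clan.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Generate a synthetic proteome with three planted families, then run the full
pipeline on it:

```sh
cypclass simulate --families 3 --sizes 8,8,8 --within 80 --between 25 \
    --seed 42 --out demo
# 24 proteins in 3 families -> demo

printf 'proteins: demo/proteins.fasta\nhits: demo/hits.tsv\nout_dir: demo/out\n' \
    > demo/pipeline.yaml
cypclass run --config demo/pipeline.yaml
# pipeline artifacts in demo/out
```

`demo/out/summary.json` then reads:

```json
{
  "converged": true,
  "cypome_fraction_pct": 100.0,
  "frac_mega": 0.0,
  "frac_singlet": 0.0,
  "n_candidates": 24,
  "n_clusters": 3,
  "n_proteins": 24,
  "objective": 0.0
}
```

The 24 proteins fall into exactly 3 clusters — the planted families — with
no singlet or mega clusters, so the sweep objective is 0. `clusters.tsv`,
`graph.tsv` and `histogram.tsv` in `demo/out/` carry the partition, the
weighted edge list, and the size distribution, each under a provenance
header; re-running the same config reproduces them byte-for-byte. With real
data you would start from your own FASTA and a 12-column tabular search
output instead of `simulate`, and add `references:`/`clan_map:` (for
nomenclature) and `curated_fasta:`/`curated_categories:` (for functional
transfer) to the config.

Individual stages are also exposed: `cypclass filter-domains`,
`build-graph`, `cluster`, `sweep`, `assign-families`, `infer-clans`,
`annotate-function`, `stats`, `convert`, `validate`.

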