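# oligorank

Network-constrained prioritization of **oligogenic variant combinations** in
personal genomes.

Most variant-prioritization tools rank variants one at a time, which
systematically under-ranks the causative variants of digenic and oligogenic
diseases: each variant on its own may look only moderately damaging, while
the *combination* — two or three variants in interacting genes — is what
causes disease. oligorank is for researchers and method developers studying
this problem: it ranks n-tuples of candidate variants jointly, using a
background gene-interaction network as a connectivity constraint, and ships
the spike-in benchmark machinery needed to evaluate such rankers.

## The model

Every variant *v* carries a phenotype-aware score σ(*v*) ∈ [0, 1] (from any
pathogenicity/phenotype classifier via a score table, or from the built-in
scorer that blends a pathogenicity value with Resnik best-match-average
semantic similarity between the patient's ontology terms and the gene's
phenotype annotations). Given an interaction network Υ, an n-tuple of
variants scores

```
score(v1, …, vn) = σ(v1) + … + σ(vn)   if the variants' genes form a
                                        connected subgraph of Υ
                 = 0                    otherwise
```

Compound heterozygotes (two alleles of one gene) are handled by adding a
self-loop to every node of Υ, so a repeated gene counts as interacting with
itself. Non-exonic variants are assigned their nearest gene. No variants
are filtered by allele frequency, quality or FILTER status. Enumeration of
tuples is exhaustive (O(n^k), the oracle) or by beam search: keep the
`beam_width` best partial tuples per level, extend each by variants whose
gene is adjacent to a gene already in the tuple, then re-check strict
connectivity on completed tuples. With a saturating beam width the beam
ranking is provably identical to the exhaustive one (this is tested).

## Worked example

`python examples/rank_variant_pairs.py` ranks all pairs from five candidate
variants over a small network in which KCNQ1–KCNE1 and MYO7A–USH2A
interact while SHROOM4 is isolated:

```
rank  score  members (gene)
   1  1.65   1:1010:A:G (KCNQ1), 1:1020:A:G (KCNE1)
   2  0.75   1:1030:A:G (MYO7A), 1:1040:A:G (USH2A)
```

The top pair scores 0.85 + 0.80 = 1.65 because its genes interact. The
single best-scoring variant (σ = 0.95, in SHROOM4) appears in *no* pair:
its gene has no interaction partners, so every pair containing it scores 0
and is dropped. That is the point of the method — a coherent pair of
moderate variants outranks a lone high scorer in an unconnected gene.

Other examples: `compound_heterozygotes.py` (self-loops admit a triallelic
combination, score 2.55), `phenotype_scoring.py` (σ(v) from ontology
similarity), `spike_in_benchmark.py` (Top-k recovery table over 50
synthetic cases plus a Mann-Whitney rank comparison).

## Benchmark harness

`oligorank.benchmark` generates seeded synthetic cases: a truth pair or
triple of causative variants, scored at a chosen quantile of the Beta(2, 5)
background score distribution, spiked into a background variant set over an
Erdős–Rényi gene network. `run_benchmark` reports Top-set / Top-10
recovery counts per method, both over all cases and over the
"interacting only" split (cases whose truth genes interact).
`compare_rank_distributions` runs an exact two-sided Mann-Whitney U test
between rank samples.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json` runs
the package's main computation from scratch: a 50-case spike-in benchmark
(100 background variants, 20 genes, connected truth pairs scored above all
background) evaluated with both single-variant and tuple ranking, plus a
per-case cross-check of beam search against the exhaustive oracle, writing
its JSON results to `--out`.
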