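# Methods

## The scoring model

A candidate disease module is an unordered set of k distinct variants
(k ∈ {1, 2, 3, …}; in practice 2 for digenic, 3 for triallelic disease).
Each variant v carries a score σ(v) ∈ [0, 1] expressing how likely it is to
be causative given its predicted pathogenicity and the match between the
patient's phenotype and the phenotypes associated with the variant's gene.
The tuple score is additive under a hard connectivity constraint:

    score(v1,…,vk) = Σ σ(vi)  if the genes of v1..vk form a connected
                               subgraph of the background network Υ
                   = 0        otherwise

Assumptions this encodes: (a) causative variants of an oligogenic disease
act through interacting genes — a disease module; (b) per-variant evidence
is independent enough for a sum to be a useful joint score; (c) a tuple in
non-interacting genes carries no joint information (score 0), so such
tuples are omitted from rankings by default. Zero-score tuples can be
retained with `include_disconnected=True`, but they are unordered evidence.

"Connected subgraph" is read as connectivity of the subgraph *induced* on
the tuple's distinct genes: every gene must be reachable from every other
through tuple genes only. The relaxed reading — connectivity through
intermediate genes outside the tuple — is available via `allow_bridges`,
default off, because direct interaction evidence is the stronger and more
interpretable claim. Beam search only guarantees equivalence with the
exhaustive oracle under the default (induced) reading.

Compound heterozygosity: a tuple may contain two variants of one gene.
This is admitted only when both (a) `allow_compound_het` is set and (b) the
network carries self-loops (`add_self_loops`), making "gene interacts with
itself" an explicit modelling step rather than a silent default.

## Gene assignment and input policy

Variants are assigned the gene whose interval contains them; variants
outside all intervals get the gene with the smallest distance to an
interval boundary on the same chromosome (ties: lexicographically smallest
gene id; chromosome without genes: no gene, which disconnects any tuple
containing the variant). Coordinates are 1-based inclusive; strand is
ignored. No filtering is applied on input — no minor-allele-frequency,
quality, or FILTER-status cuts — since variants of medium or common
frequency can still participate in oligogenic combinations. Multi-allelic
VCF records are split per ALT allele; genotypes come from the first
sample's GT field (absent → het).

## The built-in per-variant scorer

The scorer the method actually consumes is any map variant → [0, 1]; real
deployments should plug in classifier output via `load_scores`. The
built-in stand-in is

    σ(v) = w · pathogenicity + (1 − w) · similarity,    default w = 0.5

with similarity the Resnik best-match-average between the patient profile
and the gene's annotations: IC(t) = −ln(annotation frequency of t) over
the propagated corpus, per-pair similarity is the IC of the highest-IC
common ancestor, averaged best-match in both directions and normalized by
the corpus-wide maximum IC. Both term sets are reduced to their minimal
(most specific) elements before averaging, which makes a profile equal to
a gene's own term set at maximal IC score exactly 1 and keeps the measure
symmetric. w = 0.5 weights the two evidence sources equally in the absence
of any calibration data; the natural log and max-IC normalization are
conventional choices, both configurable at call sites.

## Beam search

Exhaustive enumeration scores all C(n, k) tuples and is the oracle; it
refuses instances above a candidate cap (default 2×10⁶). Beam search
(default width 1000) proceeds level by level: seed with the best single
variants whose genes are in the network, extend each partial tuple by
variants whose gene is adjacent to at least one gene already in it
(self-loop adjacency permits same-gene extension when compound-het is
allowed), deduplicate by member-id set, keep the `beam_width` best partial
sums, and finally re-score completed tuples with the strict connectivity
check. Extension-time connectivity is deliberately weaker than the final
check so that any connected module can be assembled along a spanning tree
of itself; since all σ ≥ 0, partial sums are monotone and per-level
truncation by partial sum is well-founded. A narrow beam can legitimately
lose tuples (e.g. width 1 seeds on an isolated high scorer and dies);
equivalence with the oracle is guaranteed — and tested over 200 random
instances — once the width is at least the number of candidate partials at
every level. Ties everywhere break lexicographically on sorted member
variant ids, so outputs are byte-deterministic.

## Synthetic benchmark: what it emulates, what it does not

`generate_case` emulates the spike-in protocol used to evaluate this class
of methods: insert a known causative pair/triple into a background variant
set and ask whether a method recovers the full combination at the top
("top set": all truth variants at ranks 1..|truth|; tuple criterion: the
rank-1 tuple equals the truth set) or within the top ten. Background
scores are drawn from Beta(2, 5) — right-skewed, most variants
benign-looking, occasional high-scoring distractors — standing in for the
empirical score distribution of a trained classifier, which is not
reproducible here. Genes are assigned uniformly; the network is
Erdős–Rényi (default 20 genes, edge probability 0.2); truth variants get
the score at a chosen Beta(2, 5) quantile (quantile 1.0 → score 1.0,
strictly above every background draw). `truth_connected=True` wires the
truth genes into a path; `False` severs all edges among them, guaranteeing
the case falls outside the "interacting only" split — the generator states
both worlds exactly rather than leaving them to chance. Everything is
reproducible from one master seed (per-case seeds are spawned below 2³¹).

A green benchmark therefore establishes the *mechanics* of recovery — the
additive score, the connectivity constraint, the split bookkeeping — under
a stated synthetic world. It does not establish performance on real
genomes: real score distributions, linkage between variants, network
ascertainment bias, and phenotype annotation quality are all outside the
generator.

## Rank comparisons

`compare_rank_distributions` is a two-sided Mann-Whitney U test, as used to
compare the rank distributions two methods give to causative variants.
Small samples (both n ≤ 20) without ties use the exact null distribution;
with ties, the exact permutation null is enumerated when C(m+n, m) ≤ 2×10⁵
(two-sided p = P(|U − mn/2| ≥ |U_obs − mn/2|)); otherwise the normal
approximation with tie correction applies. Exhaustive enumeration at the
n = 20 tie boundary (C(40, 20) ≈ 1.4×10¹¹) is infeasible, hence the cap.

## Numerical and degenerate-input choices

- Tuple additivity is exact floating-point summation over ≤ 3 terms; tests
  assert it to 1e−12.
- Similarity is clamped to [0, 1] against float drift after normalization.
- k = 1 degenerates to single-variant ranking restricted to in-network
  genes; an empty network yields an empty (header-only) ranking.
- Duplicate network edges keep the maximum confidence; input self-pairs
  are ignored (self-loops are an explicit operation).
- Variants absent from a score table score 0 with a logged warning rather
  than erroring, so partial classifier output degrades gracefully.

## Known limitations

- The built-in scorer is a stand-in, not a trained classifier; absolute σ
  values are only meaningful relative to the chosen corpus and weights.
- Beam search has no optimality guarantee at practical widths; it trades
  completeness for memory, and the dead-end behaviour at tiny widths is
  documented rather than patched.
- No variant normalization, phasing, structural variants, or
  mode-of-inheritance modelling (the default of no genotype-based
  filtering matches an "unknown inheritance" analysis).
- Scaling beyond k = 3 is untested territory; the candidate space grows as
  O(n^k) and beam width would need problem-specific tuning.
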