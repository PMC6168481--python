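"""Rank pairs of candidate variants under a network-connectivity constraint.

Builds a small set of scored variants and a gene-interaction network, then
ranks all variant pairs: a pair scores the sum of its per-variant scores if
its genes interact, and 0 (dropped) otherwise. Note how the top-scoring
single variant, sitting in a gene with no interaction partners, appears in
no ranked pair at all — the network constraint is doing the work.
"""

import networkx as nx

from oligorank import (
    InteractionNetwork,
    RankingConfig,
    ScoredVariant,
    Variant,
    rank_tuples_beam,
    rank_tuples_exhaustive,
)

# five candidate variants with phenotype-aware scores in [0, 1]
candidates = [
    ("SHROOM4", 0.95),  # highest score, but its gene is isolated below
    ("KCNQ1", 0.85),
    ("KCNE1", 0.80),
    ("MYO7A", 0.40),
    ("USH2A", 0.35),
]
svs = [
    ScoredVariant(Variant(chrom="1", pos=1000 + 10 * i, ref="A", alt="G"), gene, score)
    for i, (gene, score) in enumerate(candidates)
]

# background interaction network: two interacting pairs, one isolated gene
g = nx.Graph()
g.add_edge("KCNQ1", "KCNE1")
g.add_edge("MYO7A", "USH2A")
g.add_node("SHROOM4")
net = InteractionNetwork(graph=g)

cfg = RankingConfig(k=2, beam_width=100)
ranked = rank_tuples_beam(svs, net, cfg)

print("rank  score  members (gene)")
for rank, t in enumerate(ranked, start=1):
    members = ", ".join(f"{sv.id} ({sv.gene})" for sv in t.variants)
    print(f"{rank:>4}  {t.score:.2f}   {members}")

# the exhaustive oracle agrees whenever the beam is wide enough
exh = rank_tuples_exhaustive(svs, net, cfg)
assert [(t.ids, t.score) for t in exh] == [(t.ids, t.score) for t in ranked]
print()
print("The KCNQ1+KCNE1 pair (1.65) leads because both genes interact;")
print("the 0.95 variant in isolated SHROOM4 cannot join any connected pair.")
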