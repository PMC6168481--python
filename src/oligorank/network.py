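"""The background gene-interaction network and tuple connectivity queries.

The network is an undirected gene graph with optional per-edge confidence in
[0, 1]. Edge lists are read in the STRING protein-links dialect (two ids
plus an optional integer combined score 0-1000). Compound-heterozygote
combinations — two variant alleles of the same gene — are supported by
adding a self-loop to every node, which makes a repeated gene count as
"interacting with itself".
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

__all__ = [
    "InteractionNetwork",
    "load_network",
    "add_self_loops",
    "is_connected_tuple",
]


@dataclass
class InteractionNetwork:
    """Undirected gene graph with optional per-edge confidence.

    Wraps a :class:`networkx.Graph`; an adjacency dict of sets is cached for
    the hot connectivity path used during tuple enumeration.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    self_loops_enabled: bool = False
    _adj: Optional[dict[str, set[str]]] = field(default=None, repr=False, compare=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def confidence(self, a: str, b: str) -> Optional[float]:
        data = self.graph.get_edge_data(a, b)
        if data is None:
            return None
        return data.get("confidence")

    def adjacency(self) -> dict[str, set[str]]:
        """Node → set of neighbours (a self-looped node neighbours itself)."""
        if self._adj is None:
            self._adj = {n: set(self.graph.adj[n]) for n in self.graph.nodes}
        return self._adj

    def has_self_loop(self, gene: str) -> bool:
        return self.graph.has_edge(gene, gene)


def load_network(
    path: str | os.PathLike,
    min_confidence: float = 0.0,
    id_map: str | os.PathLike | Mapping[str, str] | None = None,
) -> InteractionNetwork:
    """Load a whitespace/tab-separated edge list in the STRING dialect.

    Each line is ``gene_a gene_b [combined_score]`` with the combined score
    an integer in [0, 1000]; scores are divided by 1000 to give a
    confidence in [0, 1]. Edges below ``min_confidence`` are dropped,
    duplicate edges are collapsed keeping the maximum confidence, and
    self-pairs in the input are ignored (self-loops are only introduced by
    :func:`add_self_loops`). An optional two-column id-mapping file (or
    dict) translates protein ids to gene ids before edges are built.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")

    mapping: Optional[Mapping[str, str]] = None
    if id_map is not None:
        if isinstance(id_map, Mapping):
            mapping = id_map
        else:
            mapping = {}
            with open(id_map, "rt") as fh:
                for line_no, line in enumerate(fh, start=1):
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    fields = line.split()
                    if len(fields) != 2:
                        raise ValueError(f"{id_map}: line {line_no}: expected 2 columns")
                    mapping[fields[0]] = fields[1]

    best: dict[tuple[str, str], Optional[float]] = {}
    with open(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}: line {line_no}: expected 2 or 3 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            if mapping is not None:
                a = mapping.get(a, a)
                b = mapping.get(b, b)
            conf: Optional[float] = None
            if len(fields) == 3:
                try:
                    raw = int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {line_no}: score {fields[2]!r} is not an integer") from exc
                if not 0 <= raw <= 1000:
                    raise ValueError(f"{path}: line {line_no}: score {raw} outside [0, 1000]")
                conf = raw / 1000.0
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in best:
                best[key] = conf
            else:
                prev = best[key]
                # collapse duplicates keeping max confidence; a scored edge
                # outranks an unscored duplicate
                if prev is None:
                    best[key] = conf
                elif conf is not None and conf > prev:
                    best[key] = conf

    g = nx.Graph()
    for (a, b), conf in best.items():
        if conf is not None and conf < min_confidence:
            continue
        if conf is None and min_confidence > 0.0:
            continue
        if conf is None:
            g.add_edge(a, b)
        else:
            g.add_edge(a, b, confidence=conf)
    return InteractionNetwork(graph=g)


def add_self_loops(net: InteractionNetwork) -> InteractionNetwork:
    """Return a copy of the network with a self-edge on every node.

    Self-loops extend tuple ranking to compound-heterozygote combinations:
    a gene carrying two variant alleles is then treated as connected to
    itself. Idempotent; existing edges are unchanged.
    """
    g = net.graph.copy()
    for n in list(g.nodes):
        g.add_edge(n, n)
    return InteractionNetwork(graph=g, self_loops_enabled=True)


def is_connected_tuple(
    genes: Iterable[str],
    net: InteractionNetwork,
    allow_bridges: bool = False,
) -> bool:
    """Decide whether a gene multiset forms a connected subgraph of the network.

    True iff (a) every distinct gene is a node of the network, (b) the
    subgraph induced on the distinct genes is connected (a single distinct
    gene is trivially connected), and (c) any gene occurring more than once
    in the multiset — a compound-heterozygote combination — carries a
    self-loop.

    With ``allow_bridges=True`` the relaxed reading is used: the genes need
    only lie in one connected component of the full network, so genes
    outside the tuple may bridge them. The default, stricter reading
    requires direct interaction evidence within the tuple itself.
    """
    gene_list = list(genes)
    if not gene_list:
        raise ValueError("empty gene multiset")
    adj = net.adjacency()
    distinct = set(gene_list)
    if not distinct <= adj.keys():
        return False
    # compound-het rule: a repeated gene needs a self-loop
    if len(gene_list) != len(distinct):
        counts: dict[str, int] = {}
        for g in gene_list:
            counts[g] = counts.get(g, 0) + 1
        for g, c in counts.items():
            if c > 1 and g not in adj[g]:
                return False
    if len(distinct) == 1:
        return True
    if allow_bridges:
        # BFS in the full network from one tuple gene until all are reached
        target = set(distinct)
        start = next(iter(distinct))
        seen = {start}
        frontier = [start]
        target.discard(start)
        while frontier and target:
            nxt: list[str] = []
            for u in frontier:
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        target.discard(w)
                        nxt.append(w)
            frontier = nxt
        return not target
    # induced-subgraph connectivity via BFS restricted to the tuple's genes
    start = next(iter(distinct))
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u] & distinct:
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        frontier = nxt
    return seen == distinct
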