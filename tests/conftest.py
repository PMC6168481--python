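"""Shared fixtures: toy ontology, annotations, networks and variant factories.

All fixtures are generated programmatically; nothing is read from checked-in
data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from oligorank.network import InteractionNetwork
from oligorank.phenotype import AnnotationSet, Ontology, ScoredVariant
from oligorank.variants import Variant

import networkx as nx


def make_variant(i: int, chrom: str = "1", genotype: str = "het") -> Variant:
    """Deterministic distinct variants indexed by i."""
    return Variant(chrom=chrom, pos=100 + 10 * i, ref="A", alt="G", genotype=genotype)


def make_scored(i: int, gene: str | None, score: float) -> ScoredVariant:
    return ScoredVariant(variant=make_variant(i), gene=gene, score=score)


def make_network(edges, self_loops: bool = False, nodes=()) -> InteractionNetwork:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    net = InteractionNetwork(graph=g)
    if self_loops:
        from oligorank.network import add_self_loops

        net = add_self_loops(net)
    return net


@pytest.fixture
def toy_ontology() -> Ontology:
    """Five terms: R root, A and B below R, C and D below A."""
    return Ontology(
        terms=frozenset({"R", "A", "B", "C", "D"}),
        parents={
            "R": frozenset(),
            "A": frozenset({"R"}),
            "B": frozenset({"R"}),
            "C": frozenset({"A"}),
            "D": frozenset({"A"}),
        },
    )


@pytest.fixture
def toy_annotations() -> AnnotationSet:
    """Four genes annotated to leaves/inner terms of the toy ontology."""
    return AnnotationSet(
        gene_terms={
            "g1": frozenset({"C"}),
            "g2": frozenset({"D"}),
            "g3": frozenset({"B"}),
            "g4": frozenset({"A"}),
        }
    )


@pytest.fixture
def deep_ontology() -> Ontology:
    """Seven terms, two branches of different depth for similarity tests.

    R -> A -> C -> E, R -> A -> D, R -> B -> F
    """
    return Ontology(
        terms=frozenset({"R", "A", "B", "C", "D", "E", "F"}),
        parents={
            "R": frozenset(),
            "A": frozenset({"R"}),
            "B": frozenset({"R"}),
            "C": frozenset({"A"}),
            "D": frozenset({"A"}),
            "E": frozenset({"C"}),
            "F": frozenset({"B"}),
        },
    )


@pytest.fixture
def deep_annotations() -> AnnotationSet:
    return AnnotationSet(
        gene_terms={
            "gx": frozenset({"E"}),
            "gy": frozenset({"D", "F"}),
            "gz": frozenset({"B"}),
        }
    )


def random_instance(rng: np.random.Generator, max_variants: int = 30, max_genes: int = 15):
    """A random ranking instance: scored variants plus an ER gene network.

    Some variants get no gene, some genes are shared between variants, so
    gene-missing and compound-het edge cases appear naturally.
    """
    n_var = int(rng.integers(5, max_variants + 1))
    n_genes = int(rng.integers(3, max_genes + 1))
    genes = [f"G{i}" for i in range(n_genes)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    p = float(rng.uniform(0.1, 0.6))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p:
                g.add_edge(genes[i], genes[j])
    svs = []
    for i in range(n_var):
        gene = None if rng.random() < 0.1 else genes[int(rng.integers(0, n_genes))]
        svs.append(make_scored(i, gene, float(rng.random())))
    return svs, InteractionNetwork(graph=g)
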