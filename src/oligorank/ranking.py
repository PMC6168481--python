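"""Tuple scoring and ranking: the core network-constrained prioritization.

A candidate disease module is an unordered set of k distinct variants. Its
score is

    score(v_1, ..., v_k) = sigma(v_1) + ... + sigma(v_k)

when the genes harbouring the variants form a connected subgraph of the
background interaction network, and 0 otherwise. Disconnected tuples carry
no ranking information and are dropped by default.

Two enumeration strategies are provided. ``rank_tuples_exhaustive`` scores
every k-subset — worst-case O(n^k), usable as a brute-force oracle on small
instances. ``rank_tuples_beam`` builds tuples incrementally, keeping only
the ``beam_width`` best partial tuples per level and extending each by
variants whose gene is adjacent to a gene already in the partial tuple;
with a saturating beam width it reproduces the exhaustive ranking exactly.
Extension-time connectivity is deliberately relaxed (adjacent to any member)
so that connected modules can be assembled edge by edge; a strict
induced-subgraph connectivity check is re-applied to every completed tuple.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Optional, Sequence

from oligorank.network import InteractionNetwork, is_connected_tuple
from oligorank.phenotype import ScoredVariant

__all__ = [
    "ScoredTuple",
    "RankingConfig",
    "score_tuple",
    "rank_variants",
    "rank_tuples_exhaustive",
    "rank_tuples_beam",
    "write_tuples_tsv",
]

DEFAULT_CANDIDATE_CAP = 2_000_000


@dataclass(frozen=True)
class ScoredTuple:
    """An unordered tuple of scored variants in canonical (id-sorted) form."""

    variants: tuple[ScoredVariant, ...]
    score: float
    connected: bool

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sv.id for sv in self.variants)

    @property
    def genes(self) -> tuple[Optional[str], ...]:
        """Gene multiset of the members (sorted, None last)."""
        return tuple(sorted((sv.gene for sv in self.variants), key=lambda g: (g is None, g)))


@dataclass(frozen=True)
class RankingConfig:
    """Knobs of tuple enumeration.

    k is the module size (number of variants per tuple); beam_width bounds
    memory in beam search; allow_compound_het admits same-gene tuples
    (which additionally need self-loops in the network to score non-zero);
    include_disconnected keeps zero-score tuples in the output.
    """

    k: int = 2
    beam_width: int = 1000
    allow_compound_het: bool = False
    include_disconnected: bool = False
    allow_bridges: bool = False
    candidate_cap: int = DEFAULT_CANDIDATE_CAP

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.beam_width < 1:
            raise ValueError(f"beam_width must be >= 1, got {self.beam_width}")


def score_tuple(
    t: Sequence[ScoredVariant],
    net: InteractionNetwork,
    allow_bridges: bool = False,
) -> ScoredTuple:
    """Score one tuple: sum of member scores if connected, else 0.

    Any member without an assigned gene, or with a gene absent from the
    network, makes the tuple disconnected. Members must be distinct.
    """
    if not t:
        raise ValueError("empty tuple")
    members = tuple(sorted(t, key=lambda sv: sv.id))
    ids = [sv.id for sv in members]
    if len(set(ids)) != len(ids):
        raise ValueError(f"tuple members must be distinct variants, got {ids}")
    genes = [sv.gene for sv in members]
    if any(g is None for g in genes):
        connected = False
    else:
        connected = is_connected_tuple(genes, net, allow_bridges=allow_bridges)
    score = sum(sv.score for sv in members) if connected else 0.0
    return ScoredTuple(variants=members, score=score, connected=connected)


def rank_variants(svs: Iterable[ScoredVariant]) -> list[ScoredVariant]:
    """Rank single variants by descending score.

    Ties break by (chrom, pos, ref, alt) ascending; the returned list's
    1-based positions are the ranks (no shared ranks).
    """
    return sorted(
        svs,
        key=lambda sv: (
            -sv.score,
            sv.variant.chrom,
            sv.variant.pos,
            sv.variant.ref,
            sv.variant.alt,
        ),
    )


def _sort_tuples(tuples: list[ScoredTuple]) -> list[ScoredTuple]:
    """Descending score, ties by lexicographic sorted member ids."""
    return sorted(tuples, key=lambda st: (-st.score, st.ids))


def rank_tuples_exhaustive(
    svs: Sequence[ScoredVariant],
    net: InteractionNetwork,
    cfg: RankingConfig = RankingConfig(),
) -> list[ScoredTuple]:
    """Score every k-subset of the variants — the brute-force oracle.

    Same-gene combinations are enumerated only when compound-heterozygote
    tuples are allowed. Tuples scoring 0 are dropped unless
    ``include_disconnected``. Refuses instances above the candidate cap;
    use beam search there instead.
    """
    svs = list(svs)
    n = len(svs)
    if cfg.k <= n and comb(n, cfg.k) > cfg.candidate_cap:
        raise ValueError(
            f"C({n}, {cfg.k}) = {comb(n, cfg.k)} exceeds the candidate cap "
            f"{cfg.candidate_cap}; use rank_tuples_beam for instances this large"
        )
    out: list[ScoredTuple] = []
    for combo in combinations(svs, cfg.k):
        genes = [sv.gene for sv in combo if sv.gene is not None]
        if not cfg.allow_compound_het and len(set(genes)) != len(genes):
            continue
        st = score_tuple(combo, net, allow_bridges=cfg.allow_bridges)
        if st.score == 0.0 and not cfg.include_disconnected:
            continue
        out.append(st)
    return _sort_tuples(out)


def rank_tuples_beam(
    svs: Sequence[ScoredVariant],
    net: InteractionNetwork,
    cfg: RankingConfig = RankingConfig(),
) -> list[ScoredTuple]:
    """Beam-search enumeration of connected variant tuples.

    Level 1 seeds the beam with the ``beam_width`` highest-scoring variants
    whose gene is in the network. Each subsequent level extends every beam
    member by every variant whose gene is adjacent to at least one gene
    already in the partial tuple (self-loop adjacency permits same-gene
    extension when compound-heterozygote tuples are allowed), deduplicates
    partial tuples by member-id set, and keeps the ``beam_width`` best
    partial sums. Completed tuples are re-scored with the strict
    induced-subgraph connectivity check and returned in the same order as
    the exhaustive ranking. A small beam legitimately loses tuples; a beam
    width at least the number of candidate partials at every level makes
    the output identical to :func:`rank_tuples_exhaustive`.
    """
    svs = list(svs)
    adj = net.adjacency()
    in_net = [sv for sv in svs if sv.gene is not None and sv.gene in adj]

    # gene -> variants in that gene, for adjacency-driven extension
    by_gene: dict[str, list[ScoredVariant]] = {}
    for sv in in_net:
        by_gene.setdefault(sv.gene, []).append(sv)

    def partial_key(members: tuple[ScoredVariant, ...]) -> frozenset[str]:
        return frozenset(sv.id for sv in members)

    def truncate(partials: dict[frozenset[str], tuple[tuple[ScoredVariant, ...], float]]):
        ordered = sorted(
            partials.values(),
            key=lambda p: (-p[1], tuple(sorted(sv.id for sv in p[0]))),
        )
        return ordered[: cfg.beam_width]

    # level 1: singleton partial tuples
    level: dict[frozenset[str], tuple[tuple[ScoredVariant, ...], float]] = {
        frozenset((sv.id,)): ((sv,), sv.score) for sv in in_net
    }
    beam = truncate(level)

    for _ in range(1, cfg.k):
        nxt: dict[frozenset[str], tuple[tuple[ScoredVariant, ...], float]] = {}
        for members, total in beam:
            member_ids = {sv.id for sv in members}
            member_genes = {sv.gene for sv in members}
            # candidate genes adjacent to any gene already in the tuple
            neigh: set[str] = set()
            for g in member_genes:
                neigh |= adj[g]
            for g in neigh:
                if g in member_genes and not cfg.allow_compound_het:
                    continue
                for sv in by_gene.get(g, ()):
                    if sv.id in member_ids:
                        continue
                    key = frozenset(member_ids | {sv.id})
                    if key in nxt:
                        continue
                    nxt[key] = (members + (sv,), total + sv.score)
        beam = truncate(nxt)

    out: list[ScoredTuple] = []
    for members, _total in beam:
        st = score_tuple(members, net, allow_bridges=cfg.allow_bridges)
        if st.score == 0.0 and not cfg.include_disconnected:
            continue
        out.append(st)
    return _sort_tuples(out)


def write_tuples_tsv(
    tuples: Sequence[ScoredTuple],
    path: str | os.PathLike,
    header_meta: Optional[dict] = None,
) -> None:
    """Write ranked tuples as TSV: rank, score, members, connected flag.

    ``header_meta`` (e.g. version/seed/config) is serialized into a single
    commented header line so runs are auditable and byte-reproducible.
    """
    with open(path, "wt") as fh:
        if header_meta:
            meta = " ".join(f"{k}={v}" for k, v in sorted(header_meta.items()))
            fh.write(f"# {meta}\n")
        fh.write("rank\tscore\tmembers\tconnected\n")
        for rank, st in enumerate(tuples, start=1):
            members = ";".join(
                f"{sv.id}|{sv.gene if sv.gene is not None else '.'}|{sv.score:.6f}"
                for sv in st.variants
            )
            fh.write(f"{rank}\t{st.score:.6f}\t{members}\t{int(st.connected)}\n")


def config_hash(cfg: RankingConfig) -> str:
    """Short stable hash of a ranking configuration, for output headers."""
    text = (
        f"k={cfg.k};beam_width={cfg.beam_width};"
        f"allow_compound_het={cfg.allow_compound_het};"
        f"include_disconnected={cfg.include_disconnected};"
        f"allow_bridges={cfg.allow_bridges}"
    )
    return hashlib.sha1(text.encode()).hexdigest()[:12]
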