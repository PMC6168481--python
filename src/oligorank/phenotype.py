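"""Per-variant scoring: pathogenicity blended with phenotype semantic similarity.

Each variant receives a score sigma(v) in [0, 1]. Production users plug in
scores from a trained variant-pathogenicity classifier via
:func:`load_scores`; the built-in scorer is an explicit, simplified
stand-in that combines a supplied pathogenicity value with Resnik
best-match-average semantic similarity between the patient's phenotype
profile and the candidate gene's phenotype annotations:

    sigma(v) = w * pathogenicity + (1 - w) * similarity,   default w = 0.5

Similarity uses information content IC(t) = -ln(p(t)) over an annotation
corpus, normalized by the corpus-wide maximum IC so results lie in [0, 1].
The ontology reader handles the OBO subset actually needed here: [Term]
stanzas with id / is_a / is_obsolete tags.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from oligorank.variants import Variant, VariantSet

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "AnnotationSet",
    "PhenotypeProfile",
    "ScoredVariant",
    "read_obo",
    "read_annotations",
    "propagate_annotations",
    "information_content",
    "semantic_similarity",
    "score_variant",
    "load_scores",
]


@dataclass(frozen=True)
class Ontology:
    """A directed acyclic is-a hierarchy of phenotype terms.

    ``parents`` maps each term to its direct parents; roots have an empty
    parent set. Stands in for phenotype vocabularies such as HPO or MP.
    """

    terms: frozenset[str]
    parents: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for term, ps in self.parents.items():
            if term not in self.terms:
                raise ValueError(f"parent map references unknown term {term!r}")
            missing = ps - self.terms
            if missing:
                raise ValueError(f"term {term!r} has unknown parents {sorted(missing)}")
        if not self.terms:
            return
        self._check_acyclic()
        if not self.roots:
            raise ValueError("ontology has no root terms (cycle through every term?)")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t: str, stack: list[str]) -> None:
            st = state.get(t)
            if st == 1:
                return
            if st == 0:
                raise ValueError(f"cycle in ontology involving term {t!r}")
            state[t] = 0
            for p in self.parents.get(t, ()):  # DFS up the is-a edges
                visit(p, stack)
            state[t] = 1

        for t in self.terms:
            visit(t, [])

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive parent closure of a term (memoized)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        cache: dict[str, frozenset[str]] = self.__dict__.setdefault("_anc_cache", {})

        def closure(t: str) -> frozenset[str]:
            hit = cache.get(t)
            if hit is not None:
                return hit
            out = {t}
            for p in self.parents.get(t, ()):
                out |= closure(p)
            fs = frozenset(out)
            cache[t] = fs
            return fs

        return closure(term)


@dataclass(frozen=True)
class AnnotationSet:
    """Gene → set of ontology terms (gene-to-phenotype associations)."""

    gene_terms: Mapping[str, frozenset[str]]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_terms)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())


@dataclass(frozen=True)
class PhenotypeProfile:
    """The patient's phenotype as a set of ontology terms."""

    terms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))


@dataclass(frozen=True)
class ScoredVariant:
    """A variant with its assigned gene and score sigma(v) in [0, 1]."""

    variant: Variant
    gene: Optional[str]
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def id(self) -> str:
        return self.variant.id


def read_obo(path: str | os.PathLike) -> Ontology:
    """Read an OBO-format ontology, honouring only id / is_a / is_obsolete.

    Trailing ``! comment`` text after an is_a target is stripped; obsolete
    terms are skipped entirely.
    """
    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    cur_id: Optional[str] = None
    cur_parents: set[str] = set()
    cur_obsolete = False
    in_term = False

    def flush() -> None:
        nonlocal cur_id, cur_parents, cur_obsolete
        if cur_id is not None and not cur_obsolete:
            terms.add(cur_id)
            parents.setdefault(cur_id, set()).update(cur_parents)
        cur_id, cur_parents, cur_obsolete = None, set(), False

    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term or not line:
                continue
            if line.startswith("id:"):
                cur_id = line[3:].strip()
            elif line.startswith("is_a:"):
                target = line[5:].split("!", 1)[0].strip()
                if target:
                    cur_parents.add(target)
            elif line.startswith("is_obsolete:") and "true" in line:
                cur_obsolete = True
    flush()
    # drop is_a links to terms that were obsolete/absent
    clean = {t: frozenset(p for p in ps if p in terms) for t, ps in parents.items()}
    return Ontology(terms=frozenset(terms), parents=clean)


def read_annotations(path: str | os.PathLike) -> AnnotationSet:
    """Read a gene-annotation TSV: gene_id, term_id (one pair per line)."""
    gene_terms: dict[str, set[str]] = {}
    with open(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {line_no}: expected 2 tab-separated columns")
            gene_terms.setdefault(fields[0], set()).add(fields[1])
    return AnnotationSet(gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()})


def propagate_annotations(ann: AnnotationSet, ont: Ontology) -> AnnotationSet:
    """Close every gene's term set under ancestors (true-path rule)."""
    out: dict[str, frozenset[str]] = {}
    for gene, terms in ann.gene_terms.items():
        closed: set[str] = set()
        for t in terms:
            if t not in ont.terms:
                raise ValueError(f"gene {gene!r} annotated to unknown term {t!r}")
            closed |= ont.ancestors(t)
        out[gene] = frozenset(closed)
    return AnnotationSet(gene_terms=out)


def information_content(ont: Ontology, ann: AnnotationSet) -> dict[str, float]:
    """Per-term information content from a propagated annotation corpus.

    IC(t) = -ln(n_t / N) where n_t is the number of genes annotated to t
    and N the number of annotated genes. Terms annotating every gene
    (e.g. roots after propagation) get IC 0; terms annotating no gene are
    absent from the returned table and therefore never serve as the
    most-informative common ancestor in similarity computation.
    """
    n_genes = len(ann.gene_terms)
    if n_genes == 0:
        raise ValueError("no annotated genes; information content is undefined")
    counts: dict[str, int] = {}
    for terms in ann.gene_terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n_genes) for t, c in counts.items()}


def _minimal_terms(terms: frozenset[str], ont: Ontology) -> frozenset[str]:
    """Drop terms that are proper ancestors of another member.

    On a propagated (ancestor-closed) set this recovers the original direct
    annotations, so best-match averaging is not diluted by redundant
    ancestor terms — without this, a gene's similarity to its own exact
    term set would fall below 1.
    """
    out = set(terms)
    for t in terms:
        for s in terms:
            if s != t and t in ont.ancestors(s):
                out.discard(t)
                break
    return frozenset(out)


def _best_match_one_direction(
    from_terms: Iterable[str],
    to_terms: frozenset[str],
    ont: Ontology,
    ic: Mapping[str, float],
    to_ancestors: frozenset[str],
) -> float:
    """Average over from_terms of the max-IC common ancestor with to_terms."""
    total = 0.0
    n = 0
    for t in from_terms:
        common = ont.ancestors(t) & to_ancestors
        best = 0.0
        for a in common:
            v = ic.get(a)
            if v is not None and v > best:
                best = v
        total += best
        n += 1
    return total / n if n else 0.0


def semantic_similarity(
    profile: PhenotypeProfile,
    gene: str,
    ont: Ontology,
    ann: AnnotationSet,
    ic: Optional[Mapping[str, float]] = None,
) -> float:
    """Resnik best-match-average similarity between a profile and a gene.

    For each profile term, take the maximum over the gene's terms of the IC
    of their highest-IC common ancestor; average over profile terms. Repeat
    with the roles swapped and take the mean of the two directions, then
    normalize by the corpus-wide maximum IC so the result lies in [0, 1].
    Both term sets are first reduced to their minimal elements (on a
    propagated set that recovers the direct annotations), so a profile
    equal to a gene's own term set at maximal IC scores exactly 1. A gene
    with no annotations scores 0. ``ann`` must be propagated.
    """
    if not profile.terms:
        raise ValueError("empty phenotype profile")
    if ic is None:
        ic = information_content(ont, ann)
    gene_terms = _minimal_terms(ann.terms_of(gene), ont)
    if not gene_terms:
        return 0.0
    max_ic = max(ic.values(), default=0.0)
    if max_ic == 0.0:
        return 0.0

    profile_terms = _minimal_terms(profile.terms, ont)
    profile_anc = frozenset().union(*(ont.ancestors(t) for t in profile_terms))
    gene_anc = frozenset().union(*(ont.ancestors(t) for t in gene_terms))
    fwd = _best_match_one_direction(profile_terms, gene_terms, ont, ic, gene_anc)
    rev = _best_match_one_direction(gene_terms, profile_terms, ont, ic, profile_anc)
    sim = 0.5 * (fwd + rev) / max_ic
    # guard against float drift out of [0, 1]
    return min(1.0, max(0.0, sim))


def score_variant(
    v: Variant,
    gene: Optional[str],
    pathogenicity: float,
    profile: PhenotypeProfile,
    ont: Ontology,
    ann: AnnotationSet,
    w: float = 0.5,
    ic: Optional[Mapping[str, float]] = None,
) -> ScoredVariant:
    """Blend pathogenicity and phenotype similarity into sigma(v).

    score = w * pathogenicity + (1 - w) * semantic_similarity; a variant
    without an assigned gene gets similarity 0. Monotone nondecreasing in
    both inputs for any fixed w in [0, 1].
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight w must lie in [0, 1], got {w}")
    if not 0.0 <= pathogenicity <= 1.0:
        raise ValueError(f"pathogenicity must lie in [0, 1], got {pathogenicity}")
    sim = 0.0 if gene is None else semantic_similarity(profile, gene, ont, ann, ic=ic)
    score = w * pathogenicity + (1.0 - w) * sim
    return ScoredVariant(variant=v, gene=gene, score=min(1.0, max(0.0, score)))


def load_scores(path: str | os.PathLike, vs: VariantSet) -> list[ScoredVariant]:
    """Attach precomputed scores (TSV: variant_id, score) to a variant set.

    This is the hook for real classifier output. Variants absent from the
    table are scored 0 with a logged warning; a score outside [0, 1] is an
    error.
    """
    table: dict[str, float] = {}
    with open(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {line_no}: expected 2 tab-separated columns")
            vid, raw = fields
            score = float(raw)
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}: line {line_no}: score {score} outside [0, 1]")
            table[vid] = score
    out: list[ScoredVariant] = []
    for v in vs:
        if v.id in table:
            score = table[v.id]
        else:
            logger.warning("variant %s absent from score table %s; scored 0", v.id, path)
            score = 0.0
        out.append(ScoredVariant(variant=v, gene=vs.gene_of.get(v.id), score=score))
    return out
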