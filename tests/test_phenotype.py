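"""Phenotype scoring: ontology closure, information content, similarity, sigma."""

from __future__ import annotations

import math

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from oligorank.phenotype import (
    AnnotationSet,
    Ontology,
    PhenotypeProfile,
    information_content,
    load_scores,
    propagate_annotations,
    read_obo,
    score_variant,
    semantic_similarity,
)
from oligorank.variants import VariantSet

from conftest import make_variant


# Frozen IC values for the toy corpus (4 genes; g1:C, g2:D, g3:B, g4:A
# propagated up R <- A <- {C,D}, R <- B): counts R:4, A:3, B:1, C:1, D:1.
TOY_IC = {
    "R": 0.0,
    "A": 0.2876820724517809,  # -ln(3/4)
    "B": 1.3862943611198906,  # -ln(1/4)
    "C": 1.3862943611198906,
    "D": 1.3862943611198906,
}


def brute_force_similarity(profile_terms, gene_terms, parents, ic):
    """Independent Resnik BMA: explicit loops over all common-ancestor pairs."""

    def ancestors(t):
        out = {t}
        for p in parents.get(t, ()):
            out |= ancestors(p)
        return out

    def mica(t1, t2):
        common = ancestors(t1) & ancestors(t2)
        vals = [ic[a] for a in common if a in ic]
        return max(vals, default=0.0)

    def one_way(src, dst):
        return sum(max(mica(s, d) for d in dst) for s in src) / len(src)

    max_ic = max(ic.values())
    return 0.5 * (one_way(profile_terms, gene_terms) + one_way(gene_terms, profile_terms)) / max_ic


class TestOntology:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Ontology(
                terms=frozenset({"A", "B"}),
                parents={"A": frozenset({"B"}), "B": frozenset({"A"})},
            )

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError):
            Ontology(terms=frozenset({"A"}), parents={"A": frozenset({"Z"})})

    def test_ancestors_reflexive_transitive(self, deep_ontology):
        assert deep_ontology.ancestors("E") == {"E", "C", "A", "R"}
        assert deep_ontology.ancestors("R") == {"R"}

    def test_obo_reader(self, tmp_path):
        p = tmp_path / "toy.obo"
        p.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: T:1\nname: root\n\n"
            "[Term]\nid: T:2\nis_a: T:1 ! root\n\n"
            "[Term]\nid: T:3\nis_a: T:2\nis_obsolete: true\n\n"
            "[Typedef]\nid: part_of\n"
        )
        ont = read_obo(p)
        assert ont.terms == {"T:1", "T:2"}
        assert ont.parents["T:2"] == {"T:1"}
        assert ont.roots == {"T:1"}


class TestPropagation:
    def test_closure(self, toy_ontology, toy_annotations):
        prop = propagate_annotations(toy_annotations, toy_ontology)
        assert prop.terms_of("g1") == {"C", "A", "R"}
        assert prop.terms_of("g3") == {"B", "R"}

    def test_root_annotation_is_fixpoint(self, toy_ontology):
        ann = AnnotationSet(gene_terms={"g": frozenset({"R"})})
        assert propagate_annotations(ann, toy_ontology).terms_of("g") == {"R"}

    def test_empty_annotations(self, toy_ontology):
        assert propagate_annotations(AnnotationSet(gene_terms={}), toy_ontology).gene_terms == {}

    def test_unknown_term_named_in_error(self, toy_ontology):
        ann = AnnotationSet(gene_terms={"g": frozenset({"NOPE"})})
        with pytest.raises(ValueError, match="NOPE"):
            propagate_annotations(ann, toy_ontology)


class TestInformationContent:
    def test_toy_table(self, toy_ontology, toy_annotations):
        prop = propagate_annotations(toy_annotations, toy_ontology)
        ic = information_content(toy_ontology, prop)
        assert ic == pytest.approx(TOY_IC)

    def test_one_in_four_closed_form(self, toy_ontology, toy_annotations):
        prop = propagate_annotations(toy_annotations, toy_ontology)
        ic = information_content(toy_ontology, prop)
        assert ic["B"] == pytest.approx(-math.log(0.25))

    def test_root_ic_zero(self, toy_ontology, toy_annotations):
        prop = propagate_annotations(toy_annotations, toy_ontology)
        assert information_content(toy_ontology, prop)["R"] == 0.0

    def test_no_genes_errors(self, toy_ontology):
        with pytest.raises(ValueError):
            information_content(toy_ontology, AnnotationSet(gene_terms={}))


class TestSemanticSimilarity:
    @pytest.fixture
    def corpus(self, deep_ontology, deep_annotations):
        prop = propagate_annotations(deep_annotations, deep_ontology)
        ic = information_content(deep_ontology, prop)
        return deep_ontology, prop, ic

    def test_matches_brute_force(self, corpus, deep_ontology, deep_annotations):
        ont, prop, ic = corpus
        parents = {t: set(ps) for t, ps in ont.parents.items()}
        for gene in prop.gene_terms:
            for profile_terms in [{"E"}, {"D", "F"}, {"B"}, {"E", "F"}]:
                got = semantic_similarity(PhenotypeProfile(frozenset(profile_terms)), gene, ont, prop, ic=ic)
                # the oracle works on the direct (pre-propagation) term sets
                expect = brute_force_similarity(
                    sorted(profile_terms), sorted(deep_annotations.gene_terms[gene]), parents, ic
                )
                assert got == pytest.approx(expect, abs=1e-12)

    def test_self_similarity_at_max_ic_is_one(self, corpus):
        ont, prop, ic = corpus
        # gx is the only gene annotated to E, so IC(E) attains the corpus maximum
        assert ic["E"] == max(ic.values())
        sim = semantic_similarity(PhenotypeProfile(frozenset({"E"})), "gx", ont, prop, ic=ic)
        assert sim == pytest.approx(1.0)

    def test_root_only_overlap_is_zero(self, corpus):
        ont, prop, ic = corpus
        # gz is annotated to B; profile D shares only R (IC 0) with branch B
        sim = semantic_similarity(PhenotypeProfile(frozenset({"D"})), "gz", ont, prop, ic=ic)
        assert sim == 0.0

    def test_unannotated_gene_scores_zero(self, corpus):
        ont, prop, ic = corpus
        assert semantic_similarity(PhenotypeProfile(frozenset({"E"})), "missing", ont, prop, ic=ic) == 0.0

    def test_empty_profile_errors(self, corpus):
        ont, prop, ic = corpus
        with pytest.raises(ValueError):
            semantic_similarity(PhenotypeProfile(frozenset()), "gx", ont, prop, ic=ic)

    def test_symmetry(self, corpus):
        """Swapping profile and gene annotation sets leaves similarity unchanged."""
        ont, prop, ic = corpus
        for gene_a, gene_b in [("gx", "gy"), ("gy", "gz"), ("gx", "gz")]:
            sim_ab = semantic_similarity(
                PhenotypeProfile(prop.terms_of(gene_a)), gene_b, ont, prop, ic=ic
            )
            sim_ba = semantic_similarity(
                PhenotypeProfile(prop.terms_of(gene_b)), gene_a, ont, prop, ic=ic
            )
            assert sim_ab == pytest.approx(sim_ba, abs=1e-12)

    def test_range(self, corpus):
        ont, prop, ic = corpus
        for gene in prop.gene_terms:
            for terms in [{"E"}, {"F"}, {"B", "D"}, {"R"}]:
                sim = semantic_similarity(PhenotypeProfile(frozenset(terms)), gene, ont, prop, ic=ic)
                assert 0.0 <= sim <= 1.0


class TestScoreVariant:
    @pytest.fixture
    def corpus(self, toy_ontology, toy_annotations):
        prop = propagate_annotations(toy_annotations, toy_ontology)
        return toy_ontology, prop

    def test_convex_combination(self, corpus):
        ont, prop = corpus
        profile = PhenotypeProfile(frozenset({"C"}))
        sv = score_variant(make_variant(0), "g1", 0.8, profile, ont, prop, w=1.0)
        assert sv.score == pytest.approx(0.8)  # w=1 degenerates to pathogenicity

    def test_arithmetic(self, corpus):
        ont, prop = corpus
        profile = PhenotypeProfile(frozenset({"B"}))
        # similarity(profile={B}, g3={B}) = 1 (B attains max IC); w=0.5 blends
        sv = score_variant(make_variant(0), "g3", 0.8, profile, ont, prop, w=0.5)
        assert sv.score == pytest.approx(0.9)

    def test_no_gene_means_zero_similarity(self, corpus):
        ont, prop = corpus
        profile = PhenotypeProfile(frozenset({"C"}))
        sv = score_variant(make_variant(0), None, 0.6, profile, ont, prop, w=0.5)
        assert sv.score == pytest.approx(0.3)

    def test_invalid_weight_errors(self, corpus):
        ont, prop = corpus
        with pytest.raises(ValueError):
            score_variant(make_variant(0), "g1", 0.5, PhenotypeProfile(frozenset({"C"})), ont, prop, w=1.5)

    @given(
        p1=st.floats(0, 1), p2=st.floats(0, 1), w=st.floats(0, 1)
    )
    @settings(
        max_examples=50,
        deadline=None,
        derandomize=True,
        # the corpus fixture is read-only, so sharing it across examples is safe
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_monotone_in_pathogenicity(self, corpus, p1, p2, w):
        ont, prop = corpus
        profile = PhenotypeProfile(frozenset({"C"}))
        lo, hi = sorted([p1, p2])
        s_lo = score_variant(make_variant(0), "g1", lo, profile, ont, prop, w=w).score
        s_hi = score_variant(make_variant(0), "g1", hi, profile, ont, prop, w=w).score
        assert s_lo <= s_hi + 1e-12


class TestLoadScores:
    def variant_set(self):
        return VariantSet(
            variants=tuple(make_variant(i) for i in range(3)),
            gene_of={make_variant(i).id: "A" for i in range(3)},
        )

    def test_full_table(self, tmp_path):
        vs = self.variant_set()
        p = tmp_path / "scores.tsv"
        p.write_text("".join(f"{vid}\t0.{i + 1}\n" for i, vid in enumerate(vs.ids)))
        svs = load_scores(p, vs)
        assert [sv.score for sv in svs] == pytest.approx([0.1, 0.2, 0.3])
        assert all(sv.gene == "A" for sv in svs)

    def test_missing_variant_scored_zero_with_warning(self, tmp_path, caplog):
        vs = self.variant_set()
        p = tmp_path / "scores.tsv"
        p.write_text(f"{vs.ids[0]}\t0.9\n{vs.ids[1]}\t0.5\n")
        with caplog.at_level("WARNING"):
            svs = load_scores(p, vs)
        assert svs[2].score == 0.0
        assert any(vs.ids[2] in rec.message for rec in caplog.records)

    def test_out_of_range_score_errors(self, tmp_path):
        vs = self.variant_set()
        p = tmp_path / "scores.tsv"
        p.write_text(f"{vs.ids[0]}\t1.3\n")
        with pytest.raises(ValueError, match="outside"):
            load_scores(p, vs)
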