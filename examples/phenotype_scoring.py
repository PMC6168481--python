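"""Score variants by blending pathogenicity with phenotype similarity.

Builds a miniature phenotype ontology and gene-annotation corpus, then
scores candidate variants for a patient presenting with deafness:
sigma(v) = w * pathogenicity + (1 - w) * similarity, where similarity is
Resnik best-match-average over the ontology, normalized to [0, 1].
"""

from oligorank import (
    AnnotationSet,
    Ontology,
    PhenotypeProfile,
    Variant,
    information_content,
    propagate_annotations,
    score_variant,
    semantic_similarity,
)

# a tiny phenotype ontology: root -> {ear, heart}; ear -> deafness
ont = Ontology(
    terms=frozenset({"P:root", "P:ear", "P:heart", "P:deafness", "P:arrhythmia"}),
    parents={
        "P:root": frozenset(),
        "P:ear": frozenset({"P:root"}),
        "P:heart": frozenset({"P:root"}),
        "P:deafness": frozenset({"P:ear"}),
        "P:arrhythmia": frozenset({"P:heart"}),
    },
)
ann = propagate_annotations(
    AnnotationSet(
        gene_terms={
            "MYO7A": frozenset({"P:deafness"}),
            "KCNQ1": frozenset({"P:arrhythmia"}),
            "TTN": frozenset({"P:heart"}),
        }
    ),
    ont,
)
ic = information_content(ont, ann)
patient = PhenotypeProfile(terms=frozenset({"P:deafness"}))

print("gene    similarity  pathogenicity  sigma")
for i, (gene, patho) in enumerate([("MYO7A", 0.6), ("KCNQ1", 0.6), ("TTN", 0.9)]):
    v = Variant(chrom="1", pos=100 + i, ref="A", alt="G")
    sim = semantic_similarity(patient, gene, ont, ann, ic=ic)
    sv = score_variant(v, gene, patho, patient, ont, ann, w=0.5, ic=ic)
    print(f"{gene:<7} {sim:>10.3f}  {patho:>13.2f}  {sv.score:.3f}")

print()
print("MYO7A matches the patient's phenotype exactly (similarity 1.0), so a")
print("moderately pathogenic MYO7A variant outscores a more damaging-looking")
print("variant in TTN, whose annotations only share ancestry with deafness")
print("at the uninformative root.")
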