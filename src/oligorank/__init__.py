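"""Network-constrained prioritization of oligogenic variant combinations.

oligorank ranks single variants and n-tuples of variants from a personal
genome by a phenotype-aware per-variant score sigma(v) in [0, 1]. A tuple's
score is the sum of its members' scores when the genes harbouring the
variants form a connected subgraph of a background gene-interaction network,
and 0 otherwise. Tuples are enumerated either exhaustively (the brute-force
oracle) or by beam search for tractability. A spike-in benchmark generator
and Top-k recovery harness emulate the evaluation protocol used for this
class of method: known causative variant combinations are inserted into a
background variant set and the methods are scored on how often they recover
the full combination at the top ranks.
"""

from oligorank.variants import (
    Variant,
    GeneModel,
    VariantSet,
    read_vcf,
    write_vcf,
    read_gene_model,
    assign_genes,
    spike_variants,
)
from oligorank.network import (
    InteractionNetwork,
    load_network,
    add_self_loops,
    is_connected_tuple,
)
from oligorank.phenotype import (
    Ontology,
    AnnotationSet,
    PhenotypeProfile,
    ScoredVariant,
    read_obo,
    read_annotations,
    propagate_annotations,
    information_content,
    semantic_similarity,
    score_variant,
    load_scores,
)
from oligorank.ranking import (
    ScoredTuple,
    RankingConfig,
    score_tuple,
    rank_variants,
    rank_tuples_exhaustive,
    rank_tuples_beam,
    write_tuples_tsv,
)
from oligorank.benchmark import (
    BenchmarkCase,
    RecoveryMetrics,
    generate_case,
    evaluate_single_ranking,
    evaluate_tuple_ranking,
    run_benchmark,
    compare_rank_distributions,
)
from oligorank import workflows

__version__ = "0.1.0"

__all__ = [
    "Variant",
    "GeneModel",
    "VariantSet",
    "read_vcf",
    "write_vcf",
    "read_gene_model",
    "assign_genes",
    "spike_variants",
    "InteractionNetwork",
    "load_network",
    "add_self_loops",
    "is_connected_tuple",
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
    "ScoredTuple",
    "RankingConfig",
    "score_tuple",
    "rank_variants",
    "rank_tuples_exhaustive",
    "rank_tuples_beam",
    "write_tuples_tsv",
    "BenchmarkCase",
    "RecoveryMetrics",
    "generate_case",
    "evaluate_single_ranking",
    "evaluate_tuple_ranking",
    "run_benchmark",
    "compare_rank_distributions",
    "workflows",
    "__version__",
]
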