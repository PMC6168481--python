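"""End-to-end workflows: score a VCF, rank tuples, run the benchmark.

These functions are the package's runnable entry points — thin glue over
the library modules that read the standard input formats, run one complete
analysis, and write an auditable TSV (a commented header line records the
package version, seed and a config hash, so identical inputs give
byte-identical outputs). They are what a pipeline or notebook calls; the
scripts in ``examples/`` show each one in use.
"""

from __future__ import annotations

import hashlib
import os
from typing import Mapping, Optional, Sequence

from oligorank import benchmark as bm
from oligorank.network import add_self_loops, load_network
from oligorank.phenotype import (
    PhenotypeProfile,
    ScoredVariant,
    information_content,
    load_scores,
    propagate_annotations,
    read_annotations,
    read_obo,
    score_variant,
    semantic_similarity,
)
from oligorank.ranking import (
    RankingConfig,
    config_hash,
    rank_tuples_beam,
    rank_tuples_exhaustive,
    rank_variants,
    write_tuples_tsv,
)
from oligorank.variants import assign_genes, read_gene_model, read_vcf

__all__ = ["score_workflow", "rank_workflow", "benchmark_workflow", "read_benchmark_config"]

_VERSION = "0.1.0"

DEFAULT_PATHOGENICITY = 0.5  # neutral placeholder when no pathogenicity table is given


def _load_table(path: str | os.PathLike, what: str) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {line_no}: expected 2 tab-separated columns")
            val = float(fields[1])
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{path}: line {line_no}: {what} {val} outside [0, 1]")
            out[fields[0]] = val
    return out


def score_workflow(
    vcf_path: str | os.PathLike,
    gene_model_path: str | os.PathLike,
    ontology_path: str | os.PathLike,
    annotations_path: str | os.PathLike,
    profile_terms: Sequence[str],
    out_path: str | os.PathLike,
    weight: float = 0.5,
    pathogenicity_path: Optional[str | os.PathLike] = None,
) -> list[ScoredVariant]:
    """Score every variant of a VCF and write a per-variant TSV.

    Output columns: variant id, assigned gene, pathogenicity input,
    phenotype similarity, and the blended score sigma. Pathogenicity comes
    from an optional variant_id→value TSV; absent variants get the neutral
    default 0.5.
    """
    if not profile_terms:
        raise ValueError("semantic scoring requires a nonempty phenotype profile")
    vs = assign_genes(read_vcf(vcf_path), read_gene_model(gene_model_path))
    ont = read_obo(ontology_path)
    ann = propagate_annotations(read_annotations(annotations_path), ont)
    ic = information_content(ont, ann)
    profile = PhenotypeProfile(terms=frozenset(profile_terms))
    patho = _load_table(pathogenicity_path, "pathogenicity") if pathogenicity_path else {}

    scored: list[ScoredVariant] = []
    rows: list[str] = []
    for v in vs:
        gene = vs.gene_of.get(v.id)
        p = patho.get(v.id, DEFAULT_PATHOGENICITY)
        sim = 0.0 if gene is None else semantic_similarity(profile, gene, ont, ann, ic=ic)
        sv = score_variant(v, gene, p, profile, ont, ann, w=weight, ic=ic)
        scored.append(sv)
        rows.append(
            f"{v.id}\t{gene if gene is not None else '.'}\t{p:.6f}\t{sim:.6f}\t{sv.score:.6f}"
        )

    with open(out_path, "wt") as fh:
        fh.write(f"# oligorank={_VERSION} weight={weight}\n")
        fh.write("variant_id\tgene\tpathogenicity\tsimilarity\tscore\n")
        for row in rows:
            fh.write(row + "\n")
    return scored


def rank_workflow(
    scores_path: str | os.PathLike,
    vcf_path: str | os.PathLike,
    network_path: str | os.PathLike,
    gene_model_path: str | os.PathLike,
    out_path: str | os.PathLike,
    k: int = 2,
    beam_width: int = 1000,
    exhaustive: bool = False,
    compound_het: bool = False,
    include_disconnected: bool = False,
    bridge_connectivity: bool = False,
    min_confidence: float = 0.0,
    seed: int = 0,
):
    """Rank variant tuples from a score table, VCF and network; write TSV.

    ``compound_het`` enables same-gene tuples by adding self-loops to the
    network. ``exhaustive`` switches from beam search to the brute-force
    oracle (refused above the candidate cap). With ``k=1`` the output is a
    single-variant ranking restricted to in-network genes.
    """
    vs = assign_genes(read_vcf(vcf_path), read_gene_model(gene_model_path))
    svs = load_scores(scores_path, vs)
    net = load_network(network_path, min_confidence=min_confidence)
    if compound_het:
        net = add_self_loops(net)
    cfg = RankingConfig(
        k=k,
        beam_width=beam_width,
        allow_compound_het=compound_het,
        include_disconnected=include_disconnected,
        allow_bridges=bridge_connectivity,
    )
    if exhaustive:
        ranked = rank_tuples_exhaustive(svs, net, cfg)
    else:
        ranked = rank_tuples_beam(svs, net, cfg)
    write_tuples_tsv(
        ranked,
        out_path,
        header_meta={"oligorank": _VERSION, "seed": seed, "config": config_hash(cfg)},
    )
    return ranked


def read_benchmark_config(path: str | os.PathLike) -> dict:
    """Read a flat key=value (or key<TAB>value) benchmark config file."""
    known = {
        "n_background": int,
        "n_genes": int,
        "edge_prob": float,
        "truth_size": int,
        "truth_score_quantile": float,
        "truth_connected": lambda s: s.strip().lower() in ("1", "true", "yes"),
        "n_cases": int,
        "top_n": int,
        "beam_width": int,
        "methods": lambda s: tuple(t.strip() for t in s.split(",") if t.strip()),
    }
    cfg: dict = {}
    bad: list[str] = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            else:
                key, _, val = line.partition("\t")
            key, val = key.strip(), val.strip()
            if key not in known:
                bad.append(key)
                continue
            cfg[key] = known[key](val)
    if bad:
        raise ValueError(f"invalid benchmark config keys: {sorted(bad)}")
    return cfg


def benchmark_workflow(
    config: Mapping | str | os.PathLike,
    seed: int,
    out_path: str | os.PathLike,
) -> list[bm.RecoveryMetrics]:
    """Run the spike-in benchmark from a config and write a metrics TSV.

    The output mirrors the usual recovery tables: one row per method per
    split with counts and percentages. Deterministic given the seed —
    identical runs are byte-identical.
    """
    if not isinstance(config, Mapping):
        config = read_benchmark_config(config)
    cfg = dict(config)
    n_cases = int(cfg.pop("n_cases", 50))
    top_n = int(cfg.pop("top_n", 10))
    methods = tuple(cfg.pop("methods", ("single_ranking", "tuple_ranking")))
    beam_width = int(cfg.pop("beam_width", 1000))

    unknown = set(cfg) - set(bm.DEFAULT_PARAMS)
    if unknown:
        raise ValueError(f"invalid benchmark config keys: {sorted(unknown)}")

    truth_size = int(cfg.get("truth_size", bm.DEFAULT_PARAMS["truth_size"]))
    rcfg = RankingConfig(k=truth_size, beam_width=beam_width)
    metrics = bm.run_benchmark(
        params=cfg,
        n_cases=n_cases,
        methods=methods,
        seed=seed,
        top_n=top_n,
        ranking_config=rcfg,
    )
    cfg_text = ";".join(f"{k}={v}" for k, v in sorted({**cfg, "n_cases": n_cases}.items()))
    cfg_hash = hashlib.sha1(cfg_text.encode()).hexdigest()[:12]
    with open(out_path, "wt") as fh:
        fh.write(f"# oligorank={_VERSION} seed={seed} config={cfg_hash}\n")
        fh.write("method\tsplit\ttop_set\ttop10_set\tn_cases\ttop_set_pct\ttop10_set_pct\n")
        for m in metrics:
            fh.write(
                f"{m.method}\t{m.split}\t{m.top_set}\t{m.top10_set}\t{m.n_cases}"
                f"\t{m.top_set_pct:.1f}\t{m.top10_set_pct:.1f}\n"
            )
    return metrics
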