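"""Variant representation, VCF input, gene assignment and spike-in construction.

Coordinates are 1-based inclusive throughout (VCF convention), for both
variant positions and gene intervals. No filtering of any kind is applied on
input — not by minor allele frequency, quality, or the FILTER column — so
that potentially interacting variants of medium-to-common frequency are
never discarded before ranking.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pysam

__all__ = [
    "Variant",
    "GeneModel",
    "VariantSet",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_gene_model",
    "assign_genes",
    "spike_variants",
]

GENOTYPES = ("het", "hom", "missing")


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed; names the offending line when known."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single-ALT genomic variant with a genotype call.

    The stable identifier ``chrom:pos:ref:alt`` keys variants everywhere in
    the package; it must be unique within a :class:`VariantSet`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = "het"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r} at {self.chrom}:{self.pos}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GeneModel:
    """Gene intervals: (gene_id, chrom, start, end), 1-based inclusive."""

    entries: tuple[tuple[str, str, int, int], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene_id, chrom, start, end in self.entries:
            if start > end:
                raise ValueError(f"gene {gene_id}: start {start} > end {end}")
            if gene_id in seen:
                raise ValueError(f"duplicate gene id {gene_id!r}")
            seen.add(gene_id)

    def by_chrom(self) -> dict[str, list[tuple[str, int, int]]]:
        out: dict[str, list[tuple[str, int, int]]] = {}
        for gene_id, chrom, start, end in self.entries:
            out.setdefault(chrom, []).append((gene_id, start, end))
        return out


@dataclass(frozen=True)
class VariantSet:
    """An ordered collection of variants with an optional variant→gene map."""

    variants: tuple[Variant, ...]
    gene_of: Mapping[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [v.id for v in self.variants]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids in set: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(v.id for v in self.variants)


def _genotype_from_gt(gt: Optional[tuple], alt_index: int) -> str:
    """Classify one ALT allele from a GT tuple of allele indices.

    alt_index is the 1-based ALT allele index within the record. Two copies
    of the allele → hom, one → het; a fully missing GT → missing; a called
    GT not carrying this allele defaults to het (the allele was still
    asserted by the record).
    """
    if gt is None:
        return "het"
    calls = [a for a in gt if a is not None]
    if not calls:
        return "missing"
    n = sum(1 for a in calls if a == alt_index)
    if n >= 2:
        return "hom"
    return "het"


def read_vcf(path: str | os.PathLike) -> VariantSet:
    """Read a VCF 4.x text file into a :class:`VariantSet`.

    One variant per ALT allele per record: multi-allelic records are split.
    Genotype comes from the first sample's GT field when present, otherwise
    every variant is recorded as het. Nothing is filtered — non-PASS
    records, any allele frequency, any quality are all retained.

    Raises
    ------
    VcfParseError
        On a malformed header or record (naming the 1-based line number for
        record-level failures) or an empty file.
    """
    path = os.fspath(path)
    if os.path.getsize(path) == 0:
        raise VcfParseError(f"{path}: empty file")

    # Count header lines so record errors can name their file line.
    n_header = 0
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break

    try:
        vf = pysam.VariantFile(path)
    except Exception as exc:  # pysam raises various error types for bad headers
        raise VcfParseError(f"{path}: malformed VCF header ({exc})") from exc

    variants: list[Variant] = []
    sample = next(iter(vf.header.samples), None)
    line_no = n_header
    records = vf.fetch() if vf.index is not None else vf
    it = iter(records)
    while True:
        line_no += 1
        try:
            rec = next(it)
        except StopIteration:
            break
        except Exception as exc:
            raise VcfParseError(f"{path}: malformed record at line {line_no} ({exc})") from exc
        gt = None
        if sample is not None:
            gt = rec.samples[sample].get("GT")
        alts = rec.alts or ()
        for i, alt in enumerate(alts, start=1):
            if alt is None or alt in (".", "*", "<NON_REF>"):
                continue
            try:
                variants.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotype=_genotype_from_gt(gt, i),
                    )
                )
            except ValueError as exc:
                raise VcfParseError(f"{path}: invalid record at line {line_no} ({exc})") from exc
    vf.close()
    return VariantSet(variants=tuple(variants))


def write_vcf(vs: VariantSet, path: str | os.PathLike) -> None:
    """Write a minimal single-sample VCF preserving chrom/pos/ref/alt/GT."""
    gt_repr = {"het": "0/1", "hom": "1/1", "missing": "./."}
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in vs):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for v in vs:
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gt_repr[v.genotype]}\n"
            )


def read_gene_model(path: str | os.PathLike) -> GeneModel:
    """Read a gene model TSV: gene_id, chrom, start, end (1-based inclusive).

    Lines starting with '#' are comments.
    """
    entries: list[tuple[str, str, int, int]] = []
    with open(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {line_no}: expected 4 tab-separated fields")
            gene_id, chrom, start, end = fields
            entries.append((gene_id, chrom, int(start), int(end)))
    return GeneModel(entries=tuple(entries))


def _distance(pos: int, start: int, end: int) -> int:
    """Distance from a position to an interval: 0 inside, else to the nearest boundary."""
    if start <= pos <= end:
        return 0
    return min(abs(pos - start), abs(pos - end))


def assign_genes(vs: VariantSet, gm: GeneModel) -> VariantSet:
    """Assign every variant its nearest gene.

    A variant inside a gene interval gets that gene; otherwise the gene on
    the same chromosome whose interval boundary is closest. A variant on a
    chromosome carrying no genes gets None. Ties are broken by the
    lexicographically smallest gene id, so the assignment is deterministic.
    This nearest-gene rule is what lets non-exonic variants participate in
    tuple ranking.
    """
    if not gm.entries:
        raise ValueError("gene model is empty")
    by_chrom = gm.by_chrom()
    gene_of: dict[str, Optional[str]] = {}
    for v in vs:
        genes = by_chrom.get(v.chrom)
        if not genes:
            gene_of[v.id] = None
            continue
        best = min(genes, key=lambda g: (_distance(v.pos, g[1], g[2]), g[0]))
        gene_of[v.id] = best[0]
    return replace(vs, gene_of=gene_of)


def spike_variants(
    background: VariantSet,
    causative: Sequence[Variant],
    genotype: Optional[str] = "het",
) -> tuple[VariantSet, frozenset[str]]:
    """Insert known causative variants into a background variant set.

    Emulates the construction of a synthetic case genome: the returned set
    holds all background variants plus all causative variants, re-sorted by
    (chrom, pos), and the causative ids are returned as the ground-truth
    set. Inserted variants default to a het genotype (``genotype=None``
    keeps each causative variant's own genotype).

    Raises
    ------
    ValueError
        If a causative variant id already exists in the background.
    """
    bg_ids = set(background.ids)
    spiked: list[Variant] = list(background.variants)
    truth: list[str] = []
    for v in causative:
        if genotype is not None:
            v = replace(v, genotype=genotype)
        if v.id in bg_ids:
            raise ValueError(f"causative variant {v.id} already present in background")
        bg_ids.add(v.id)
        spiked.append(v)
        truth.append(v.id)
    spiked.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    gene_of = dict(background.gene_of)
    return VariantSet(variants=tuple(spiked), gene_of=gene_of), frozenset(truth)
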