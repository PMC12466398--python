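"""Breed-specific fixed-variant cascade and candidate-gene prioritization.

The cascade keeps, in order: sites where every sample is homozygous for the
alternate allele (cohort AF = 1); sites covered by at least ``min_dp`` reads
in every sample; autosomal sites.  Genes harboring at least ``min_variants``
surviving exon variants of HIGH or MODERATE predicted impact are reported as
prioritized candidate genes (PCGs).  Stage counts are monotone by
construction and reported alongside the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_store import (
    GeneModel,
    VariantRecord,
    is_autosome,
    is_exonic_consequence,
    most_severe_per_gene,
)

log = logging.getLogger(__name__)

__all__ = [
    "FixedVariantReport",
    "PCGEntry",
    "fixed_alt_filter",
    "depth_filter",
    "autosome_filter",
    "pcg_select",
    "fixed_variant_cascade",
]


def fixed_alt_filter(
    records: Iterable[VariantRecord], allow_missing: bool = False
) -> list[VariantRecord]:
    """Sites where the alternate allele is fixed across the cohort.

    Strict reading by default: every sample must be a called homozygote for
    an alternate allele; a single missing genotype disqualifies the site.
    ``allow_missing=True`` relaxes to "all non-missing calls are hom-alt"
    (at least one call required).
    """
    out = []
    for rec in records:
        called = [(a, b) for a, b in rec.genotypes if a >= 0 and b >= 0]
        n_missing = rec.n_samples - len(called)
        if not called:
            continue
        all_hom_alt = all(a == b and a > 0 for a, b in called)
        if all_hom_alt and (allow_missing or n_missing == 0):
            out.append(rec)
    return out


def depth_filter(
    records: Iterable[VariantRecord], min_dp: int = 10
) -> list[VariantRecord]:
    """Sites supported by at least ``min_dp`` reads in every sample.

    The bound is inclusive ("at least").  A site with any missing DP is
    dropped and counted in the QC log (conservative).
    """
    out = []
    n_missing_dp = 0
    for rec in records:
        if not rec.depths or any(d is None for d in rec.depths):
            n_missing_dp += 1
            continue
        if all(d >= min_dp for d in rec.depths):
            out.append(rec)
    if n_missing_dp:
        log.info("depth_filter: %d sites dropped for missing DP", n_missing_dp)
    return out


def autosome_filter(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Sites on named autosomes (X and unplaced contigs excluded)."""
    return [rec for rec in records if is_autosome(rec.chrom)]


@dataclass(frozen=True)
class PCGEntry:
    """One prioritized candidate gene with its qualifying-variant count."""

    gene_id: str
    gene_symbol: str
    n_qualifying_variants: int
    chrom: str
    start: int | None = None
    end: int | None = None


def pcg_select(
    records: Sequence[VariantRecord],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel] | None = None,
    impact_set: frozenset[str] | set[str] = frozenset({"HIGH", "MODERATE"}),
    min_variants: int = 5,
    include_utr: bool = False,
) -> list[PCGEntry]:
    """Prioritized candidate genes from surviving fixed variants.

    Per gene, counts distinct variants whose (most severe per-gene)
    annotation is exonic with impact in ``impact_set``; genes reaching
    ``min_variants`` are returned sorted by chromosome then gene start.
    A variant annotated to several genes counts once for each.  Genes absent
    from the supplied models are still reported (coordinates unknown), with
    a warning.
    """
    gene_map: dict[str, GeneModel] = {}
    if genes:
        gene_list = genes.values() if isinstance(genes, Mapping) else genes
        gene_map = {g.gene_id: g for g in gene_list}

    counts: dict[str, int] = {}
    symbols: dict[str, str] = {}
    chrom_of: dict[str, str] = {}
    for rec in records:
        if not rec.annotations:
            continue
        for gene_id, ann in most_severe_per_gene(rec.annotations).items():
            if not gene_id:
                continue
            if ann.impact not in impact_set:
                continue
            if not is_exonic_consequence(ann.consequence, include_utr=include_utr):
                continue
            counts[gene_id] = counts.get(gene_id, 0) + 1
            symbols.setdefault(gene_id, ann.gene_symbol)
            chrom_of.setdefault(gene_id, rec.chrom)

    entries = []
    for gene_id, n in counts.items():
        if n < min_variants:
            continue
        model = gene_map.get(gene_id)
        if model is None and gene_map:
            log.warning("PCG %s not present in supplied gene models", gene_id)
        entries.append(
            PCGEntry(
                gene_id=gene_id,
                gene_symbol=(model.symbol if model else symbols.get(gene_id, "")),
                n_qualifying_variants=n,
                chrom=(model.chrom if model else chrom_of.get(gene_id, "")),
                start=model.start if model else None,
                end=model.end if model else None,
            )
        )

    def sort_key(e: PCGEntry):
        c = e.chrom
        return ((0, int(c)) if c.isdigit() else (1, 0), e.start or 0, e.gene_id)

    return sorted(entries, key=sort_key)


@dataclass
class FixedVariantReport:
    """Stage counts and survivors of the fixed-variant cascade."""

    stage_counts: dict[str, int]
    survivors: list[VariantRecord]
    pcgs: list[PCGEntry]

    def stage_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": k, "n_sites": v} for k, v in self.stage_counts.items()]
        )

    def pcg_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": e.gene_id,
                    "gene_symbol": e.gene_symbol,
                    "n_variants": e.n_qualifying_variants,
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                }
                for e in self.pcgs
            ],
            columns=["gene_id", "gene_symbol", "n_variants", "chrom", "start", "end"],
        )


def fixed_variant_cascade(
    records: Iterable[VariantRecord],
    genes: Sequence[GeneModel] | None = None,
    min_dp: int = 10,
    impact_set: frozenset[str] | set[str] = frozenset({"HIGH", "MODERATE"}),
    min_variants: int = 5,
    allow_missing: bool = False,
    include_utr: bool = False,
) -> FixedVariantReport:
    """Run the full cascade: AF=1 → depth → autosomes → PCG selection.

    The fixed-allele criterion is applied before the depth filter and the
    autosome restriction last, matching the narrated order of the analysis
    this reproduces.  Each stage's survivor set is a subset of the previous
    one.
    """
    records = list(records)
    fixed = fixed_alt_filter(records, allow_missing=allow_missing)
    deep = depth_filter(fixed, min_dp=min_dp)
    autosomal = autosome_filter(deep)
    pcgs = pcg_select(
        autosomal,
        genes=genes,
        impact_set=impact_set,
        min_variants=min_variants,
        include_utr=include_utr,
    )
    n_hm_exonic = sum(
        1
        for rec in autosomal
        if any(
            gid
            and ann.impact in impact_set
            and is_exonic_consequence(ann.consequence, include_utr=include_utr)
            for gid, ann in most_severe_per_gene(rec.annotations).items()
        )
    )
    stage_counts = {
        "input": len(records),
        "fixed_alt": len(fixed),
        "depth_pass": len(deep),
        "autosomal": len(autosomal),
        "exonic_high_moderate": n_hm_exonic,
        "pcg_genes": len(pcgs),
    }
    return FixedVariantReport(stage_counts=stage_counts, survivors=autosomal, pcgs=pcgs)
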