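"""Genotyping a cohort at known Mendelian-trait variants.

Given a catalog of trait-associated variants (OMIA-style: position, alleles,
gene, phenotype), the scan matches each catalog entry against the cohort VCF
after left-normalizing allele representations, counts heterozygous and
homozygous-alternate carriers, computes the folded minor allele frequency,
and flags variants segregating in the cohort (at least one copy of the
non-reference allele, but not fixed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .variant_store import VariantRecord, normalize_chrom

log = logging.getLogger(__name__)

__all__ = [
    "CatalogVariant",
    "MatchResult",
    "normalize_allele_pair",
    "read_catalog",
    "write_catalog",
    "builtin_horse_trait_catalog",
    "match_catalog",
    "maf_from_counts",
    "segregation_report",
]


@dataclass(frozen=True)
class CatalogVariant:
    """One known Mendelian-trait variant (OMIA-style entry)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str = ""
    gene_symbol: str = ""
    phenotype: str = ""
    omia_id: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        pos, ref, alt = normalize_allele_pair(self.pos, self.ref, self.alt)
        return (normalize_chrom(self.chrom), pos, ref, alt)


def normalize_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize a ref/alt pair: trim shared suffix, then shared prefix.

    Brings HGVS-style catalog coordinates and anchor-base VCF records onto a
    common representation so indel/delins entries compare positionally.
    At least one base is retained on each side.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def maf_from_counts(n_het: int, n_hom_alt: int, n_samples: int) -> float:
    """Folded minor allele frequency from diploid genotype counts.

    The alternate-allele count is ``n_het + 2*n_hom_alt`` over ``2*n_samples``
    non-missing alleles; the frequency is folded to min(freq, 1-freq).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if n_het + n_hom_alt > n_samples:
        raise ValueError("carrier counts exceed sample count")
    freq = (n_het + 2 * n_hom_alt) / (2 * n_samples)
    return min(freq, 1.0 - freq)


@dataclass
class MatchResult:
    """Genotype evidence for one catalog variant in the cohort."""

    variant: CatalogVariant
    matched: bool
    record: VariantRecord | None = None
    allele_mismatch: bool = False
    n_het: int = 0
    n_hom_alt: int = 0
    n_missing: int = 0
    n_samples: int = 0

    @property
    def n_called(self) -> int:
        return self.n_samples - self.n_missing

    @property
    def maf(self) -> float:
        if self.n_called == 0:
            return 0.0
        return maf_from_counts(self.n_het, self.n_hom_alt, self.n_called)

    @property
    def status(self) -> str:
        if not self.matched or (self.n_het + self.n_hom_alt) == 0:
            return "absent"
        if self.n_hom_alt == self.n_called and self.n_het == 0:
            return "fixed"
        return "segregating"


def match_catalog(
    catalog: Sequence[CatalogVariant], records: Iterable[VariantRecord]
) -> list[MatchResult]:
    """Match catalog entries against cohort records and count carriers.

    Matching is exact on (chromosome, position, alleles) after chromosome
    aliasing and left-normalization on both sides.  A record at the right
    position with incompatible alleles is still reported, flagged with
    ``allele_mismatch`` (counts are taken from the record's alternate
    allele).  Unmatched entries are reported as absent.
    """
    by_key: dict[tuple, VariantRecord] = {}
    by_pos: dict[tuple[str, int], VariantRecord] = {}
    for rec in records:
        if len(rec.alts) != 1:
            continue
        pos, ref, alt = normalize_allele_pair(rec.pos, rec.ref, rec.alts[0])
        chrom = normalize_chrom(rec.chrom)
        by_key[(chrom, pos, ref, alt)] = rec
        by_pos[(chrom, pos)] = rec

    out: list[MatchResult] = []
    for cv in catalog:
        key = cv.key
        rec = by_key.get(key)
        mismatch = False
        if rec is None:
            rec = by_pos.get(key[:2])
            if rec is not None:
                mismatch = True
                log.warning(
                    "catalog %s %s:%d matched on position only (allele mismatch)",
                    cv.gene_symbol, cv.chrom, cv.pos,
                )
        if rec is None:
            out.append(MatchResult(cv, matched=False))
            continue
        n_het = n_hom_alt = n_missing = 0
        for a, b in rec.genotypes:
            if a < 0 or b < 0:
                n_missing += 1
            elif a != b:
                n_het += 1
            elif a > 0:
                n_hom_alt += 1
        out.append(
            MatchResult(
                cv,
                matched=True,
                record=rec,
                allele_mismatch=mismatch,
                n_het=n_het,
                n_hom_alt=n_hom_alt,
                n_missing=n_missing,
                n_samples=rec.n_samples,
            )
        )
    return out


def segregation_report(
    catalog: Sequence[CatalogVariant],
    records: Iterable[VariantRecord],
    include_all: bool = False,
) -> pd.DataFrame:
    """Per-catalog-variant segregation table ordered by chromosome, position.

    By default only variants with at least one observed alternate allele are
    listed (segregating or fixed); ``include_all`` adds absent entries.
    Columns mirror the standard reporting layout: alleles, MAF, heterozygote
    count, variant type, gene and phenotype.
    """
    matches = match_catalog(catalog, records)
    rows = []
    for m in matches:
        if not include_all and m.status == "absent":
            continue
        cv = m.variant
        rows.append(
            {
                "chrom": normalize_chrom(cv.chrom),
                "pos": cv.pos,
                "a1": cv.alt,
                "a2": cv.ref,
                "maf": m.maf,
                "n_het": m.n_het,
                "n_hom_alt": m.n_hom_alt,
                "n_missing": m.n_missing,
                "variant_type": cv.variant_type,
                "gene": cv.gene_symbol,
                "phenotype": cv.phenotype,
                "omia_id": cv.omia_id,
                "status": m.status,
                "allele_mismatch": m.allele_mismatch,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "a1", "a2", "maf", "n_het", "n_hom_alt", "n_missing",
            "variant_type", "gene", "phenotype", "omia_id", "status", "allele_mismatch",
        ],
    )
    if not df.empty:
        chrom_rank = df["chrom"].map(lambda c: (0, int(c)) if c.isdigit() else (1, 0))
        df = (
            df.assign(_rank=chrom_rank)
            .sort_values(["_rank", "pos"], kind="mergesort")
            .drop(columns="_rank")
            .reset_index(drop=True)
        )
    return df


# ---------------------------------------------------------------------------
# Catalog TSV I/O and the built-in demonstration catalog
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "chrom", "pos", "ref", "alt", "variant_type", "gene_symbol", "phenotype", "omia_id",
]


def write_catalog(catalog: Iterable[CatalogVariant], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": cv.chrom,
                "pos": cv.pos,
                "ref": cv.ref,
                "alt": cv.alt,
                "variant_type": cv.variant_type,
                "gene_symbol": cv.gene_symbol,
                "phenotype": cv.phenotype,
                "omia_id": cv.omia_id,
            }
            for cv in catalog
        ],
        columns=_CATALOG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> list[CatalogVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    return [
        CatalogVariant(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            variant_type=str(getattr(r, "variant_type", "")),
            gene_symbol=str(getattr(r, "gene_symbol", "")),
            phenotype=str(getattr(r, "phenotype", "")),
            omia_id=str(getattr(r, "omia_id", "")),
        )
        for r in df.itertuples()
    ]


def builtin_horse_trait_catalog() -> list[CatalogVariant]:
    """Seven OMIA coat-colour/gait variants known to segregate in Kazakh horses.

    EquCab3.0 coordinates.  These are the classic MC1R chestnut, KIT white
    spotting, MITF splashed-white and DMRT3 gait variants; useful as a small
    built-in catalog for demonstrations and end-to-end tests.
    """
    return [
        CatalogVariant("3", 36979560, "C", "T", "missense", "MC1R",
                       "coat color, chestnut", "OMIA:001199-9796"),
        CatalogVariant("3", 79538738, "C", "T", "missense", "KIT",
                       "white spotting", "OMIA:000209-9796"),
        CatalogVariant("3", 79548220, "T", "C", "missense", "KIT",
                       "coat color, dominant white", "OMIA:000209-9796"),
        CatalogVariant("3", 79566881, "T", "C", "missense", "KIT",
                       "increased white spotting", "OMIA:000209-9796"),
        CatalogVariant("16", 21555811, "C", "AAAT", "deletion", "MITF",
                       "splashed white", "OMIA:000214-9796"),
        CatalogVariant("16", 21608936, "C", "T", "regulatory", "MITF",
                       "white splashing", "OMIA:000214-9796"),
        CatalogVariant("23", 22391254, "C", "A", "stop-gain", "DMRT3",
                       "gaitedness", "OMIA:001715-9796"),
    ]
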