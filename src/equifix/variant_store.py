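"""Variant, genotype and annotation data model with VCF I/O.

The in-memory substrate for every downstream statistic is a
:class:`GenotypeMatrix` of alternate-allele dosage codes {0, 1, 2} (−1 for
missing) over biallelic sites, plus per-site alternate-allele frequencies
recomputed from the genotypes themselves.  VCF parsing is delegated to
cyvcf2/htslib; VEP-style ``CSQ`` and SnpEff-style ``ANN`` consequence strings
are mapped onto a single :class:`AnnotationRecord` schema with impact classes
derived from the consequence term by the standard VEP severity mapping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "AnnotationRecord",
    "VariantRecord",
    "GenotypeMatrix",
    "GeneModel",
    "VcfParseError",
    "ConfigurationError",
    "EmptyMatrixError",
    "canonical_consequence",
    "impact_of",
    "is_exonic_consequence",
    "most_severe",
    "most_severe_per_gene",
    "parse_annotation_field",
    "read_vcf",
    "write_vcf",
    "classify_variant",
    "build_genotype_matrix",
    "normalize_chrom",
    "is_autosome",
    "read_gene_models",
    "write_gene_models",
    "AUTOSOMES",
    "CHROM_ALIASES",
]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; carries file/line context."""


class ConfigurationError(ValueError):
    """Raised for invalid user configuration (unknown samples, bad paths)."""


class EmptyMatrixError(ValueError):
    """Raised when site filtering leaves an empty genotype matrix."""


# ---------------------------------------------------------------------------
# Consequence ontology
# ---------------------------------------------------------------------------

# Sequence Ontology terms ordered from most to least severe (VEP ranking,
# restricted to the classes this pipeline reports).
CONSEQUENCE_SEVERITY: tuple[str, ...] = (
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
    "synonymous_variant",
    "stop_retained_variant",
    "coding_sequence_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)

_SEVERITY_RANK = {term: i for i, term in enumerate(CONSEQUENCE_SEVERITY)}

IMPACT_HIGH = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "frameshift_variant",
    }
)
IMPACT_MODERATE = frozenset(
    {
        "missense_variant",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering_variant",
    }
)
IMPACT_LOW = frozenset(
    {"synonymous_variant", "splice_region_variant", "stop_retained_variant"}
)

# Consequences that place the changed allele inside an exon.  UTR terms are
# deliberately not included here; callers that want them can add them.
EXONIC_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering_variant",
        "coding_sequence_variant",
        "stop_retained_variant",
        "non_coding_transcript_exon_variant",
    }
)

UTR_CONSEQUENCES = frozenset({"5_prime_UTR_variant", "3_prime_UTR_variant"})

# Short / legacy spellings accepted on input, mapped to canonical SO terms.
_CONSEQUENCE_ALIASES = {
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
    "frameshift": "frameshift_variant",
    "splice_region": "splice_region_variant",
    "splice_donor": "splice_donor_variant",
    "splice_acceptor": "splice_acceptor_variant",
    "stop_gained_variant": "stop_gained",
    "stop_lost_variant": "stop_lost",
    "start_lost_variant": "start_lost",
    "stop_retained": "stop_retained_variant",
    "protein_altering": "protein_altering_variant",
    "coding_sequence": "coding_sequence_variant",
    "non_coding_transcript_exon": "non_coding_transcript_exon_variant",
    "5'utr": "5_prime_UTR_variant",
    "3'utr": "3_prime_UTR_variant",
    "5_prime_utr_variant": "5_prime_UTR_variant",
    "3_prime_utr_variant": "3_prime_UTR_variant",
    "intergenic": "intergenic_variant",
    "intron": "intron_variant",
    "upstream": "upstream_gene_variant",
    "downstream": "downstream_gene_variant",
    "upstream_gene": "upstream_gene_variant",
    "downstream_gene": "downstream_gene_variant",
}


def canonical_consequence(term: str) -> str:
    """Map a consequence spelling onto its canonical SO term.

    Unknown terms are returned unchanged (downstream summaries bucket them
    under "other").
    """
    t = term.strip()
    if t in _SEVERITY_RANK:
        return t
    return _CONSEQUENCE_ALIASES.get(t.lower(), t)


def impact_of(consequence: str) -> str:
    """VEP impact class (HIGH/MODERATE/LOW/MODIFIER) for a consequence term."""
    c = canonical_consequence(consequence)
    if c in IMPACT_HIGH:
        return "HIGH"
    if c in IMPACT_MODERATE:
        return "MODERATE"
    if c in IMPACT_LOW:
        return "LOW"
    return "MODIFIER"


def is_exonic_consequence(consequence: str, include_utr: bool = False) -> bool:
    c = canonical_consequence(consequence)
    if include_utr and c in UTR_CONSEQUENCES:
        return True
    return c in EXONIC_CONSEQUENCES


def severity_rank(consequence: str) -> int:
    """Lower rank = more severe; unknown terms rank least severe."""
    return _SEVERITY_RANK.get(canonical_consequence(consequence), len(CONSEQUENCE_SEVERITY))


# ---------------------------------------------------------------------------
# Chromosome naming
# ---------------------------------------------------------------------------

# EquCab3.0 RefSeq accessions for the 31 autosomes and X.
CHROM_ALIASES: dict[str, str] = {
    f"NC_{9143 + i:06d}.3": str(i) for i in range(1, 32)
}
CHROM_ALIASES["NC_009175.3"] = "X"

AUTOSOMES = frozenset(str(i) for i in range(1, 32))


def normalize_chrom(name: str) -> str:
    """Canonicalize a chromosome label to "1".."31" / "X".

    Accepts plain numbers, "chr"/"ECA"/"ECC" prefixes and EquCab3.0 RefSeq
    accessions (with or without version).  Unknown labels pass through
    unchanged and are treated as unplaced contigs.
    """
    n = name.strip()
    for prefix in ("chr", "Chr", "CHR", "ECA", "ECC", "eca"):
        if n.startswith(prefix) and len(n) > len(prefix):
            n = n[len(prefix):]
            break
    if n in AUTOSOMES or n == "X":
        return n
    if n in CHROM_ALIASES:
        return CHROM_ALIASES[n]
    base = n.split(".")[0]
    for acc, canon in CHROM_ALIASES.items():
        if acc.split(".")[0] == base:
            return canon
    return name.strip()


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationRecord:
    """One functional consequence of a variant for one gene/transcript."""

    gene_id: str
    gene_symbol: str
    consequence: str
    impact: str
    is_exonic: bool

    @classmethod
    def from_consequence(
        cls, consequence: str, gene_id: str = "", gene_symbol: str = ""
    ) -> "AnnotationRecord":
        c = canonical_consequence(consequence)
        return cls(
            gene_id=gene_id,
            gene_symbol=gene_symbol,
            consequence=c,
            impact=impact_of(c),
            is_exonic=is_exonic_consequence(c),
        )


@dataclass
class VariantRecord:
    """One VCF site with per-sample genotypes/depths and annotations.

    ``genotypes`` holds diploid allele-index pairs with −1 marking a missing
    allele; ``depths`` holds per-sample DP with None for missing.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: list[str]
    genotypes: list[tuple[int, int]]
    depths: list[int | None] = field(default_factory=list)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    qual_info: dict | None = None
    vid: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.alts:
            raise ValueError("at least one alternate allele required")
        if self.depths and len(self.depths) != len(self.genotypes):
            raise ValueError("depths length must equal genotypes length")
        n_alleles = 1 + len(self.alts)
        for a, b in self.genotypes:
            if max(a, b) >= n_alleles:
                raise ValueError(
                    f"allele index out of range at {self.chrom}:{self.pos}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def alt_codes(self) -> np.ndarray:
        """Alternate-allele dosage per sample (biallelic sites only)."""
        if len(self.alts) != 1:
            raise ValueError("dosage codes defined for biallelic sites only")
        out = np.empty(len(self.genotypes), dtype=np.int8)
        for i, (a, b) in enumerate(self.genotypes):
            out[i] = MISSING if (a < 0 or b < 0) else a + b
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon intervals (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene body")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def symbol(self) -> str:
        return self.gene_symbol or self.gene_id


# ---------------------------------------------------------------------------
# Annotation string parsing (VEP CSQ / SnpEff ANN)
# ---------------------------------------------------------------------------

_DEFAULT_CSQ_FIELDS = ["Allele", "Consequence", "IMPACT", "Gene", "SYMBOL"]
_DEFAULT_ANN_FIELDS = [
    "Allele",
    "Annotation",
    "Annotation_Impact",
    "Gene_Name",
    "Gene_ID",
]


def _fields_from_description(desc: str) -> list[str] | None:
    if "Format:" in desc:
        fmt = desc.split("Format:", 1)[1].strip().strip('"').strip()
        return [f.strip() for f in fmt.split("|")]
    return None


def parse_annotation_field(
    raw: str, fields: Sequence[str] | None = None, dialect: str = "CSQ"
) -> list[AnnotationRecord]:
    """Parse a CSQ or ANN INFO value into AnnotationRecords.

    Multiple transcript entries (comma separated) and multiple consequence
    terms per entry ("&" joined, most severe kept) are supported.  Impact is
    always re-derived from the consequence term so the mapping is uniform
    regardless of what the annotator wrote.
    """
    if fields is None:
        fields = _DEFAULT_CSQ_FIELDS if dialect == "CSQ" else _DEFAULT_ANN_FIELDS
    fields = list(fields)

    def idx(*names: str) -> int | None:
        for n in names:
            if n in fields:
                return fields.index(n)
        return None

    i_csq = idx("Consequence", "Annotation")
    i_gene = idx("Gene", "Gene_ID")
    i_sym = idx("SYMBOL", "Gene_Name")

    out: list[AnnotationRecord] = []
    for entry in raw.split(","):
        parts = entry.split("|")
        if i_csq is None or i_csq >= len(parts):
            continue
        terms = [t for t in parts[i_csq].split("&") if t]
        if not terms:
            continue
        term = min(terms, key=severity_rank)
        gene = parts[i_gene] if i_gene is not None and i_gene < len(parts) else ""
        sym = parts[i_sym] if i_sym is not None and i_sym < len(parts) else ""
        out.append(AnnotationRecord.from_consequence(term, gene_id=gene, gene_symbol=sym))
    return out


def most_severe(annotations: Iterable[AnnotationRecord]) -> AnnotationRecord | None:
    """Single most severe annotation across all transcripts/genes."""
    anns = list(annotations)
    if not anns:
        return None
    return min(anns, key=lambda a: (severity_rank(a.consequence), a.gene_id))


def most_severe_per_gene(
    annotations: Iterable[AnnotationRecord],
) -> dict[str, AnnotationRecord]:
    """Reduce transcript-level annotations to one (most severe) per gene."""
    best: dict[str, AnnotationRecord] = {}
    for a in annotations:
        key = a.gene_id or a.gene_symbol
        cur = best.get(key)
        if cur is None or severity_rank(a.consequence) < severity_rank(cur.consequence):
            best[key] = a
    return best


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path, sample_subset: Sequence[str] | None = None
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF v4.x file.

    Missing DP or annotation fields yield empty fields, never failures.
    An unknown sample in ``sample_subset`` raises :class:`ConfigurationError`.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports header problems here
        raise VcfParseError(f"{path}: cannot open/parse VCF header: {exc}") from exc

    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in vcf.samples]
        if unknown:
            raise ConfigurationError(
                f"samples not present in {path}: {', '.join(unknown)}"
            )
        vcf.close()
        vcf = VCF(path, samples=list(sample_subset))

    csq_fields = ann_fields = None
    try:
        csq_fields = _fields_from_description(vcf.get_header_type("CSQ")["Description"])
    except KeyError:
        pass
    try:
        ann_fields = _fields_from_description(vcf.get_header_type("ANN")["Description"])
    except KeyError:
        pass

    line_no = 0
    try:
        for rec in vcf:
            line_no += 1
            gts = [
                (int(g[0]), int(g[1])) if len(g) >= 3 else (MISSING, MISSING)
                for g in rec.genotypes
            ]
            dp_arr = rec.format("DP")
            if dp_arr is None:
                depths: list[int | None] = [None] * len(gts)
            else:
                depths = [int(d) if d >= 0 else None for d in dp_arr.ravel()]

            annotations: list[AnnotationRecord] = []
            raw_csq = rec.INFO.get("CSQ")
            if raw_csq:
                annotations.extend(parse_annotation_field(raw_csq, csq_fields, "CSQ"))
            raw_ann = rec.INFO.get("ANN")
            if raw_ann:
                annotations.extend(parse_annotation_field(raw_ann, ann_fields, "ANN"))

            qual_info = {}
            for key, name in (("AF", "af"), ("BaseQRankSum", "base_q_rank_sum"), ("DP", "site_depth")):
                val = rec.INFO.get(key)
                if val is not None:
                    qual_info[name] = float(val) if not isinstance(val, tuple) else float(val[0])

            yield VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alts=list(rec.ALT),
                genotypes=gts,
                depths=depths,
                annotations=annotations,
                qual_info=qual_info or None,
                vid=rec.ID or ".",
            )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: malformed VCF record near data line {line_no + 1}: {exc}"
        ) from exc
    finally:
        vcf.close()


def vcf_sample_ids(path: str | Path) -> list[str]:
    """Sample names from a VCF header."""
    vcf = VCF(str(path))
    try:
        return list(vcf.samples)
    finally:
        vcf.close()


def _fmt_genotype(gt: tuple[int, int]) -> str:
    a, b = gt
    sa = "." if a < 0 else str(a)
    sb = "." if b < 0 else str(b)
    return f"{sa}/{sb}"


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    sample_ids: Sequence[str],
    contigs: Sequence[tuple[str, int]] | None = None,
    csq_fields: Sequence[str] | None = None,
    extra_header: Sequence[str] = (),
) -> None:
    """Write VariantRecords as an uncompressed VCF v4.2 text file.

    Annotations are emitted as a VEP-style CSQ string; per-site qual_info
    (AF, BaseQRankSum, site depth) goes to INFO.  Output is byte-deterministic
    for a fixed input sequence.
    """
    csq_fields = list(csq_fields or _DEFAULT_CSQ_FIELDS)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=equifix",
    ]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency, as called">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total site depth">',
        '##INFO=<ID=BQRS,Number=1,Type=Float,Description="BaseQRankSum-style site statistic">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: '
        + "|".join(csq_fields)
        + '">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines.extend(extra_header)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for rec in records:
            info_parts = []
            qi = rec.qual_info or {}
            if "af" in qi:
                info_parts.append(f"AF={qi['af']:.6g}")
            if "site_depth" in qi:
                info_parts.append(f"DP={int(qi['site_depth'])}")
            if "base_q_rank_sum" in qi:
                info_parts.append(f"BQRS={qi['base_q_rank_sum']:.4g}")
            if rec.annotations:
                entries = []
                for a in rec.annotations:
                    entry = {
                        "Allele": rec.alts[0],
                        "Consequence": a.consequence,
                        "IMPACT": a.impact,
                        "Gene": a.gene_id,
                        "SYMBOL": a.gene_symbol,
                    }
                    entries.append("|".join(entry.get(f, "") for f in csq_fields))
                info_parts.append("CSQ=" + ",".join(entries))
            info = ";".join(info_parts) if info_parts else "."

            has_dp = bool(rec.depths) and any(d is not None for d in rec.depths)
            if has_dp:
                fmt = "GT:DP"
                cols = [
                    _fmt_genotype(g) + ":" + ("." if d is None else str(d))
                    for g, d in zip(rec.genotypes, rec.depths)
                ]
            else:
                fmt = "GT"
                cols = [_fmt_genotype(g) for g in rec.genotypes]
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(rec.pos),
                        rec.vid,
                        rec.ref,
                        ",".join(rec.alts),
                        ".",
                        ".",
                        info,
                        fmt,
                    ]
                    + cols
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Classification and matrix construction
# ---------------------------------------------------------------------------


def _is_symbolic(allele: str) -> bool:
    return allele.startswith("<") or "[" in allele or "]" in allele or allele == "*"


def classify_variant(v: VariantRecord) -> tuple[str, str]:
    """Classify a site by allelicity and type.

    Returns ``(allelicity, vtype)`` with allelicity in {"biallelic",
    "multiallelic"} and vtype in {"SNP", "indel", "mixed"}.  Symbolic alleles
    (<DEL>, breakends) are classified "mixed" and excluded from matrices.
    """
    allelicity = "biallelic" if len(v.alts) == 1 else "multiallelic"
    if any(_is_symbolic(a) for a in v.alts):
        return allelicity, "mixed"
    kinds = set()
    for alt in v.alts:
        if len(v.ref) == 1 and len(alt) == 1:
            kinds.add("SNP")
        elif len(v.ref) != len(alt):
            kinds.add("indel")
        else:
            kinds.add("mixed")  # MNP-like: equal lengths > 1
    if kinds == {"SNP"}:
        return allelicity, "SNP"
    if kinds == {"indel"}:
        return allelicity, "indel"
    return allelicity, "mixed"


@dataclass
class GenotypeMatrix:
    """Samples × biallelic-sites alternate-allele dosage matrix.

    ``codes`` is int8 with values {0, 1, 2} and −1 for missing; ``sites``
    is a DataFrame with columns chrom/pos/ref/alt aligned with the columns
    of ``codes``.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("codes shape does not match sample_ids × sites")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @cached_property
    def p(self) -> np.ndarray:
        """Per-site alternate-allele frequency from non-missing calls."""
        codes = self.codes
        obs = codes != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return p

    def swapped_alleles(self) -> "GenotypeMatrix":
        """Matrix with ref/alt orientation flipped at every site (2−x)."""
        codes = np.where(self.codes == MISSING, MISSING, 2 - self.codes)
        sites = self.sites.rename(columns={"ref": "alt", "alt": "ref"})[
            ["chrom", "pos", "ref", "alt"]
        ]
        return GenotypeMatrix(list(self.sample_ids), sites.reset_index(drop=True), codes)


def build_genotype_matrix(
    records: Iterable[VariantRecord],
    keep: Callable[[VariantRecord], bool] | None = None,
    maf_gt: float | None = None,
    sample_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from biallelic records passing the filters.

    ``keep`` is an arbitrary record predicate (type/chromosome filters are
    composed there); ``maf_gt`` additionally requires the folded allele
    frequency, recomputed from the genotypes, to exceed the threshold
    strictly.  Multiallelic and symbolic sites never enter the matrix.
    """
    rows: list[np.ndarray] = []
    meta: list[tuple[str, int, str, str]] = []
    n_samples = None
    for rec in records:
        allelicity, vtype = classify_variant(rec)
        if allelicity != "biallelic" or vtype == "mixed":
            continue
        if keep is not None and not keep(rec):
            continue
        codes = rec.alt_codes()
        if n_samples is None:
            n_samples = len(codes)
        elif len(codes) != n_samples:
            raise ValueError(f"inconsistent sample count at {rec.chrom}:{rec.pos}")
        if maf_gt is not None:
            obs = codes != MISSING
            if obs.sum() == 0:
                continue
            p = codes[obs].sum() / (2 * obs.sum())
            if min(p, 1 - p) <= maf_gt:
                continue
        rows.append(codes)
        meta.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))

    if not rows:
        raise EmptyMatrixError("no sites retained after filtering")

    codes = np.stack(rows, axis=1)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(codes.shape[0])]
    sites = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    log.info("genotype matrix: %d samples × %d sites retained", codes.shape[0], codes.shape[1])
    return GenotypeMatrix(list(sample_ids), sites, codes)


# ---------------------------------------------------------------------------
# Gene-model TSV I/O (BED-like: chrom, start, end, strand, gene_id, feature)
# ---------------------------------------------------------------------------


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append((g.chrom, g.start, g.end, g.strand, g.gene_id, "gene", g.gene_symbol))
        for s, e in g.exons:
            rows.append((g.chrom, s, e, g.strand, g.gene_id, "exon", g.gene_symbol))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_id", "feature", "gene_symbol"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes: list[GeneModel] = []
    for gid, grp in df.groupby("gene_id", sort=False):
        body = grp[grp["feature"] == "gene"]
        if body.empty:
            raise ConfigurationError(f"gene {gid}: no 'gene' feature row")
        b = body.iloc[0]
        exons = tuple(
            (int(r.start), int(r.end))
            for r in grp[grp["feature"] == "exon"].itertuples()
        )
        genes.append(
            GeneModel(
                gene_id=str(gid),
                chrom=str(b.chrom),
                start=int(b.start),
                end=int(b.end),
                exons=tuple(sorted(exons)),
                strand=str(b.strand),
                gene_symbol=str(b.get("gene_symbol", "") or ""),
            )
        )
    return genes
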