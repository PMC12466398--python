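"""Synthetic multi-sample cohort generator with known ground truth.

Emulates the input structure of a small whole-genome-sequenced horse cohort:
20 diploid individuals, 31 autosomes plus X, biallelic SNPs and indels with a
Beta-shaped site-frequency spectrum, per-sample inbreeding, per-genotype
Poisson read depths, breed-fixed alternative alleles, and known Mendelian
trait variants injected at chosen heterozygote counts.  Every simulated site
is recorded in a truth table so downstream estimators can be validated by
parameter recovery.

Genotypes at a site with alternate-allele frequency ``p`` for an individual
with inbreeding coefficient ``F`` are drawn from the F-adjusted
Hardy–Weinberg triple::

    P(hom-ref) = (1-p)^2 + F p (1-p)
    P(het)     = 2 p (1-p) (1-F)
    P(hom-alt) = p^2 + F p (1-p)

Inbreeding is therefore simulated marginally per genotype, not through
pedigrees or homozygosity tracts: adequate for recovering moment-based
inbreeding estimators, but carrying no linkage disequilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_store import (
    AnnotationRecord,
    GeneModel,
    VariantRecord,
    normalize_chrom,
    read_vcf,
    write_gene_models,
    write_vcf,
)
from .trait_catalog_scan import CatalogVariant

log = logging.getLogger(__name__)

__all__ = [
    "CohortSimSpec",
    "FixedVariantSpec",
    "SimulatedCohort",
    "default_chromosomes",
    "make_gene_models",
    "sample_genotype_codes",
    "annotate_synthetic",
    "locate_site",
    "simulate_cohort",
]

_BASES = ("A", "C", "G", "T")

# Relative weights for drawn exonic consequence labels.  No codon model exists
# for synthetic sequence, so exonic labels are assigned, not computed; the
# defaults roughly follow the relative abundance of exonic classes observed in
# real mammalian WGS annotation.
SNP_EXON_WEIGHTS = {
    "missense_variant": 0.48,
    "synonymous_variant": 0.33,
    "splice_region_variant": 0.07,
    "non_coding_transcript_exon_variant": 0.06,
    "stop_gained": 0.03,
    "start_lost": 0.02,
    "stop_lost": 0.01,
}
INDEL_EXON_WEIGHTS = {
    "frameshift_variant": 0.70,
    "inframe_deletion": 0.15,
    "inframe_insertion": 0.15,
}


def default_chromosomes(scale: float = 1.0) -> list[tuple[str, int]]:
    """31 autosomes plus X with lengths shrinking from 1.6 Mb to 0.4 Mb.

    A miniature genome preserving the many-chromosome layout of the horse
    karyotype at a size where whole-cohort simulation takes seconds.
    """
    chroms = []
    for i in range(1, 32):
        length = int((1_600_000 - 40_000 * (i - 1)) * scale)
        chroms.append((str(i), length))
    chroms.append(("X", int(1_000_000 * scale)))
    return chroms


def make_gene_models(
    chromosomes: Sequence[tuple[str, int]],
    genes_per_chrom: int = 1,
    gene_length: int = 20_000,
    n_exons: int = 4,
    exon_length: int = 1_000,
) -> list[GeneModel]:
    """Deterministic synthetic gene models, evenly spaced per chromosome."""
    genes: list[GeneModel] = []
    idx = 1
    for chrom, length in chromosomes:
        usable = length - gene_length - 20_000
        if usable <= 0 or genes_per_chrom < 1:
            continue
        for g in range(genes_per_chrom):
            start = 10_000 + (g * usable) // max(genes_per_chrom, 1)
            end = start + gene_length - 1
            span = gene_length // n_exons
            exons = tuple(
                (start + k * span, start + k * span + exon_length - 1)
                for k in range(n_exons)
            )
            genes.append(
                GeneModel(
                    gene_id=f"GENE{idx:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    exons=exons,
                    strand="+" if idx % 2 else "-",
                    gene_symbol=f"SYN{idx}",
                )
            )
            idx += 1
    return genes


@dataclass(frozen=True)
class FixedVariantSpec:
    """Breed-fixed alternative-allele sites to inject.

    ``n_background`` sites are placed uniformly at random; ``plantings`` force
    a given number of exonic high/moderate-impact fixed variants into named
    genes (the planted truth for candidate-gene recovery tests).  Planted
    sites get a read-depth floor of ``planted_depth_floor`` in every sample so
    their qualification under the depth filter is set by construction.
    """

    n_background: int = 0
    plantings: tuple[tuple[str, int], ...] = ()
    planted_depth_floor: int = 10


@dataclass
class CohortSimSpec:
    """Full parameterization of a synthetic cohort.

    The defaults describe the reference scenario: 20 diploid samples over a
    miniature 32-chromosome genome, ~one variant per 5 kb, a U-shaped
    Beta(0.5, 0.5) site-frequency spectrum, 10% indels, 8% multiallelic
    sites, no inbreeding, and 20× mean depth (Poisson per genotype).
    """

    n_samples: int = 20
    chromosomes: list[tuple[str, int]] = field(default_factory=default_chromosomes)
    site_density: float = 2e-4
    freq_model: tuple = ("beta", 0.5, 0.5)
    f_inbreeding: float | Sequence[float] = 0.0
    indel_fraction: float = 0.10
    multiallelic_fraction: float = 0.08
    depth_mean: float | Sequence[float] = 20.0
    fixed_variant_spec: FixedVariantSpec | int | None = None
    catalog_spec: Sequence[tuple[CatalogVariant, int]] = ()
    gene_models: list[GeneModel] | None = None
    snp_exon_weights: dict = field(default_factory=lambda: dict(SNP_EXON_WEIGHTS))
    indel_exon_weights: dict = field(default_factory=lambda: dict(INDEL_EXON_WEIGHTS))
    flank_bp: int = 5_000
    seed: int = 0

    def sample_f(self) -> np.ndarray:
        f = np.asarray(self.f_inbreeding, dtype=float)
        if f.ndim == 0:
            f = np.full(self.n_samples, float(f))
        if f.shape != (self.n_samples,):
            raise ValueError("f_inbreeding must be scalar or length n_samples")
        return f

    def sample_depth(self) -> np.ndarray:
        d = np.asarray(self.depth_mean, dtype=float)
        if d.ndim == 0:
            d = np.full(self.n_samples, float(d))
        if d.shape != (self.n_samples,):
            raise ValueError("depth_mean must be scalar or length n_samples")
        return d


def sample_allele_freqs(freq_model: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw alternate-allele frequencies from the named family.

    Supported families: ``("beta", a, b)``, ``("uniform", lo, hi)``,
    ``("fixed", value_or_list)``.  Frequencies are clipped to (0.01, 0.99)
    so every background site is polymorphic in expectation.
    """
    kind = freq_model[0]
    if kind == "beta":
        p = rng.beta(freq_model[1], freq_model[2], size=size)
    elif kind == "uniform":
        p = rng.uniform(freq_model[1], freq_model[2], size=size)
    elif kind == "fixed":
        vals = np.atleast_1d(np.asarray(freq_model[1], dtype=float))
        p = vals[rng.integers(0, len(vals), size=size)] if len(vals) > 1 else np.full(size, vals[0])
    else:
        raise ValueError(f"unknown freq_model family: {kind!r}")
    return np.clip(p, 0.01, 0.99)


def sample_genotype_codes(
    p: np.ndarray,
    f: float | np.ndarray,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
    chunk: int = 20_000,
) -> np.ndarray:
    """Draw an (n_samples × n_sites) dosage matrix under F-adjusted HWE.

    ``f`` may be a scalar or per-sample vector.  Probabilities that go
    negative for strongly negative F are clamped to zero and renormalized
    (logged once).
    """
    rng = rng if rng is not None else np.random.default_rng()
    p = np.asarray(p, dtype=float)
    fv = np.asarray(f, dtype=float)
    if fv.ndim == 0:
        if n_samples is None:
            raise ValueError("n_samples required when f is scalar")
        fv = np.full(n_samples, float(fv))
    n = len(fv)
    m = len(p)
    out = np.empty((n, m), dtype=np.int8)
    clamped = False
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        pc = p[lo:hi][None, :]
        fc = fv[:, None]
        het = 2 * pc * (1 - pc) * (1 - fc)
        hom_ref = (1 - pc) ** 2 + fc * pc * (1 - pc)
        hom_alt = pc**2 + fc * pc * (1 - pc)
        probs = np.stack([hom_ref, het, hom_alt])
        if (probs < 0).any():
            clamped = True
            probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=0)
        c0 = probs[0]
        c1 = probs[0] + probs[1]
        u = rng.random((n, hi - lo))
        out[:, lo:hi] = (u >= c0).astype(np.int8) + (u >= c1).astype(np.int8)
    if clamped:
        log.warning("genotype probabilities clamped to 0 for extreme negative F")
    return out


# ---------------------------------------------------------------------------
# Geometric annotation
# ---------------------------------------------------------------------------

_REGION_SEVERITY = {"exon": 0, "intron": 1, "upstream": 2, "downstream": 2, "intergenic": 3}


def locate_site(
    chrom: str, pos: int, genes: Sequence[GeneModel], flank: int = 5_000
) -> tuple[str, GeneModel | None]:
    """Positional class of a site relative to gene models.

    Returns (region, gene) with region in {exon, intron, upstream,
    downstream, intergenic}.  When several genes apply, the most severe
    region wins; ties break on the lexically smaller gene_id.
    """
    chrom = normalize_chrom(chrom)
    candidates: list[tuple[int, str, str, GeneModel]] = []
    for g in genes:
        if normalize_chrom(g.chrom) != chrom:
            continue
        if g.contains(pos):
            region = "exon" if g.in_exon(pos) else "intron"
        elif g.start - flank <= pos < g.start:
            region = "upstream" if g.strand == "+" else "downstream"
        elif g.end < pos <= g.end + flank:
            region = "downstream" if g.strand == "+" else "upstream"
        else:
            continue
        candidates.append((_REGION_SEVERITY[region], region, g.gene_id, g))
    if not candidates:
        return "intergenic", None
    candidates.sort(key=lambda t: (t[0], t[2]))
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        log.debug("overlapping genes at %s:%d; keeping %s", chrom, pos, candidates[0][2])
    _, region, _, gene = candidates[0]
    return region, gene


_REGION_CONSEQUENCE = {
    "intron": "intron_variant",
    "upstream": "upstream_gene_variant",
    "downstream": "downstream_gene_variant",
    "intergenic": "intergenic_variant",
}


def _draw_weighted(weights: dict, rng: np.random.Generator) -> str:
    keys = list(weights)
    w = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def annotate_synthetic(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
    is_indel: bool = False,
    exon_label: str | None = None,
    snp_exon_weights: dict = SNP_EXON_WEIGHTS,
    indel_exon_weights: dict = INDEL_EXON_WEIGHTS,
    flank: int = 5_000,
) -> AnnotationRecord:
    """Assign a consequence annotation to a synthetic site by geometry.

    Non-exonic classes follow from position alone; exonic labels are drawn
    from the configured weights (or forced via ``exon_label``).
    """
    region, gene = locate_site(chrom, pos, genes, flank=flank)
    if region == "exon":
        label = exon_label or _draw_weighted(
            indel_exon_weights if is_indel else snp_exon_weights, rng
        )
    else:
        label = _REGION_CONSEQUENCE[region]
    return AnnotationRecord.from_consequence(
        label,
        gene_id=gene.gene_id if gene else "",
        gene_symbol=gene.symbol if gene else "",
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """A simulated cohort on disk plus its in-memory ground truth."""

    vcf_path: Path
    truth_path: Path
    truth: pd.DataFrame
    sample_ids: list[str]
    sample_f: np.ndarray
    gene_models: list[GeneModel]
    spec: CohortSimSpec

    def records(self) -> list[VariantRecord]:
        return list(read_vcf(self.vcf_path))


def _unique_positions(n: int, length: int, occupied: set, rng: np.random.Generator) -> np.ndarray:
    """n distinct 1-based positions avoiding ``occupied``."""
    out: set[int] = set()
    while len(out) < n:
        draw = rng.integers(1, length + 1, size=max(2 * (n - len(out)), 16))
        for v in draw:
            v = int(v)
            if v not in occupied and v not in out:
                out.add(v)
                if len(out) == n:
                    break
    return np.sort(np.fromiter(out, dtype=np.int64))


def _draw_snp_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return ref, alt


def _draw_indel_alleles(rng: np.random.Generator) -> tuple[str, str]:
    anchor = _BASES[rng.integers(0, 4)]
    tail = "".join(_BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 4))))
    if rng.random() < 0.5:  # deletion
        return anchor + tail, anchor
    return anchor, anchor + tail


def simulate_cohort(spec: CohortSimSpec, out_dir: str | Path) -> SimulatedCohort:
    """Generate an annotated multi-sample VCF cohort with ground truth.

    Writes ``cohort.vcf`` (GT:DP, CSQ annotations, INFO AF/DP/BQRS),
    ``truth.tsv`` (one row per site with true frequency, class and
    provenance) and ``gene_models.tsv`` under ``out_dir``.  Identical spec
    and seed produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_f = spec.sample_f()
    depth_mean = spec.sample_depth()
    sample_ids = [f"horse{i + 1:02d}" for i in range(n)]

    genes = spec.gene_models if spec.gene_models is not None else make_gene_models(spec.chromosomes)
    genes_by_id = {g.gene_id: g for g in genes}

    chrom_order = [c for c, _ in spec.chromosomes]
    chrom_len = {c: int(l) for c, l in spec.chromosomes}

    # site registry: (chrom -> set of occupied positions)
    occupied: dict[str, set[int]] = {c: set() for c in chrom_order}
    sites: list[dict] = []

    # -- background sites ---------------------------------------------------
    for chrom, length in spec.chromosomes:
        m = int(rng.poisson(spec.site_density * length))
        if m == 0:
            continue
        positions = _unique_positions(m, length, occupied[chrom], rng)
        occupied[chrom].update(int(x) for x in positions)
        p = sample_allele_freqs(spec.freq_model, m, rng)
        u = rng.random(m)
        for j, pos in enumerate(positions):
            if u[j] < spec.multiallelic_fraction:
                vtype = "multiallelic"
            elif u[j] < spec.multiallelic_fraction + spec.indel_fraction:
                vtype = "indel"
            else:
                vtype = "SNP"
            sites.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "vtype": vtype,
                    "p_true": float(p[j]),
                    "category": "background",
                    "het_target": None,
                }
            )

    # -- fixed-alternative sites -------------------------------------------
    fspec = spec.fixed_variant_spec
    if isinstance(fspec, int):
        fspec = FixedVariantSpec(n_background=fspec)
    if fspec is not None:
        autosomes = [(c, l) for c, l in spec.chromosomes if c != "X"] or spec.chromosomes
        for _ in range(fspec.n_background):
            ci = int(rng.integers(0, len(autosomes)))
            chrom, length = autosomes[ci]
            pos = int(_unique_positions(1, length, occupied[chrom], rng)[0])
            occupied[chrom].add(pos)
            vtype = "indel" if rng.random() < spec.indel_fraction else "SNP"
            sites.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "vtype": vtype,
                    "p_true": 1.0,
                    "category": "fixed",
                    "het_target": None,
                }
            )
        for gene_id, count in fspec.plantings:
            gene = genes_by_id[gene_id]
            exon_positions = [
                pos
                for s, e in gene.exons
                for pos in range(s, e + 1)
                if pos not in occupied[gene.chrom]
            ]
            if count > len(exon_positions):
                raise ValueError(f"gene {gene_id}: not enough exon space for {count} plantings")
            chosen = rng.choice(len(exon_positions), size=count, replace=False)
            for k in sorted(int(i) for i in chosen):
                pos = exon_positions[k]
                occupied[gene.chrom].add(pos)
                label = "missense_variant" if rng.random() < 0.8 else "stop_gained"
                sites.append(
                    {
                        "chrom": gene.chrom,
                        "pos": pos,
                        "vtype": "SNP",
                        "p_true": 1.0,
                        "category": "planted",
                        "het_target": None,
                        "exon_label": label,
                        "gene_hint": gene_id,
                    }
                )

    # -- catalog injections -------------------------------------------------
    for cv, het_count in spec.catalog_spec:
        if het_count > n:
            raise ValueError(f"catalog {cv.gene_symbol}: heterozygote target > n_samples")
        chrom = normalize_chrom(cv.chrom)
        if chrom not in occupied:
            occupied[chrom] = set()
            chrom_order.append(chrom)
            chrom_len[chrom] = cv.pos + 10_000
        pos = cv.pos
        if pos in occupied[chrom]:
            log.warning("catalog position %s:%d collides with a simulated site; shifted +1", chrom, pos)
            pos += 1
        occupied[chrom].add(pos)
        sites.append(
            {
                "chrom": chrom,
                "pos": pos,
                "vtype": "catalog",
                "p_true": het_count / (2 * n),
                "category": "catalog",
                "het_target": het_count,
                "catalog": cv,
            }
        )

    # -- order, alleles, genotypes, annotation ------------------------------
    rank = {c: i for i, c in enumerate(chrom_order)}
    sites.sort(key=lambda s: (rank[s["chrom"]], s["pos"]))

    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    bi_idx = [i for i, s in enumerate(sites) if s["vtype"] in ("SNP", "indel", "catalog")]
    p_bi = np.array(
        [sites[i]["p_true"] for i in bi_idx if sites[i]["category"] == "background"]
    )
    # genotype draws for polymorphic background biallelic sites, one block
    bg_bi = [i for i in bi_idx if sites[i]["category"] == "background"]
    codes_bg = sample_genotype_codes(p_bi, sample_f, rng=rng) if len(bg_bi) else np.empty((n, 0), np.int8)
    bg_col = {site_i: j for j, site_i in enumerate(bg_bi)}

    for i, s in enumerate(sites):
        chrom, pos, vtype = s["chrom"], s["pos"], s["vtype"]
        category = s["category"]
        if vtype == "multiallelic":
            ref = _BASES[rng.integers(0, 4)]
            alts = list(rng.permutation([b for b in _BASES if b != ref])[:2])
            # simple 3-allele HWE, no inbreeding: freqs (1-p, 0.6p, 0.4p)
            p = s["p_true"]
            freqs = np.array([1 - p, 0.6 * p, 0.4 * p])
            draws = rng.choice(3, size=(n, 2), p=freqs)
            gts = [(int(a), int(b)) for a, b in draws]
        else:
            if category == "catalog":
                cv: CatalogVariant = s["catalog"]
                ref, alt = cv.ref, cv.alt
                # indel-like catalog alleles written VCF-style with an anchor
                # base, exercising left-normalization on the matching side
                if len(ref) != len(alt):
                    anchor = _BASES[rng.integers(0, 4)]
                    ref, alt = anchor + ref, anchor + alt
                    pos = pos - 1
                het = int(s["het_target"])
                carriers = rng.choice(n, size=het, replace=False) if het else np.array([], int)
                gts = [(0, 1) if k in set(int(c) for c in carriers) else (0, 0) for k in range(n)]
                alts = [alt]
            elif category in ("fixed", "planted"):
                if vtype == "indel":
                    ref, alt = _draw_indel_alleles(rng)
                else:
                    ref, alt = _draw_snp_alleles(rng)
                alts = [alt]
                gts = [(1, 1)] * n
            else:  # polymorphic background biallelic
                if vtype == "indel":
                    ref, alt = _draw_indel_alleles(rng)
                else:
                    ref, alt = _draw_snp_alleles(rng)
                alts = [alt]
                col = codes_bg[:, bg_col[i]]
                gts = [(0, 0) if c == 0 else ((0, 1) if c == 1 else (1, 1)) for c in col]

        ann = annotate_synthetic(
            chrom,
            pos,
            genes,
            rng,
            is_indel=(vtype == "indel"),
            exon_label=s.get("exon_label"),
            snp_exon_weights=spec.snp_exon_weights,
            indel_exon_weights=spec.indel_exon_weights,
            flank=spec.flank_bp,
        )

        dp = rng.poisson(depth_mean).astype(int)
        if category == "planted":
            floor = fspec.planted_depth_floor
            dp = floor + rng.poisson(np.maximum(depth_mean - floor, 0.0)).astype(int)
        depths = [int(d) for d in dp]

        n_alleles = sum(1 for a, b in gts for x in (a, b))
        n_alt = sum((a > 0) + (b > 0) for a, b in gts)
        af_called = n_alt / n_alleles if n_alleles else 0.0
        qual_info = {
            "af": af_called,
            "site_depth": int(sum(depths)),
            "base_q_rank_sum": float(rng.normal()),
        }

        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=alts,
                genotypes=gts,
                depths=depths,
                annotations=[ann],
                qual_info=qual_info,
            )
        )
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": ",".join(alts),
                "vtype": (
                    ("SNP" if len(ref) == len(alts[0]) == 1 else "indel")
                    if vtype == "catalog"
                    else vtype
                ),
                "p_true": s["p_true"],
                "consequence": ann.consequence,
                "impact": ann.impact,
                "gene_id": ann.gene_id,
                "category": category,
                "het_target": s["het_target"],
            }
        )

    contigs = [(c, max(chrom_len[c], max((r.pos for r in records if r.chrom == c), default=0) + 1000)) for c in chrom_order]
    vcf_path = out_dir / "cohort.vcf"
    write_vcf(records, vcf_path, sample_ids, contigs=contigs)

    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    write_gene_models(genes, out_dir / "gene_models.tsv")
    pd.DataFrame({"sample_id": sample_ids, "f_true": sample_f}).to_csv(
        out_dir / "samples.tsv", sep="\t", index=False
    )
    log.info("simulated cohort: %d samples, %d sites -> %s", n, len(records), vcf_path)
    return SimulatedCohort(
        vcf_path=vcf_path,
        truth_path=truth_path,
        truth=truth,
        sample_ids=sample_ids,
        sample_f=sample_f,
        gene_models=genes,
        spec=spec,
    )
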