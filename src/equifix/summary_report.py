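"""Cohort-level summaries and pipeline orchestration.

Per-chromosome variant counts (all vs. biallelic, SNP vs. indel), functional
annotation class counts over the biallelic set (one most-severe consequence
per variant so the classes partition it), megabase-bin variant densities, and
a ``run_pipeline`` entry point that chains every stage of the analysis on one
input VCF (or a freshly simulated cohort) and writes the report files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import breed_fixed_scan, diversity, relatedness, trait_catalog_scan
from .variant_store import (
    CONSEQUENCE_SEVERITY,
    GeneModel,
    VariantRecord,
    build_genotype_matrix,
    classify_variant,
    is_autosome,
    most_severe,
    normalize_chrom,
    read_gene_models,
    read_vcf,
    vcf_sample_ids,
)

log = logging.getLogger(__name__)

__all__ = [
    "summarize_by_chromosome",
    "summarize_by_class",
    "density_bins",
    "percentage",
    "run_pipeline",
    "PipelineConfig",
]

_CHROM_TABLE_ORDER = [str(i) for i in range(1, 32)] + ["X"]


def percentage(part: float, whole: float, digits: int = 2) -> float:
    """Percentage with half-up rounding at ``digits`` decimals."""
    if whole == 0:
        return 0.0
    q = Decimal(10) ** -digits
    return float(Decimal(100 * part / whole).quantize(q, rounding=ROUND_HALF_UP))


def _chrom_sort_key(c: str):
    return (0, int(c)) if c.isdigit() else ((1, 0) if c == "X" else (2, 0))


def summarize_by_chromosome(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Variant counts per chromosome: all and biallelic, split SNP/indel.

    Mixed-type sites count in the indel column of the "all variants" block.
    Records on unrecognized contigs go to an explicit "unplaced" row that is
    excluded from the autosomal subtotal; a "Total" row sums every column.
    """
    counters: dict[str, dict[str, int]] = {}
    for rec in records:
        chrom = normalize_chrom(rec.chrom)
        if chrom not in _CHROM_TABLE_ORDER:
            chrom = "unplaced"
        c = counters.setdefault(
            chrom,
            {
                "all_indels": 0, "all_snps": 0, "all_total": 0,
                "bi_indels": 0, "bi_snps": 0, "bi_total": 0,
            },
        )
        allelicity, vtype = classify_variant(rec)
        c["all_total"] += 1
        if vtype == "SNP":
            c["all_snps"] += 1
        else:
            c["all_indels"] += 1
        if allelicity == "biallelic" and vtype in ("SNP", "indel"):
            c["bi_total"] += 1
            if vtype == "SNP":
                c["bi_snps"] += 1
            else:
                c["bi_indels"] += 1

    chroms = sorted(counters, key=_chrom_sort_key)
    rows = [{"chrom": c, **counters[c]} for c in chroms]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "all_indels", "all_snps", "all_total", "bi_indels", "bi_snps", "bi_total"],
    )
    cols = df.columns[1:]
    placed = df[df["chrom"] != "unplaced"]
    autosomal = placed[placed["chrom"] != "X"]
    subtotal = {"chrom": "autosomal_subtotal", **{c: int(autosomal[c].sum()) for c in cols}}
    total = {"chrom": "Total", **{c: int(df[c].sum()) for c in cols}}
    return pd.concat([df, pd.DataFrame([subtotal, total])], ignore_index=True)


def summarize_by_class(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Biallelic variant counts per functional annotation class.

    Each variant contributes once, under its most severe consequence across
    all transcripts/genes, so the class counts partition the biallelic set
    and the Total row matches the per-chromosome biallelic grand total.
    Unknown terms (and unannotated variants) fall into an "other" bucket.
    """
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        allelicity, vtype = classify_variant(rec)
        if allelicity != "biallelic" or vtype not in ("SNP", "indel"):
            continue
        ann = most_severe(rec.annotations)
        cls = ann.consequence if ann is not None else "other"
        if cls not in CONSEQUENCE_SEVERITY:
            if ann is not None:
                log.warning("unknown consequence term %r bucketed as 'other'", cls)
            cls = "other"
        c = counts.setdefault(cls, {"snps": 0, "indels": 0})
        c["snps" if vtype == "SNP" else "indels"] += 1

    rows = [
        {"class": cls, "snps": v["snps"], "indels": v["indels"], "total": v["snps"] + v["indels"]}
        for cls, v in counts.items()
    ]
    rows.sort(key=lambda r: (-r["total"], r["class"]))
    df = pd.DataFrame(rows, columns=["class", "snps", "indels", "total"])
    total = {
        "class": "Total",
        "snps": int(df["snps"].sum()) if len(df) else 0,
        "indels": int(df["indels"].sum()) if len(df) else 0,
        "total": int(df["total"].sum()) if len(df) else 0,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


_FIG_GROUPS = {
    "intron_variant": "intron",
    "intergenic_variant": "intergenic",
    "upstream_gene_variant": "updown",
    "downstream_gene_variant": "updown",
}


def density_bins(
    records: Iterable[VariantRecord],
    bin_size: int = 1_000_000,
    chrom_lengths: Mapping[str, int] | None = None,
    survivors: Iterable[VariantRecord] | None = None,
) -> pd.DataFrame:
    """Per-megabase-bin variant counts (ring-plot logic as a table).

    Counts, per bin: all variants; filtered-cascade survivors (when given);
    and the consequence groups intron / intergenic / up-or-downstream /
    other, assigned from each variant's most severe consequence.  The four
    groups partition each bin's total.
    """
    surv_keys = set()
    if survivors is not None:
        surv_keys = {(normalize_chrom(r.chrom), r.pos) for r in survivors}

    data: dict[tuple[str, int], dict[str, int]] = {}
    max_bin: dict[str, int] = {}
    for rec in records:
        chrom = normalize_chrom(rec.chrom)
        b = (rec.pos - 1) // bin_size
        key = (chrom, b)
        c = data.setdefault(
            key,
            {"all": 0, "filtered": 0, "intron": 0, "intergenic": 0, "updown": 0, "other": 0},
        )
        c["all"] += 1
        if (chrom, rec.pos) in surv_keys:
            c["filtered"] += 1
        ann = most_severe(rec.annotations)
        group = _FIG_GROUPS.get(ann.consequence, "other") if ann else "other"
        c[group] += 1
        max_bin[chrom] = max(max_bin.get(chrom, 0), b)

    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            chrom = normalize_chrom(chrom)
            max_bin[chrom] = max(max_bin.get(chrom, -1), (int(length) - 1) // bin_size)

    rows = []
    for chrom in sorted(max_bin, key=_chrom_sort_key):
        for b in range(max_bin[chrom] + 1):
            c = data.get(
                (chrom, b),
                {"all": 0, "filtered": 0, "intron": 0, "intergenic": 0, "updown": 0, "other": 0},
            )
            rows.append(
                {"chrom": chrom, "bin_start": b * bin_size + 1, "bin_end": (b + 1) * bin_size, **c}
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "bin_start", "bin_end", "all", "filtered",
                 "intron", "intergenic", "updown", "other"],
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

_ALL_STAGES = ("summaries", "diversity", "relatedness", "fixed_scan", "catalog_scan")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``vcf`` names an input VCF, or ``simulate`` holds a
    :class:`~equifix.synthetic_cohort.CohortSimSpec` to generate one first.
    """

    out_dir: str | Path
    vcf: str | Path | None = None
    simulate: object | None = None  # CohortSimSpec
    gene_models: str | Path | Sequence[GeneModel] | None = None
    catalog: str | Path | Sequence | None = None
    stages: Sequence[str] = _ALL_STAGES
    window: int = 10_000
    step: int | None = None
    maf: float = 0.05
    min_dp: int = 10
    pcg_min_variants: int = 5
    autosomes_only: bool = True
    genome_size: float | None = None
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order and write all report tables.

    Returns a manifest dict with stage outputs, counts and file hashes; also
    written as ``manifest.json`` in the output directory.  Deterministic for
    a fixed config and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in config.stages if s not in _ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {', '.join(unknown)}")

    genes: Sequence[GeneModel] | None = None
    if config.simulate is not None:
        from .synthetic_cohort import simulate_cohort

        spec = config.simulate
        if spec.seed != config.seed:
            from dataclasses import replace as _replace

            spec = _replace(spec, seed=config.seed)
        cohort = simulate_cohort(spec, out_dir / "cohort")
        vcf_path = cohort.vcf_path
        genes = cohort.gene_models
    elif config.vcf is not None:
        vcf_path = Path(config.vcf)
        if not vcf_path.exists():
            raise FileNotFoundError(f"input VCF not found: {vcf_path}")
    else:
        raise ValueError("config must provide either 'vcf' or 'simulate'")

    if config.gene_models is not None:
        if isinstance(config.gene_models, (str, Path)):
            genes = read_gene_models(config.gene_models)
        else:
            genes = list(config.gene_models)

    catalog = None
    if config.catalog is not None:
        if isinstance(config.catalog, (str, Path)):
            catalog = trait_catalog_scan.read_catalog(config.catalog)
        else:
            catalog = list(config.catalog)

    records = list(read_vcf(vcf_path))
    manifest: dict = {
        "input_vcf": str(vcf_path),
        "seed": config.seed,
        "n_records": len(records),
        "outputs": {},
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(path)

    try:
        if "summaries" in config.stages:
            emit("chrom_summary.tsv", summarize_by_chromosome(records))
            emit("class_summary.tsv", summarize_by_class(records))
            emit("density_bins.tsv", density_bins(records))

        matrix = None
        if "diversity" in config.stages or "relatedness" in config.stages:

            def keep(rec: VariantRecord) -> bool:
                _, vtype = classify_variant(rec)
                if vtype != "SNP":
                    return False
                return is_autosome(rec.chrom) if config.autosomes_only else True

            matrix = build_genotype_matrix(
                records, keep=keep, maf_gt=config.maf, sample_ids=vcf_sample_ids(vcf_path)
            )

        if "diversity" in config.stages:
            hs = diversity.het_summary(matrix)
            windows = diversity.window_pi(records, window=config.window, step=config.step)
            emit("het_sites.tsv", hs.per_site)
            emit("het_samples.tsv", hs.per_sample)
            emit("pi_windows.tsv", windows)
            report = diversity.genome_diversity_report(
                matrix=matrix, windows=windows, genome_size=config.genome_size
            )
            manifest["diversity"] = report

        if "relatedness" in config.stages:
            grm = relatedness.build_grm(matrix)
            inb = relatedness.inbreeding_table(matrix, grm=grm)
            pca = relatedness.pca_from_grm(grm)
            relatedness.write_grm_text(grm, str(out_dir / "cohort"))
            emit("inbreeding.tsv", inb.table)
            emit("inbreeding_summary.tsv", inb.summary)
            emit("pca_scores.tsv", pca.scores)
            manifest["relatedness"] = {
                "n_sites_grm": grm.n_sites_used,
                "explained_pct_pc1": float(pca.explained_pct[0]),
                "f_means": {
                    str(r["method"]): float(r["mean"]) for _, r in inb.summary.iterrows()
                },
            }

        if "fixed_scan" in config.stages:
            report = breed_fixed_scan.fixed_variant_cascade(
                records,
                genes=genes,
                min_dp=config.min_dp,
                min_variants=config.pcg_min_variants,
            )
            emit("fixed_cascade.tsv", report.stage_table())
            emit("pcg.tsv", report.pcg_table())
            manifest["fixed_scan"] = report.stage_counts

        if "catalog_scan" in config.stages:
            if catalog is None:
                catalog = trait_catalog_scan.builtin_horse_trait_catalog()
            seg = trait_catalog_scan.segregation_report(catalog, records, include_all=True)
            emit("catalog_scan.tsv", seg)
            manifest["catalog_scan"] = {
                "n_catalog": len(catalog),
                "n_segregating": int((seg["status"] == "segregating").sum()),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
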