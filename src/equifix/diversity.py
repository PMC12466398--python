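"""Heterozygosity and sliding-window nucleotide diversity.

Per-site observed heterozygosity Ho is the fraction of heterozygous calls
among non-missing genotypes; expected heterozygosity He is 2p(1-p) with p the
alternate-allele frequency from non-missing alleles.  Nucleotide diversity π
uses the unbiased pairwise form per site,

    π_site = 2 j (n - j) / (n (n - 1)),

with n the number of non-missing alleles and j the alternate-allele count —
identical to the average proportion of pairwise allele mismatches over all
C(n, 2) sequence pairs.  Window π divides the summed per-site contributions
by the full window length, i.e. positions absent from the VCF are assumed
invariant.  Defaults: 10 kb non-overlapping windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_store import (
    MISSING,
    GenotypeMatrix,
    VariantRecord,
    classify_variant,
    is_autosome,
    normalize_chrom,
)

log = logging.getLogger(__name__)

__all__ = [
    "HetSummary",
    "site_heterozygosity",
    "het_summary",
    "window_pi",
    "site_pi",
    "genome_diversity_report",
]


def site_heterozygosity(codes: np.ndarray) -> tuple[float, float]:
    """(Ho, He) for one biallelic site given its dosage codes.

    Raises ValueError when every genotype is missing (callers skip and log
    such sites).
    """
    codes = np.asarray(codes)
    obs = codes != MISSING
    n_called = int(obs.sum())
    if n_called == 0:
        raise ValueError("all genotypes missing at site")
    called = codes[obs]
    ho = float((called == 1).sum() / n_called)
    p = float(called.sum() / (2 * n_called))
    he = 2.0 * p * (1.0 - p)
    return ho, he


@dataclass
class HetSummary:
    """Per-site and per-sample heterozygosity with genome-wide means."""

    per_site: pd.DataFrame  # chrom, pos, ho, he
    ho_mean: float
    he_mean: float
    per_sample: pd.DataFrame  # sample_id, het_fraction
    n_sites_skipped: int = 0


def het_summary(matrix: GenotypeMatrix, unbiased: bool = False) -> HetSummary:
    """Observed/expected heterozygosity over all sites of a matrix.

    Means are across sites.  ``unbiased`` applies the 2n/(2n-1) small-sample
    correction to He.  Per-sample heterozygous-call fractions are included
    for QC.
    """
    codes = matrix.codes
    obs = codes != MISSING
    n_called = obs.sum(axis=0)
    usable = n_called > 0
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.info("het_summary: %d all-missing sites skipped", n_skipped)

    het = (codes == 1) & obs
    ho = np.where(usable, het.sum(axis=0) / np.maximum(n_called, 1), np.nan)
    alt = np.where(obs, codes, 0).sum(axis=0)
    n_alleles = 2 * n_called
    p = np.where(usable, alt / np.maximum(n_alleles, 1), np.nan)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        with np.errstate(invalid="ignore"):
            he = he * n_alleles / np.maximum(n_alleles - 1, 1)

    per_site = matrix.sites[["chrom", "pos"]].copy()
    per_site["ho"] = ho
    per_site["he"] = he
    per_site = per_site[usable].reset_index(drop=True)

    sample_called = obs.sum(axis=1)
    sample_het = het.sum(axis=1)
    per_sample = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "het_fraction": sample_het / np.maximum(sample_called, 1),
            "n_called": sample_called,
        }
    )
    return HetSummary(
        per_site=per_site,
        ho_mean=float(np.nanmean(ho[usable])) if usable.any() else float("nan"),
        he_mean=float(np.nanmean(he[usable])) if usable.any() else float("nan"),
        per_sample=per_sample,
        n_sites_skipped=n_skipped,
    )


def site_pi(n_alleles: int, n_alt: int) -> float:
    """Unbiased per-site π: mean pairwise difference over C(n,2) pairs."""
    if n_alleles < 2:
        raise ValueError("need at least 2 non-missing alleles")
    j = n_alt
    return 2.0 * j * (n_alleles - j) / (n_alleles * (n_alleles - 1))


def window_pi(
    records: Iterable[VariantRecord],
    window: int = 10_000,
    step: int | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per bp over biallelic sites.

    Windows are 1-based half-open [start, start+window) laid out per
    chromosome every ``step`` bp (default: non-overlapping).  With
    overlapping windows a site contributes to every window covering it.
    Sites with fewer than two called alleles are skipped and counted.
    Returns a DataFrame of chrom/start/end/n_sites/pi/callable_bp rows,
    including empty windows (pi = 0).
    """
    step = step or window
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")

    per_chrom: dict[str, list[tuple[int, float]]] = {}
    max_pos: dict[str, int] = {}
    n_skipped = 0
    for rec in records:
        allelicity, _ = classify_variant(rec)
        if allelicity != "biallelic":
            continue
        if autosomes_only and not is_autosome(rec.chrom):
            continue
        chrom = normalize_chrom(rec.chrom)
        codes = rec.alt_codes()
        obs = codes != MISSING
        n = int(2 * obs.sum())
        if n < 2:
            n_skipped += 1
            continue
        j = int(codes[obs].sum())
        per_chrom.setdefault(chrom, []).append((rec.pos, site_pi(n, j)))
        max_pos[chrom] = max(max_pos.get(chrom, 0), rec.pos)
    if n_skipped:
        log.info("window_pi: %d sites with <2 called alleles skipped", n_skipped)

    rows = []
    chroms = sorted(per_chrom, key=lambda c: (0, int(c)) if c.isdigit() else (1, c))
    if chrom_lengths is not None:
        extra = [
            normalize_chrom(c)
            for c in chrom_lengths
            if normalize_chrom(c) not in per_chrom
            and (not autosomes_only or is_autosome(c))
        ]
        chroms = chroms + sorted(extra, key=lambda c: (0, int(c)) if c.isdigit() else (1, c))
    for chrom in chroms:
        length = None
        if chrom_lengths is not None:
            for k, v in chrom_lengths.items():
                if normalize_chrom(k) == chrom:
                    length = int(v)
                    break
        if length is None:
            length = max_pos.get(chrom, 0)
        sites = sorted(per_chrom.get(chrom, []))
        positions = np.array([s[0] for s in sites], dtype=np.int64)
        contribs = np.array([s[1] for s in sites], dtype=float)
        start = 1
        while start <= length:
            end = start + window  # half-open
            in_win = (positions >= start) & (positions < end)
            callable_bp = min(end, length + 1) - start
            total = float(contribs[in_win].sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_sites": int(in_win.sum()),
                    "pi": total / callable_bp if callable_bp else 0.0,
                    "callable_bp": callable_bp,
                }
            )
            start += step
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "pi", "callable_bp"]
    )


def genome_diversity_report(
    matrix: GenotypeMatrix | None = None,
    windows: pd.DataFrame | None = None,
    genome_size: float | Sequence[float] | None = None,
    pi_mean: float | None = None,
    unbiased_he: bool = False,
) -> dict:
    """Genome-level diversity summary.

    Reports Ho/He means (from the matrix), the length-weighted mean window π,
    and — when a genome size (or several) is given — the projected count of
    pairwise nucleotide differences π_mean × genome_size between two random
    genomes of that size.  ``pi_mean`` may be supplied directly in place of a
    window table.
    """
    out: dict = {}
    if matrix is not None:
        hs = het_summary(matrix, unbiased=unbiased_he)
        out["ho_mean"] = hs.ho_mean
        out["he_mean"] = hs.he_mean
    if windows is not None and len(windows):
        w = windows["callable_bp"].to_numpy(dtype=float)
        pi = windows["pi"].to_numpy(dtype=float)
        pi_mean = float((pi * w).sum() / w.sum()) if w.sum() else 0.0
        out["n_windows"] = int(len(windows))
    if pi_mean is not None:
        out["pi_mean"] = float(pi_mean)
        if genome_size is not None:
            sizes = np.atleast_1d(np.asarray(genome_size, dtype=float))
            proj = [float(float(pi_mean) * s) for s in sizes]
            out["projected_pairwise_differences"] = proj[0] if len(proj) == 1 else proj
    return out
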