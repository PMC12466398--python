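"""Genomic relationship matrix, inbreeding estimators and PCA.

The GRM follows the pooled-denominator (VanRaden method 1) construction:
genotype codes are centered per site, Z = X - 2p, and

    GRM = Z Z' / (2 Σ_i p_i (1 - p_i)).

Three genomic inbreeding estimators are computed:

* ``F_GRM`` — deviation of the GRM diagonal from unity, GRM_ii − 1;
* ``F_HOM`` — excess of observed over expected homozygous loci,
  (N_OHom − N_EHom) / (N_NonMiss − N_EHom) with
  N_EHom = Σ (1 − 2 p_i (1 − p_i));
* ``F_UNI`` — correlation between uniting gametes, the mean over sites of
  (x² − (1 + 2p) x + 2p²) / (2p(1−p)).

All three are invariant to which allele is treated as focal and to site
order.  Missing genotypes are imputed to 2p (zero after centering) in the
GRM, which keeps it positive semidefinite; F_HOM and F_UNI instead skip
missing sites per sample.  Allele frequencies always come from the sample
itself, focal individual included.

Note that F_GRM under the pooled denominator differs slightly from GCTA's
default diagonal (which standardizes per site); ``per_site=True`` switches
to per-site scaling for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_store import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "GRMResult",
    "InbreedingResult",
    "PCAResult",
    "build_grm",
    "f_grm",
    "f_hom",
    "f_uni",
    "inbreeding_table",
    "summarize_inbreeding",
    "pca_from_grm",
]


@dataclass
class GRMResult:
    matrix: np.ndarray
    sample_ids: list[str]
    n_sites_used: int
    site_weights_sum: float  # 2 Σ p(1-p)
    per_site: bool = False


def _checked_inputs(m: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = m.codes.astype(float)
    obs = m.codes != MISSING
    p = m.p
    if np.isnan(p).any():
        raise ValueError("matrix contains all-missing sites; filter them upstream")
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        idx = int(np.argmax(mono))
        site = m.sites.iloc[idx]
        raise ValueError(
            f"monomorphic site reached estimator stage at {site.chrom}:{site.pos}; "
            "filter to polymorphic sites first"
        )
    empty = ~obs.any(axis=1)
    if empty.any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(empty)]
        raise ValueError(f"sample(s) with no called genotypes: {', '.join(bad)}")
    return codes, obs, p


def build_grm(m: GenotypeMatrix, per_site: bool = False) -> GRMResult:
    """Genomic relationship matrix from a polymorphic biallelic matrix.

    ``per_site=False`` (default) pools the 2Σp(1-p) denominator; ``True``
    standardizes each site by sqrt(2p(1-p)) and divides by the site count.
    Missing codes are imputed to 2p before centering.
    """
    codes, obs, p = _checked_inputs(m)
    two_p = 2.0 * p
    z = np.where(obs, codes, two_p) - two_p  # missing -> 0 after centering
    w = 2.0 * p * (1.0 - p)
    if per_site:
        zs = z / np.sqrt(w)
        grm = zs @ zs.T / m.n_sites
    else:
        grm = (z @ z.T) / w.sum()
    grm = (grm + grm.T) / 2.0  # enforce exact symmetry
    return GRMResult(
        matrix=grm,
        sample_ids=list(m.sample_ids),
        n_sites_used=m.n_sites,
        site_weights_sum=float(w.sum()),
        per_site=per_site,
    )


def f_grm(grm: GRMResult) -> np.ndarray:
    """Per-sample inbreeding as the GRM diagonal minus one."""
    return np.diag(grm.matrix) - 1.0


def f_hom(m: GenotypeMatrix) -> np.ndarray:
    """Excess-homozygosity inbreeding coefficient per sample.

    Counts observed homozygous loci against the expectation
    Σ (1 − 2p(1−p)) over that sample's non-missing sites.  A sample whose
    denominator vanishes gets NaN with a warning.
    """
    codes, obs, p = _checked_inputs(m)
    het_exp = 2.0 * p * (1.0 - p)
    n_obs_hom = (((m.codes == 0) | (m.codes == 2)) & obs).sum(axis=1).astype(float)
    n_non_miss = obs.sum(axis=1).astype(float)
    n_exp_hom = (obs * (1.0 - het_exp)).sum(axis=1)
    denom = n_non_miss - n_exp_hom
    out = np.full(m.n_samples, np.nan)
    ok = np.abs(denom) >= 1e-12
    if not ok.all():
        bad = [m.sample_ids[i] for i in np.flatnonzero(~ok)]
        log.warning("f_hom undefined (zero denominator) for: %s", ", ".join(bad))
    out[ok] = (n_obs_hom[ok] - n_exp_hom[ok]) / denom[ok]
    return out


def f_uni(m: GenotypeMatrix) -> np.ndarray:
    """Uniting-gametes inbreeding coefficient per sample.

    Mean over the sample's non-missing sites of the per-site standardized
    term (x² − (1+2p)x + 2p²) / (2p(1−p)).
    """
    codes, obs, p = _checked_inputs(m)
    w = 2.0 * p * (1.0 - p)
    term = (codes**2 - (1.0 + 2.0 * p) * codes + 2.0 * p**2) / w
    term = np.where(obs, term, 0.0)
    n = obs.sum(axis=1).astype(float)
    out = np.full(m.n_samples, np.nan)
    ok = n > 0
    if not ok.all():
        bad = [m.sample_ids[i] for i in np.flatnonzero(~ok)]
        log.warning("f_uni undefined (no called sites) for: %s", ", ".join(bad))
    out[ok] = term.sum(axis=1)[ok] / n[ok]
    return out


@dataclass
class InbreedingResult:
    """Per-sample estimates from all three methods plus homozygosity counts."""

    table: pd.DataFrame  # sample_id, f_grm, f_hom, f_uni, n_ohom, n_ehom, n_nonmiss
    summary: pd.DataFrame  # method × (min, max, mean)


def inbreeding_table(m: GenotypeMatrix, grm: GRMResult | None = None) -> InbreedingResult:
    """All three inbreeding estimators side by side (reporting schema)."""
    if grm is None:
        grm = build_grm(m)
    codes, obs, p = _checked_inputs(m)
    het_exp = 2.0 * p * (1.0 - p)
    table = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "f_grm": f_grm(grm),
            "f_hom": f_hom(m),
            "f_uni": f_uni(m),
            "n_ohom": (((m.codes == 0) | (m.codes == 2)) & obs).sum(axis=1),
            "n_ehom": (obs * (1.0 - het_exp)).sum(axis=1),
            "n_nonmiss": obs.sum(axis=1),
        }
    )
    return InbreedingResult(table=table, summary=summarize_inbreeding(table))


def summarize_inbreeding(table: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean per method, mirroring the descriptive-statistics layout."""
    rows = []
    for method in ("f_grm", "f_hom", "f_uni"):
        vals = table[method].to_numpy(dtype=float)
        rows.append(
            {
                "method": method.upper(),
                "min": float(np.nanmin(vals)),
                "max": float(np.nanmax(vals)),
                "mean": float(np.nanmean(vals)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending, clamped at 0
    scores: pd.DataFrame  # sample_id + PC1..PCk
    explained_pct: np.ndarray  # over all components, sums to 100


def pca_from_grm(grm: GRMResult, k: int = 10) -> PCAResult:
    """Principal components of the samples from the GRM eigendecomposition.

    Component scores are eigenvector × sqrt(eigenvalue).  The sign of each
    component is fixed so its largest-magnitude loading is positive, making
    plots reproducible.  ``k`` is clamped to the sample count.
    """
    n = grm.matrix.shape[0]
    if k > n:
        log.warning("pca_from_grm: k=%d clamped to n_samples=%d", k, n)
        k = n
    evals, evecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals_clamped = np.clip(evals, 0.0, None)
    total = evals_clamped.sum()
    explained = 100.0 * evals_clamped / total if total > 0 else np.zeros_like(evals)

    scores = np.empty((n, k))
    for j in range(k):
        v = evecs[:, j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        scores[:, j] = v * np.sqrt(evals_clamped[j])
    df = pd.DataFrame(scores, columns=[f"PC{j + 1}" for j in range(k)])
    df.insert(0, "sample_id", grm.sample_ids)
    return PCAResult(eigenvalues=evals_clamped, scores=df, explained_pct=explained)


def write_grm_text(grm: GRMResult, prefix: str) -> None:
    """GCTA-style text output: lower triangle TSV plus a sample-id list."""
    n = len(grm.sample_ids)
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_sites_used}\t{grm.matrix[i, j]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")
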