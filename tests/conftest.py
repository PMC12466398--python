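"""Shared fixtures and independent brute-force oracles.

The oracle functions below are deliberately written as explicit loops over
samples and sites, straight from the printed formulas, so they share no code
path with the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from equifix.synthetic_cohort import (
    CohortSimSpec,
    FixedVariantSpec,
    simulate_cohort,
)

MISSING = -1


# ---------------------------------------------------------------------------
# Brute-force oracles (explicit loops, no numpy vectorization)
# ---------------------------------------------------------------------------


def oracle_site_freq(codes, site):
    """Alternate-allele frequency at one site from non-missing calls."""
    alt = tot = 0
    for s in range(len(codes)):
        c = codes[s][site]
        if c != MISSING:
            alt += c
            tot += 2
    return alt / tot if tot else float("nan")


def oracle_grm(codes):
    """VanRaden method-1 GRM: Z = x − 2p, pooled 2Σp(1−p) denominator.

    Missing codes are imputed to 2p (zero after centering), matching the
    documented policy.
    """
    n = len(codes)
    m = len(codes[0])
    p = [oracle_site_freq(codes, i) for i in range(m)]
    denom = sum(2.0 * pi * (1.0 - pi) for pi in p)
    grm = [[0.0] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            acc = 0.0
            for i in range(m):
                za = (codes[a][i] - 2 * p[i]) if codes[a][i] != MISSING else 0.0
                zb = (codes[b][i] - 2 * p[i]) if codes[b][i] != MISSING else 0.0
                acc += za * zb
            grm[a][b] = acc / denom
    return grm


def oracle_f_grm(codes):
    grm = oracle_grm(codes)
    return [grm[i][i] - 1.0 for i in range(len(codes))]


def oracle_f_hom(codes):
    """(N_OHom − N_EHom) / (N_NonMiss − N_EHom) per sample."""
    n = len(codes)
    m = len(codes[0])
    p = [oracle_site_freq(codes, i) for i in range(m)]
    out = []
    for s in range(n):
        n_ohom = n_ehom = n_nonmiss = 0.0
        for i in range(m):
            c = codes[s][i]
            if c == MISSING:
                continue
            n_nonmiss += 1
            if c in (0, 2):
                n_ohom += 1
            n_ehom += 1.0 - 2.0 * p[i] * (1.0 - p[i])
        out.append((n_ohom - n_ehom) / (n_nonmiss - n_ehom))
    return out


def oracle_f_uni(codes):
    """Mean per-site (x² − (1+2p)x + 2p²) / (2p(1−p)) over non-missing sites."""
    n = len(codes)
    m = len(codes[0])
    p = [oracle_site_freq(codes, i) for i in range(m)]
    out = []
    for s in range(n):
        acc = 0.0
        cnt = 0
        for i in range(m):
            x = codes[s][i]
            if x == MISSING:
                continue
            pi = p[i]
            acc += (x * x - (1.0 + 2.0 * pi) * x + 2.0 * pi * pi) / (2.0 * pi * (1.0 - pi))
            cnt += 1
        out.append(acc / cnt)
    return out


def oracle_pairwise_pi(codes, site):
    """Mean allele mismatch over all C(n,2) pairs of sequences at one site.

    Each diploid contributes two sequences; heterozygotes contribute one
    reference and one alternate allele (the mismatch count depends only on
    allele counts, not on phase).
    """
    alleles = []
    for s in range(len(codes)):
        c = codes[s][site]
        if c == MISSING:
            continue
        alleles.extend([1] * c + [0] * (2 - c))
    n = len(alleles)
    if n < 2:
        return None
    diff = pairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            pairs += 1
            if alleles[a] != alleles[b]:
                diff += 1
    return diff / pairs


def polymorphic_codes(codes: np.ndarray) -> np.ndarray:
    """Keep only columns polymorphic in the sample (0 < p < 1)."""
    obs = codes != MISSING
    alt = np.where(obs, codes, 0).sum(axis=0)
    tot = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = alt / np.maximum(tot, 1)
    keep = (tot > 0) & (p > 0) & (p < 1)
    return codes[:, keep]


def random_codes(
    rng: np.random.Generator, n_samples: int, n_sites: int, missing_rate: float = 0.1
) -> np.ndarray:
    """Random polymorphic dosage matrix with missing entries."""
    while True:
        codes = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
        mask = rng.random((n_samples, n_sites)) < missing_rate
        codes[mask] = MISSING
        # no all-missing samples
        if (codes == MISSING).all(axis=1).any():
            continue
        codes = polymorphic_codes(codes)
        if codes.shape[1] >= max(2, n_sites // 2):
            return codes


# ---------------------------------------------------------------------------
# Cohort fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A compact simulated cohort reused by summary/cascade tests."""
    from equifix.synthetic_cohort import default_chromosomes

    spec = CohortSimSpec(
        chromosomes=default_chromosomes(scale=0.4),
        fixed_variant_spec=FixedVariantSpec(n_background=25),
        seed=11,
    )
    return simulate_cohort(spec, tmp_path_factory.mktemp("small_cohort"))


@pytest.fixture(scope="session")
def small_cohort_records(small_cohort):
    return small_cohort.records()
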