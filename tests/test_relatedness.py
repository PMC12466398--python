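"""GRM, inbreeding estimators and PCA: hand examples, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from conftest import (
    MISSING,
    oracle_f_grm,
    oracle_f_hom,
    oracle_f_uni,
    oracle_grm,
    polymorphic_codes,
    random_codes,
)

from equifix.relatedness import (
    build_grm,
    f_grm,
    f_hom,
    f_uni,
    inbreeding_table,
    pca_from_grm,
    summarize_inbreeding,
)
from equifix.synthetic_cohort import sample_allele_freqs, sample_genotype_codes
from equifix.variant_store import GenotypeMatrix


def _matrix(codes):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    sites = pd.DataFrame(
        {"chrom": ["1"] * m, "pos": range(10, 10 + m), "ref": ["A"] * m, "alt": ["T"] * m}
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], sites, codes)


def test_grm_two_sample_hand_product():
    """One site, codes (0, 2): Z = (−1, +1), denom 0.5 → [[2,−2],[−2,2]]."""
    grm = build_grm(_matrix([[0], [2]]))
    np.testing.assert_allclose(grm.matrix, [[2, -2], [-2, 2]], atol=1e-12)
    np.testing.assert_allclose(f_grm(grm), [1.0, 1.0], atol=1e-12)


def test_all_het_single_sample_centering():
    """All-het genome at p=0.5: Z is zero → GRM diagonal 0 → F_GRM = −1."""
    grm = build_grm(_matrix([[1, 1, 1, 1]]))
    assert grm.matrix[0, 0] == pytest.approx(0.0, abs=1e-12)
    assert f_grm(grm)[0] == pytest.approx(-1.0)


def test_f_hom_forced_extremes():
    # sample frequencies are 0.5 at both loci; an all-het sample scores
    # (0-1)/(2-1) = -1 and an all-hom sample (2-1)/(2-1) = +1
    m = _matrix([[1, 1], [0, 2], [1, 1], [2, 0]])
    assert f_hom(m)[:2] == pytest.approx([-1.0, 1.0])


def test_f_uni_per_site_terms():
    """x=1 at p=0.5 contributes −1; x∈{0,2} contribute +1."""
    m = _matrix([[1, 1], [0, 2], [1, 1], [2, 0]])
    np.testing.assert_allclose(f_uni(m)[:2], [-1.0, 1.0], atol=1e-12)
    # all-het genome: F_UNI = F_HOM = -1 on the same input
    het = _matrix([[1, 1, 1], [1, 1, 1], [0, 2, 0], [2, 0, 2]])
    np.testing.assert_allclose(f_uni(het)[:2], f_hom(het)[:2], atol=1e-12)


def test_estimators_match_bruteforce_small_matrices():
    """All three estimators equal explicit-loop oracles to 1e-10 (≤8×30)."""
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        codes = random_codes(rng, n_samples=8, n_sites=30, missing_rate=0.1)
        m = _matrix(codes)
        np.testing.assert_allclose(
            build_grm(m).matrix, oracle_grm(codes.tolist()), atol=1e-10
        )
        np.testing.assert_allclose(f_grm(build_grm(m)), oracle_f_grm(codes.tolist()), atol=1e-10)
        np.testing.assert_allclose(f_hom(m), oracle_f_hom(codes.tolist()), atol=1e-10)
        np.testing.assert_allclose(f_uni(m), oracle_f_uni(codes.tolist()), atol=1e-10)


def test_allele_swap_invariance():
    """Flipping ref/alt at every site leaves GRM and all three F unchanged."""
    rng = np.random.default_rng(9)
    codes = random_codes(rng, n_samples=6, n_sites=25, missing_rate=0.1)
    m, mswap = _matrix(codes), _matrix(codes).swapped_alleles()
    np.testing.assert_allclose(build_grm(m).matrix, build_grm(mswap).matrix, atol=1e-10)
    np.testing.assert_allclose(f_hom(m), f_hom(mswap), atol=1e-10)
    np.testing.assert_allclose(f_uni(m), f_uni(mswap), atol=1e-10)


def test_site_order_invariance():
    rng = np.random.default_rng(11)
    codes = random_codes(rng, n_samples=6, n_sites=25, missing_rate=0.0)
    perm = rng.permutation(codes.shape[1])
    m1, m2 = _matrix(codes), _matrix(codes[:, perm])
    np.testing.assert_allclose(build_grm(m1).matrix, build_grm(m2).matrix, atol=1e-12)
    np.testing.assert_allclose(f_uni(m1), f_uni(m2), atol=1e-12)


def test_monomorphic_site_is_hard_error():
    with pytest.raises(ValueError, match="monomorphic"):
        build_grm(_matrix([[0, 1], [0, 1]]))  # first site all-ref


def test_all_missing_sample_named_in_error():
    codes = np.array([[1, 0], [0, 1], [MISSING, MISSING]])
    with pytest.raises(ValueError, match="s2"):
        build_grm(_matrix(codes))


def test_f_grm_recovers_true_inbreeding():
    """True F = 0.2, 200 samples × 50k sites: mean F_GRM within ±0.02."""
    rng = np.random.default_rng(2024)
    p = sample_allele_freqs(("beta", 2.0, 2.0), 50_000, rng)
    codes = sample_genotype_codes(p, 0.2, n_samples=200, rng=rng)
    m = _matrix(polymorphic_codes(codes))
    assert float(np.mean(f_grm(build_grm(m)))) == pytest.approx(0.2, abs=0.02)


def test_grm_trace_near_one_without_inbreeding():
    """trace(GRM)/n → 1 as true F → 0 (tolerance 0.02)."""
    rng = np.random.default_rng(55)
    p = sample_allele_freqs(("beta", 2.0, 2.0), 20_000, rng)
    codes = sample_genotype_codes(p, 0.0, n_samples=100, rng=rng)
    grm = build_grm(_matrix(polymorphic_codes(codes)))
    assert np.trace(grm.matrix) / 100 == pytest.approx(1.0, abs=0.02)


def test_inbreeding_summary_schema_and_null_cohort():
    """Min/max/mean per method; all-F=0 cohort means inside ±0.05."""
    rng = np.random.default_rng(31)
    p = sample_allele_freqs(("beta", 2.0, 2.0), 20_000, rng)
    codes = sample_genotype_codes(p, 0.0, n_samples=50, rng=rng)
    result = inbreeding_table(_matrix(polymorphic_codes(codes)))
    assert list(result.summary.columns) == ["method", "min", "max", "mean"]
    assert set(result.summary.method) == {"F_GRM", "F_HOM", "F_UNI"}
    for mean in result.summary["mean"]:
        assert -0.05 <= mean <= 0.05
    # summary reproducible from the per-sample table
    re = summarize_inbreeding(result.table)
    pd.testing.assert_frame_equal(re, result.summary)


def test_pca_identity_grm():
    from equifix.relatedness import GRMResult

    grm = GRMResult(np.eye(4), [f"s{i}" for i in range(4)], 10, 5.0)
    res = pca_from_grm(grm, k=4)
    np.testing.assert_allclose(res.eigenvalues, np.ones(4))
    np.testing.assert_allclose(res.explained_pct, [25.0] * 4)


def test_pca_two_by_two_closed_form():
    from equifix.relatedness import GRMResult

    grm = GRMResult(np.array([[2.0, -2.0], [-2.0, 2.0]]), ["a", "b"], 1, 0.5)
    res = pca_from_grm(grm, k=2)
    np.testing.assert_allclose(res.eigenvalues, [4.0, 0.0], atol=1e-12)
    assert res.explained_pct[0] == pytest.approx(100.0)
    # scores: eigenvector (±1/√2) × sqrt(4) = ±√2, sign convention positive lead
    assert sorted(res.scores.PC1.tolist()) == pytest.approx([-np.sqrt(2), np.sqrt(2)])


def test_pca_separates_planted_subpopulations():
    """Two duplicated subpopulations get opposite-sign PC1 scores."""
    rng = np.random.default_rng(13)
    m_sites = 2_000
    pa = sample_allele_freqs(("beta", 2.0, 2.0), m_sites, rng)
    pb = np.clip(pa + rng.choice([-0.3, 0.3], size=m_sites), 0.05, 0.95)
    codes_a = sample_genotype_codes(pa, 0.0, n_samples=10, rng=rng)
    codes_b = sample_genotype_codes(pb, 0.0, n_samples=10, rng=rng)
    codes = polymorphic_codes(np.vstack([codes_a, codes_b]))
    res = pca_from_grm(build_grm(_matrix(codes)), k=2)
    pc1 = res.scores.PC1.to_numpy()
    assert (np.sign(pc1[:10]) == np.sign(pc1[0])).all()
    assert (np.sign(pc1[10:]) == -np.sign(pc1[0])).all()


def test_pca_k_clamped():
    from equifix.relatedness import GRMResult

    grm = GRMResult(np.eye(3), ["a", "b", "c"], 5, 2.0)
    assert pca_from_grm(grm, k=10).scores.shape == (3, 4)  # sample_id + 3 PCs
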