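"""Data model, VCF round-trip, annotation parsing and matrix construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equifix.variant_store import (
    MISSING,
    AnnotationRecord,
    EmptyMatrixError,
    ConfigurationError,
    VariantRecord,
    build_genotype_matrix,
    classify_variant,
    impact_of,
    is_autosome,
    most_severe,
    most_severe_per_gene,
    normalize_chrom,
    parse_annotation_field,
    read_vcf,
    write_vcf,
)


def _rec(chrom, pos, ref, alts, gts, depths=None, ann=()):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=list(alts),
        genotypes=gts,
        depths=depths or [],
        annotations=list(ann),
    )


@pytest.mark.parametrize(
    "ref,alts,expected",
    [
        ("C", ["T"], ("biallelic", "SNP")),
        ("C", ["T", "CA"], ("multiallelic", "mixed")),
        ("AC", ["A"], ("biallelic", "indel")),
        ("A", ["T", "G"], ("multiallelic", "SNP")),
        ("AT", ["GC"], ("biallelic", "mixed")),  # MNP-like
        ("A", ["<DEL>"], ("biallelic", "mixed")),  # symbolic
    ],
)
def test_classify_variant(ref, alts, expected):
    gts = [(0, 0)] * 3
    assert classify_variant(_rec("1", 100, ref, alts, gts)) == expected


def test_classify_is_pure():
    rec = _rec("1", 100, "C", ["T"], [(0, 1)])
    assert classify_variant(rec) == classify_variant(rec)


def test_vcf_round_trip(tmp_path):
    """CHROM/POS/REF/ALT/GT/DP survive a write-then-read cycle bit-exactly."""
    records = [
        _rec("1", 100, "C", ["T"], [(0, 1), (1, 1), (0, 0)], [12, 9, 30]),
        _rec("1", 200, "AC", ["A"], [(0, 0), (MISSING, MISSING), (1, 1)]),
        _rec("2", 50, "G", ["A", "GT"], [(1, 2), (0, 1), (0, 0)], [8, 11, None]),
    ]
    path = tmp_path / "toy.vcf"
    write_vcf(records, path, ["s1", "s2", "s3"], contigs=[("1", 1000), ("2", 1000)])
    back = list(read_vcf(path))
    assert len(back) == 3
    for orig, rt in zip(records, back):
        assert (rt.chrom, rt.pos, rt.ref, rt.alts) == (orig.chrom, orig.pos, orig.ref, orig.alts)
        assert rt.genotypes == orig.genotypes
        expected_dp = orig.depths if orig.depths else [None] * orig.n_samples
        assert rt.depths == expected_dp


def test_read_vcf_unknown_sample_errors(tmp_path):
    path = tmp_path / "toy.vcf"
    write_vcf([_rec("1", 1, "A", ["T"], [(0, 1)])], path, ["s1"])
    with pytest.raises(ConfigurationError, match="nope"):
        list(read_vcf(path, sample_subset=["nope"]))


def test_csq_annotation_round_trip(tmp_path):
    """A VEP-style CSQ string parses to consequence + derived impact."""
    ann = AnnotationRecord.from_consequence("missense_variant", "GENE1", "G1")
    path = tmp_path / "ann.vcf"
    write_vcf([_rec("1", 100, "C", ["T"], [(0, 1)], [10], [ann])], path, ["s1"])
    (rec,) = read_vcf(path)
    (parsed,) = rec.annotations
    assert parsed.consequence == "missense_variant"
    assert parsed.impact == "MODERATE"
    assert parsed.gene_id == "GENE1"
    assert parsed.is_exonic


def test_parse_ann_dialect():
    """SnpEff ANN field layout maps onto the same schema."""
    fields = ["Allele", "Annotation", "Annotation_Impact", "Gene_Name", "Gene_ID"]
    (a,) = parse_annotation_field("T|stop_gained&splice_region_variant|HIGH|SYM|G9", fields, "ANN")
    assert a.consequence == "stop_gained"  # most severe of the "&" pair
    assert a.impact == "HIGH"
    assert a.gene_id == "G9"
    assert a.gene_symbol == "SYM"


@pytest.mark.parametrize(
    "term,impact",
    [
        ("frameshift_variant", "HIGH"),
        ("missense", "MODERATE"),
        ("synonymous_variant", "LOW"),
        ("intergenic_variant", "MODIFIER"),
        ("5'UTR", "MODIFIER"),
        ("some_novel_term", "MODIFIER"),
    ],
)
def test_impact_mapping_handles_aliases(term, impact):
    assert impact_of(term) == impact


def test_most_severe_per_gene_reduction():
    anns = [
        AnnotationRecord.from_consequence("intron_variant", "G1"),
        AnnotationRecord.from_consequence("missense_variant", "G1"),
        AnnotationRecord.from_consequence("synonymous_variant", "G2"),
    ]
    best = most_severe_per_gene(anns)
    assert best["G1"].consequence == "missense_variant"
    assert best["G2"].consequence == "synonymous_variant"
    assert most_severe(anns).consequence == "missense_variant"


def test_build_matrix_filters_and_codes():
    records = [
        _rec("1", 10, "A", ["T"], [(0, 0), (0, 1), (1, 1), (MISSING, MISSING)]),
        _rec("1", 20, "C", ["G", "T"], [(0, 1)] * 4),  # multiallelic -> out
        _rec("1", 30, "G", ["A"], [(0, 1)] * 4),
        _rec("1", 40, "T", ["C", "A"], [(0, 2)] * 4),  # multiallelic -> out
        _rec("1", 50, "A", ["AG"], [(1, 1)] * 4),
    ]
    m = build_genotype_matrix(records)
    assert m.n_sites == 3
    np.testing.assert_array_equal(m.codes[:, 0], [0, 1, 2, MISSING])
    assert m.p[0] == pytest.approx(0.5)  # 3 alt alleles / 6 called


def test_maf_threshold_is_strict():
    # p = 1/40 = 0.025 <= 0.05 -> excluded; p = 0.5 kept
    rare = _rec("1", 10, "A", ["T"], [(0, 1)] + [(0, 0)] * 19)
    common = _rec("1", 20, "A", ["T"], [(0, 1)] * 20)
    m = build_genotype_matrix([rare, common], maf_gt=0.05)
    assert m.n_sites == 1
    assert m.sites.iloc[0].pos == 20
    with pytest.raises(EmptyMatrixError):
        build_genotype_matrix([rare], maf_gt=0.05)


def test_matrix_freq_identity(small_cohort_records):
    """mean(codes)/2 over non-missing equals the stored p at every site."""
    m = build_genotype_matrix(small_cohort_records)
    obs = m.codes != MISSING
    manual = np.where(obs, m.codes, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
    np.testing.assert_allclose(m.p, manual, atol=1e-12)


def test_classification_partitions_records(small_cohort_records):
    """biallelic SNP + biallelic indel + multiallelic + mixed == total."""
    n = len(small_cohort_records)
    counts = {"bi_snp": 0, "bi_indel": 0, "multi": 0, "mixed": 0}
    for rec in small_cohort_records:
        allelicity, vtype = classify_variant(rec)
        if allelicity == "multiallelic":
            counts["multi"] += 1
        elif vtype == "SNP":
            counts["bi_snp"] += 1
        elif vtype == "indel":
            counts["bi_indel"] += 1
        else:
            counts["mixed"] += 1
    assert sum(counts.values()) == n
    assert counts["bi_snp"] + counts["bi_indel"] <= n


@pytest.mark.parametrize(
    "name,expected",
    [
        ("NC_009144.3", "1"),
        ("NC_009175.3", "X"),
        ("chr5", "5"),
        ("ECA23", "23"),
        ("31", "31"),
        ("scaffold_12", "scaffold_12"),
    ],
)
def test_chromosome_aliases(name, expected):
    assert normalize_chrom(name) == expected
    assert is_autosome("NC_009144.3")
    assert not is_autosome("NC_009175.3")


@settings(derandomize=True, max_examples=50)
@given(
    ref=st.sampled_from(["A", "C", "AT", "GGC"]),
    alts=st.lists(st.sampled_from(["A", "T", "G", "AT", "TTA"]), min_size=1, max_size=3),
)
def test_classify_total_over_allele_space(ref, alts):
    alts = [a for a in alts if a != ref] or ["T" if ref != "T" else "G"]
    allelicity, vtype = classify_variant(_rec("1", 5, ref, alts, [(0, 0)]))
    assert allelicity in ("biallelic", "multiallelic")
    assert vtype in ("SNP", "indel", "mixed")
    assert allelicity == ("biallelic" if len(alts) == 1 else "multiallelic")
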