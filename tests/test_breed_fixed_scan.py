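"""Fixed-variant cascade filters and candidate-gene selection."""

import numpy as np
import pytest

from equifix.breed_fixed_scan import (
    autosome_filter,
    depth_filter,
    fixed_alt_filter,
    fixed_variant_cascade,
    pcg_select,
)
from equifix.synthetic_cohort import (
    CohortSimSpec,
    FixedVariantSpec,
    default_chromosomes,
    make_gene_models,
    simulate_cohort,
)
from equifix.variant_store import MISSING, AnnotationRecord, VariantRecord


def _rec(chrom="1", pos=100, gts=None, depths=None, ann=()):
    gts = gts if gts is not None else [(1, 1)] * 20
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alts=["T"],
        genotypes=gts, depths=depths or [], annotations=list(ann),
    )


class TestFixedAltFilter:
    def test_all_hom_alt_kept(self):
        assert len(fixed_alt_filter([_rec()])) == 1

    def test_one_het_drops_site(self):
        gts = [(1, 1)] * 19 + [(0, 1)]
        assert fixed_alt_filter([_rec(gts=gts)]) == []

    def test_missing_genotype_disqualifies_strictly(self):
        gts = [(1, 1)] * 19 + [(MISSING, MISSING)]
        assert fixed_alt_filter([_rec(gts=gts)]) == []
        # relaxed policy keeps it
        assert len(fixed_alt_filter([_rec(gts=gts)], allow_missing=True)) == 1


class TestDepthFilter:
    def test_boundary_inclusive(self):
        assert len(depth_filter([_rec(depths=[10] * 20)])) == 1

    def test_single_low_sample_drops(self):
        assert depth_filter([_rec(depths=[10] * 19 + [9])]) == []

    def test_missing_dp_drops(self):
        assert depth_filter([_rec(depths=[10] * 19 + [None])]) == []
        assert depth_filter([_rec()]) == []  # no DP at all

    def test_fixture_bookkeeping(self):
        recs = [
            _rec(pos=1, depths=[15] * 20),
            _rec(pos=2, depths=[10] * 20),
            _rec(pos=3, depths=[30] * 20),
            _rec(pos=4, depths=[9] * 20),
            _rec(pos=5, depths=[10] * 19 + [0]),
            _rec(pos=6, depths=[10] * 19 + [None]),
        ]
        survivors = depth_filter(recs)
        assert [r.pos for r in survivors] == [1, 2, 3]


def test_autosome_filter_drops_x_and_unplaced():
    recs = [_rec(chrom="1"), _rec(chrom="X"), _rec(chrom="scaffold_9"), _rec(chrom="NC_009166.3")]
    assert [r.chrom for r in autosome_filter(recs)] == ["1", "NC_009166.3"]


def _exonic(gene, n, consequence="missense_variant", chrom="1", start=100):
    return [
        _rec(chrom=chrom, pos=start + i,
             ann=[AnnotationRecord.from_consequence(consequence, gene_id=gene)])
        for i in range(n)
    ]


class TestPCGSelect:
    def test_threshold_boundary(self):
        entries = pcg_select(_exonic("G1", 5))
        assert len(entries) == 1
        assert entries[0].gene_id == "G1" and entries[0].n_qualifying_variants == 5

    def test_below_threshold_excluded(self):
        assert pcg_select(_exonic("G1", 4)) == []

    def test_low_impact_exonic_does_not_count(self):
        assert pcg_select(_exonic("G1", 6, consequence="synonymous_variant")) == []

    def test_non_exonic_high_does_not_count(self):
        # splice_donor is HIGH but not an exon-placed consequence
        assert pcg_select(_exonic("G1", 6, consequence="splice_donor_variant")) == []

    def test_multi_gene_annotation_counts_once_per_gene(self):
        ann = [
            AnnotationRecord.from_consequence("missense_variant", gene_id="G1"),
            AnnotationRecord.from_consequence("missense_variant", gene_id="G2"),
        ]
        recs = [_rec(pos=100 + i, ann=ann) for i in range(5)]
        entries = pcg_select(recs)
        assert {e.gene_id for e in entries} == {"G1", "G2"}
        assert all(e.n_qualifying_variants == 5 for e in entries)

    def test_sorted_by_chromosome_then_start(self):
        recs = _exonic("GB", 5, chrom="10") + _exonic("GA", 5, chrom="2")
        assert [e.chrom for e in pcg_select(recs)] == ["2", "10"]


@pytest.fixture(scope="module")
def planted_cohort(tmp_path_factory):
    """40 autosomal genes, 9 planted with ≥5 qualifying fixed exon variants."""
    chroms = default_chromosomes(scale=0.5)
    genes = [g for g in make_gene_models(chroms, genes_per_chrom=2) if g.chrom != "X"][:40]
    planted = {genes[i].gene_id: 5 + (i % 4) for i in range(0, 27, 3)}  # 9 genes
    spec = CohortSimSpec(
        chromosomes=chroms,
        gene_models=genes,
        fixed_variant_spec=FixedVariantSpec(
            n_background=30, plantings=tuple(planted.items())
        ),
        seed=101,
    )
    cohort = simulate_cohort(spec, tmp_path_factory.mktemp("planted"))
    return cohort, planted


def test_planted_pcg_recovery(planted_cohort):
    """Sensitivity and specificity 1.0 against the planted truth."""
    cohort, planted = planted_cohort
    report = fixed_variant_cascade(cohort.records(), genes=cohort.gene_models)
    found = {e.gene_id for e in report.pcgs}
    assert found == set(planted)
    by_id = {e.gene_id: e for e in report.pcgs}
    for gene_id, n in planted.items():
        assert by_id[gene_id].n_qualifying_variants >= n


def test_cascade_monotone_and_order_invariant(planted_cohort):
    cohort, _ = planted_cohort
    records = cohort.records()
    report = fixed_variant_cascade(records, genes=cohort.gene_models)
    c = report.stage_counts
    assert c["input"] >= c["fixed_alt"] >= c["depth_pass"] >= c["autosomal"] >= c["exonic_high_moderate"]
    # shuffling the input leaves survivors and PCG counts unchanged
    rng = np.random.default_rng(0)
    shuffled = [records[i] for i in rng.permutation(len(records))]
    report2 = fixed_variant_cascade(shuffled, genes=cohort.gene_models)
    assert report2.stage_counts == c
    assert {(r.chrom, r.pos) for r in report2.survivors} == {
        (r.chrom, r.pos) for r in report.survivors
    }
    assert report2.pcgs == report.pcgs


def test_cascade_stage_subsets(planted_cohort):
    """Each stage's survivor set is a subset of the previous stage's."""
    cohort, _ = planted_cohort
    records = cohort.records()
    fixed = fixed_alt_filter(records)
    deep = depth_filter(fixed)
    auto = autosome_filter(deep)
    keys = lambda rs: {(r.chrom, r.pos) for r in rs}
    assert keys(deep) <= keys(fixed) <= keys(records)
    assert keys(auto) <= keys(deep)
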