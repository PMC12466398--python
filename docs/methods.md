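# Methods

This note documents the statistical models, conventions and numerical
choices behind equifix, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model and conventions

All statistics operate on a samples × sites matrix of alternate-allele
dosage codes {0, 1, 2} with −1 for missing, restricted to biallelic,
non-symbolic sites. Positions are 1-based (VCF convention); windows are
1-based half-open `[start, start + W)`. Per-site allele frequencies are
always recomputed from the sample genotypes (non-missing alleles only) —
the VCF `INFO/AF` field is carried along for reporting but never used in a
formula. Multiallelic sites are counted in summaries but never decomposed
into the matrix, since every matrix-based statistic here is defined on
biallelic loci.

The focal allele is the ALTERNATE allele throughout. Some printed forms of
the uniting-gametes estimator count the reference allele instead; all three
inbreeding estimators are algebraically invariant to which allele is focal
(the test suite proves this by flipping ref/alt at every site), so one
consistent orientation is used.

Consequence annotations (VEP `CSQ` or SnpEff `ANN`) are reduced to a fixed
ontology of 21 Sequence Ontology terms. Impact (HIGH / MODERATE / LOW /
MODIFIER) is always re-derived from the consequence term by the standard
VEP mapping, regardless of what the annotator wrote, so one mapping governs
the whole pipeline. Multiple transcripts per variant are allowed; gene-level
logic uses the most severe consequence per gene, and variant-level summaries
use the single most severe consequence overall so functional classes
partition the biallelic set. Chromosome labels accept plain numbers,
`chr`/`ECA` prefixes and EquCab3.0 RefSeq accessions via a built-in alias
table; unknown contigs are kept in an explicit "unplaced" bucket.

## Heterozygosity and nucleotide diversity

Per site, `Ho` = heterozygous calls / non-missing calls and `He` = 2p(1−p)
from the sample frequency. Genome means are across sites (per-sample
heterozygous fractions are also reported, for QC). `He` uses the plain
2p(1−p) by default; the 2n/(2n−1) small-sample correction is available as a
flag. Nucleotide diversity uses the unbiased pairwise form per site,
π_site = 2j(n−j)/[n(n−1)], which equals the mean allele mismatch over all
C(n, 2) pairs of sequences (each diploid contributing two sequences).

Window π divides the summed site contributions by the *full* window length:
positions absent from the VCF are assumed invariant. This is the common
VCF-only convention; it understates π if the callable fraction is low.
Defaults are 10 kb non-overlapping windows over autosomes, both
configurable; with overlapping windows a site contributes to every window
covering it, and the genome mean is the callable-length-weighted mean over
windows. Sites with fewer than two called alleles are skipped and counted.

## GRM and inbreeding estimators

The GRM uses pooled-denominator centering (VanRaden method 1): Z = X − 2p
per site, G = ZZ′ / 2Σp(1−p). A `per_site=True` flag switches to per-site
standardization (each site divided by √(2p(1−p)), mean over sites), which
is what GCTA's default diagonal uses; the two differ slightly on real data
because rare sites get more weight under per-site scaling. F_GRM is the
diagonal minus one; under the pooled form its expectation at true
inbreeding F is F itself, which the parameter-recovery tests confirm.

Missing-genotype policy differs by estimator, deliberately: the GRM imputes
a missing code to 2p (zero after centering, keeping G positive
semidefinite and the sample count constant), while F_HOM and F_UNI skip
missing sites per sample with their denominators reduced accordingly.
Frequencies include the focal individual. Monomorphic sites reaching an
estimator are a hard error — the MAF filter (strictly > 0.05 by default,
applied before GRM/PCA) must remove them upstream.

PCA is an eigendecomposition of G. Eigenvalues are clamped at zero (G is
PSD up to rounding), explained-variance percentages are eigenvalue over the
sum of all eigenvalues, scores are eigenvector × √eigenvalue, and each
component's sign is fixed so its largest-magnitude loading is positive,
making plots reproducible across BLAS builds.

## Fixed-variant cascade and candidate genes

Stage order is fixed-alternate → depth → autosomes, matching the narrative
order of the analysis this pipeline operationalizes. "Fixed" means every
sample is a called homozygote for the alternate allele; a single missing
genotype disqualifies the site under the strict default (a flag relaxes to
"all non-missing calls are hom-alt"). The depth filter requires DP ≥ 10 in
*every* sample, bound inclusive; missing DP drops the site conservatively.
"Exon variants" are the consequence terms that place the allele inside an
exon (missense, synonymous, stop/start gain/loss, frameshift, inframe
indels, protein-altering, coding-sequence, stop-retained, non-coding
exon); UTR terms are excluded by default with a flag to include them, and
splice-donor/acceptor variants — HIGH impact but intronic — never count as
exonic. A gene qualifies as a prioritized candidate with ≥5 distinct
surviving exon variants of HIGH or MODERATE impact; a variant annotated to
several genes counts once per gene. The impact set is a parameter because
"high or moderate" and "high-impact" are both defensible readings of the
selection rule.

## Trait-catalog scan

Catalog entries match VCF records exactly on (chromosome, position, ref,
alt) after chromosome aliasing and left-normalization (trim shared suffix,
then shared prefix, advancing the position) on both sides — this is what
lets an HGVS-style delins coordinate meet the anchor-base VCF encoding of
the same allele. A record at the right position with incompatible alleles
is still reported, flagged. MAF is the folded frequency
min(c, 2N−c)/2N with c = n_het + 2·n_hom_alt over non-missing samples.
"Segregating" is defined as ≥1 observed copy of the non-reference allele
and not fixed; fixed variants are listed separately rather than silently
dropped. Catalog allele labels are reported as given in the catalog file;
the computed MAF always comes from the genotypes.

## Synthetic cohorts: what they emulate and what they don't

The generator draws sites along a miniature 32-chromosome genome (31
autosomes shrinking from 1.6 Mb to 0.4 Mb, plus X at 1 Mb, ~1 variant per
5 kb by default — small enough that whole-cohort simulation runs in
seconds while preserving the many-chromosome layout). Alternate-allele
frequencies come from a configurable family (default Beta(0.5, 0.5),
clipped to (0.01, 0.99)); 10% of sites are indels and 8% multiallelic,
roughly the proportions seen in mammalian WGS call sets. Genotypes are
drawn from the F-adjusted Hardy–Weinberg triple

    P(hom-ref) = (1−p)² + Fp(1−p)
    P(het)     = 2p(1−p)(1−F)
    P(hom-alt) = p² + Fp(1−p)

with per-sample F; probabilities that go negative under strongly negative F
are clamped to zero and renormalized (logged). Depths are Poisson with a
per-sample mean (default 20×, typical of a ~380 M-read short-read run on a
2.5 Gb genome). Annotations are geometric: intergenic if no gene within
5 kb (the standard VEP flank), upstream/downstream within the strand-aware
5 kb flank, intron inside a gene body, and exonic labels *drawn* from
configured weights — there is no codon model, which is acceptable because
every downstream consumer reads labels, not sequence.

Injections give the generator its ground truth: breed-fixed background
sites (all samples hom-alt), planted exonic HIGH/MODERATE fixed variants
inside named genes, and catalog variants at exact heterozygote counts.
Planted sites draw depth as floor + Poisson(mean − floor) with the floor at
the depth-filter threshold, so planted qualification is deterministic and
the candidate-gene recovery test has an exact truth set. Identical spec and
seed produce byte-identical output files.

Because inbreeding is simulated marginally per genotype, the cohorts carry
no linkage disequilibrium, no homozygosity tracts, no allele-frequency
correlation between neighbouring sites, and no genotyping error. Passing
parameter-recovery tests therefore shows the estimators implement their
formulas and are unbiased under their own sampling model — not that they
are robust to LD pruning choices, call errors or ROH structure in real
data.

## Test problem sizes and tolerances

Brute-force oracle comparisons (all three inbreeding estimators, window π)
run on ≤10 samples × ≤50 sites and assert agreement to 1e-10 — the oracles
are explicit loops over the printed formulas sharing no code with the
vectorized paths. Parameter recovery uses 200 samples × 1e5 sites at true
F ∈ {0, 0.1, 0.25} with fixed seeds, asserting cohort means within ±0.03;
the sampler itself is checked by a χ² goodness-of-fit at α = 0.001 on 1e5
draws. Calibration checks (He against the Beta-model expectation, the
Ho/He deficit slope against F) use 2% and ±0.05 tolerances respectively.
Candidate-gene recovery plants 9 qualifying genes among 40 and requires
sensitivity = specificity = 1. The full suite runs in well under a minute
on one core.

## Known limitations

- No ROH/IBD-segment analysis, no F_ST or cross-population statistics, no
  admixture modelling, and no variant calling or annotation — the VCF and
  its consequence strings are consumed as given.
- The window-π denominator assumes all unlisted positions are callable and
  invariant; there is no per-window callability mask.
- The dual variant-calling reconciliation some studies perform (joint vs.
  per-sample merged calling) is out of scope: one VCF in, one result set
  out.
- Orthologue/paralogue annotation of candidate genes requires external
  database lookups and is not attempted.
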