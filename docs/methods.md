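# Methods

## Statistical model

All inference is exact and small-sample; no asymptotic approximation or
multiple-testing correction is applied anywhere (each test runs at a fixed
per-test level, 5% by default and 1% in the stringent settings used for the
bundled analyses).

**Two-sided exact tests.** Both the binomial and the Fisher test report
two-sided p-values under the minimum-likelihood convention: the p-value is
the total probability of every outcome whose point probability does not
exceed the observed one. Because outcomes that are exactly symmetric can
differ in floating point, point probabilities within a relative 1e-7 of the
observed one are included in the sum. Hypergeometric point probabilities
are computed from log-factorials (`gammaln`), stable to table totals around
1e6; the binomial sum is delegated to `scipy.stats.binomtest`, which
implements the identical convention. The upper-tail Fisher test returns
P(X ≥ a) for the (1,1) cell conditional on the margins; a table with an
empty row or column margin carries no evidence and is defined to return 1.

**Genotyping.** At a known SNP with ref count r and alt count a
(n = r + a; reads showing a third base are ignored for calling because they
carry no information about the ref/alt balance):

* *htperc*: HET iff a/n lies in the closed interval [het_low, het_high]
  (defaults [0.2, 0.8]; the bounds themselves call HET); above the interval
  HOM_ALT, below HOM_REF; n below `min_depth` is NO_CALL.
* *binom*: exact two-sided test of a ~ Binomial(n, q) with q = 0.45 by
  default. The skew from 0.5 absorbs reference mapping bias — reads
  carrying the alternative allele align slightly less efficiently, so even
  true heterozygotes sit below 50% alt. p ≥ α retains heterozygosity
  (p = α stays HET, i.e. rejection is strict); otherwise the call is
  HOM_REF or HOM_ALT according to whether a/n falls below or above q. When
  either allele has zero coverage no HET is called regardless of the test
  (`require_both_alleles`, on by default); the guard can be lifted for
  low-coverage data, in which case the test alone decides — note that with
  a single read the test cannot reject and the call is HET.

**ASE calling.** Each heterozygous SNP with RNA counts (r, a) is tested
with the same binomial machinery at p = q = 0.5; rejection at `alpha_ase`
is evidence of allele-specific transcription. Because a deep RNA library
over a shallow DNA library (or vice versa) can reject 0.5 for trivial
reasons, a two-sided Fisher exact test compares the DNA (r,a) and RNA
(r,a) proportions whenever DNA counts are available; the SNP supports ASE
only if both tests fire. The gate can only remove calls — disabling it
(`rna_only`, or absent DNA counts) yields a superset of supporting SNPs.
SNPs with RNA depth below `min_rna_depth` are not evaluable. Per gene, the
ASE score is supporting/evaluable; the gene is ASE iff score strictly
exceeds `score_threshold` (default 0, so one supporting SNP suffices) and
high-ASE iff score > 0.5. A gene with zero evaluable SNPs is
NOT_AVAILABLE. The aggregate ASE-gene flag requires ASE status in at least
`min_samples` samples; availability requires RNA coverage only (DNA
coverage adequacy is the genotyper's `min_depth` concern upstream).

**Detection power.** T_a = Σ_i D_i (1 − (1 − I)^i) with D_i the number of
genes carrying exactly i coding SNPs and I the per-individual per-SNP
heterozygosity frequency; (1 − I)^i is P(no het SNP) for a gene with i
SNPs under uniform, independent heterozygosity. Computed in closed form
(not by simulation); a Monte-Carlo test confirms agreement within three
standard errors. The distribution D is accepted as a two-column file —
any SNP catalogue and gene model can feed it; the repository ships only
synthetic distributions, since any concrete D depends on the SNP-database
and gene-catalogue versions used to build it. The imprinted-gene
enrichment test forms the 2x2 table with the subset *excluded* from the
comparison group ([[k, K−k], [n−k, (N−K)−(n−k)]]) and reports the
upper-tail Fisher p-value; no test is performed when the subset has zero
ASE calls.

## Pileup engine

Positions are 1-based everywhere in memory and in VCF; BED input is
converted from 0-based half-open at the boundary. "Read quality" means
mapping quality. Secondary, supplementary and duplicate-marked alignments
are excluded by default (`include_flagged` re-admits them); deletions and
reference skips at the site, and non-ACGT bases, contribute nothing to
counts or depth. Both mates of an overlapping pair count by default
(`dedup_mates` keeps one per fragment). Strand counts are reported raw,
with no bias statistic. `min_depth` is applied by consumers, not by the
pileup writer, so the pileup table is complete. Parallelism is by threads
over partitions of the site list — static (contiguous sublists differing
in size by at most one, remainder to the earlier workers) or dynamic
(contiguous chunks claimed by idle workers); every worker opens its own
file handle and writes into a pre-allocated per-site slot, so the output
is byte-identical for any worker count and either strategy. A per-site
failure aborts the run with context; in batch mode a failing job reports
its error without stopping the other jobs.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
the physics of sequencing. Genes are laid out on one synthetic contig with
SNPs spaced 200 bp apart (farther than the 50 bp read length, so no read
spans two sites). Per-site depth is Poisson with the configured mean
(defaults 30 for both DNA and RNA, typical of exome/transcriptome coverage
at assayable SNPs; the recovery fixtures use 50). Genotypes are drawn per
site (het with probability `het_fraction`, the remainder split evenly
between the homozygotes); DNA het sites draw alt counts at fraction 0.5,
RNA het sites at 0.5 for balanced genes or `ase_allele_fraction` (default
0.95, near-mono-allelic transcription) for planted ASE genes. Sequencing
errors strike each read with `base_error_rate` and land on a uniformly
random non-truth base, so third-allele counts occur and exercise their
handling. Reads are single-end, fixed length, uniform base quality 30 and
mapping quality 60, with per-read degradation injectable to exercise the
filters. All randomness flows from one seed; identical configurations give
byte-identical files. Not modeled: fragmentation, GC and positional bias,
splicing, paired ends, copy-number aberrations, and reference mapping bias
in the *reads themselves* (DNA het sites are generated at 0.5, so a test
expecting 0.45 is conservative against these fixtures) — passing tests
therefore demonstrate correctness of the counting and inference machinery,
not robustness to real-library artifacts.

The genotype validation simulation draws counts directly (no BAMs):
10,000 heterozygous sites with alt ~ Binomial(depth, 0.45) and 10,000
homozygous-reference sites with alt ~ Binomial(depth, 0.005), depths
uniform in 10–40 — matching the depth-of-coverage ≥ 10 regime of the
validation design it mirrors — and reports per-method sensitivity and FDR.

## Numerical and design choices

* Two-sided convention fixed as minimum-likelihood, with the one-sided
  tail exposed separately; tie tolerance 1e-7 relative.
* The upper-tail test returns exactly 1.0 when the observed cell is at the
  bottom of its support, avoiding a float sum of the whole pmf falling
  marginally below 1.
* htperc honors its interval bounds inclusively; binom's rejection is
  strict (p < α). The zero-coverage HET guard applies to binom only —
  htperc's interior bounds already exclude fractions 0 and 1.
* SNP-to-gene assignment is inclusive at gene boundaries; a SNP in
  overlapping genes counts for each. Strand is ignored (allele counts are
  strand-agnostic).
* Contig naming is never silently reconciled; `chr` prefixes are stripped
  or added only on request.
* Problem sizes in the test-suite fixtures (12–60 genes, 1–3 SNPs per
  gene, depths 30–50) are chosen so the planted effects are essentially
  deterministic at the stringent 1% level while the suite stays fast;
  the operating-characteristic simulations use 10,000 sites per class,
  enough to resolve sub-percent FDR.

## Known limitations

* No phasing or haplotype-level ASE: each SNP is tested marginally, and a
  gene's score treats its SNPs as exchangeable.
* No copy-number awareness: a mono-allelic deletion is indistinguishable
  from transcriptional ASE without external SCNA profiles.
* Only diploid, biallelic SNPs; multi-allelic records and indels are
  skipped on input.
* Genotype likelihoods are not produced; calls are hard with an optional
  p-value.
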