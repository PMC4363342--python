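# aseqkit

Gene-level **allele-specific expression (ASE)** analysis from paired DNA and
RNA sequencing alignments, without parental genomes.

At a heterozygous SNP, a diploid cell carries both a reference and an
alternative base; if transcription draws on both chromosomes evenly, RNA-seq
reads over that SNP should split roughly 50/50 between the two alleles. A
strong departure — most visibly mono-allelic transcription — marks
allele-specific expression, the signature of imprinting, X-inactivation,
regulatory variants, and (in tumors) events such as mono-allelic deletion or
silencing of a suppressor gene.

`aseqkit` implements the full pipeline:

1. **pileup** — filtered base counts (A/C/G/T with strand breakdown) at
   arbitrary SNP positions in an indexed BAM, with a deterministic
   multi-threaded execution contract (static or dynamic work scheduling;
   output is identical for any worker count).
2. **genotype** — heterozygous-SNP calling from DNA counts by either an
   alternative-fraction window (*htperc*, HET iff alt/(ref+alt) ∈ [0.2, 0.8])
   or an exact binomial test (*binom*) against P(alt) = q = 0.45, the skew
   from 0.5 absorbing reference mapping bias; homozygotes are the rejected
   side. Emits the complete call table plus the het-only subset.
3. **ase** — per het SNP, an exact binomial test of the RNA counts against
   p = 0.5; a rejected SNP supports ASE only if a Fisher exact test also
   finds the RNA allelic proportions different from the DNA ones (a guard
   against depth artifacts). Per gene, the **ASE score** is the fraction of
   evaluable SNPs supporting ASE; a gene is ASE when the score exceeds a
   threshold (default 0), *high ASE* when it exceeds 0.5, and flagged as an
   **ASE gene** across a cohort when ASE in ≥ N samples.
4. **power** — the closed-form upper bound on genes reachable by an ASE
   study: given D_i genes carrying i coding SNPs and a per-SNP heterozygosity
   frequency I,

       T_a = Σ_i D_i · (1 − (1 − I)^i),

   the expected number of genes with at least one heterozygous coding SNP.
5. **enrich** — one-sided Fisher/hypergeometric test for enrichment of a
   gene subset (e.g. known imprinted genes) among ASE calls.
6. **simulate** — seeded generator of synthetic paired DNA/RNA BAMs, VCF,
   BED and truth tables with planted genotypes and allele fractions, so the
   entire pipeline is testable offline.

## Worked example

```sh
aseqkit simulate --out-dir fx --n-genes 8 --ase-allele-fraction 1.0 --seed 13
aseqkit genotype --vcf fx/sites.vcf --bam fx/dna.bam \
    --method binom --alpha 0.01 --mdc 10 --out calls.tsv
aseqkit ase --het calls.tsv.het.tsv --rna-bam fx/rna.bam \
    --genes fx/genes.bed --alpha-ase 0.01 --alpha-fisher 0.01 \
    --mdc-rna 10 --out-dir ase_out
```

`calls.tsv.het.tsv` then contains the seven heterozygous SNPs of this
fixture, e.g.

```
chrom  pos   rsid  ref alt ref_count alt_count call pvalue    method
chrS1  700   snp1  G   A   14        14        HET  0.704822  binom
chrS1  2000  snp4  G   C   19        16        HET  1.000000  binom
...
```

and `ase_out/calls.tsv.het.genes.tsv` scores each gene: genes whose het
SNPs are transcribed mono-allelically (the fixture plants RNA allele
fraction 1.0 in its ASE genes) get `ase_score 1.0, status ASE,
high_ase True`, balanced genes get `ase_score 0.0, status NOT_ASE`, and
genes without an evaluable het SNP are `NOT_AVAILABLE`. The
`ase_out/aggregate.tsv` table combines samples: `ase_gene` is true for
genes ASE in at least `--min-samples` samples.

The detection-power bound from a SNPs-per-gene distribution file
(columns: i, D_i):

```sh
$ aseqkit power --dist dist.tsv --het-freq 0.3
T_a     30.0
total_genes     100
fraction        0.300
```

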