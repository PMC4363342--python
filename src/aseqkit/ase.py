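"""Gene-level allele-specific expression (ASE) calling.

Given the heterozygous SNPs of a sample (from DNA) and the RNA-seq
allelic counts at those SNPs, each SNP is tested for loss of
heterozygosity in the transcriptome: an exact binomial test with p = 0.5
on the RNA ref/alt counts. Rejection means transcription is dominated by
one allele. Because unequal DNA and RNA depths alone can push the RNA
test over the line, a per-SNP Fisher exact test compares the DNA and RNA
allelic proportions whenever DNA counts are available; only SNPs where
both tests fire count as supporting ASE.

Per gene, the ASE score is the fraction of evaluable SNPs supporting
ASE; a gene is called ASE when the score strictly exceeds a threshold
(default 0, so a single supporting SNP suffices), and "high ASE" when
the score exceeds 0.5 — the majority of its heterozygous SNPs support
mono-allelic transcription. Genes with no evaluable SNP are flagged
not-available. Across samples, a gene earns the aggregate ASE-gene flag
when it shows ASE in at least ``min_samples`` samples.

SNP-to-gene assignment supports a whole-interval *gene model* and an
exon-interval *transcript model* (intronic SNPs only match the former).
A SNP inside overlapping genes contributes to each of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .pileup import GenomicSite
from .stats import (
    BinomialObservation,
    ContingencyTable2x2,
    binom_two_sided_pvalue,
    fisher_two_sided_pvalue,
)

__all__ = [
    "GeneModel",
    "AseParams",
    "SnpStatus",
    "GeneStatus",
    "SnpAseResult",
    "GeneAseResult",
    "AggregateAseResult",
    "assign_snps_to_genes",
    "rna_het_test",
    "call_snp_ase",
    "score_gene_ase",
    "aggregate_across_samples",
    "run_ase_sample",
    "SNP_ASE_COLUMNS",
    "GENE_ASE_COLUMNS",
    "AGGREGATE_COLUMNS",
]

SNP_ASE_COLUMNS = [
    "gene_id", "chrom", "pos", "rsid",
    "dna_ref", "dna_alt", "rna_ref", "rna_alt",
    "rna_het_pvalue", "fisher_pvalue", "status",
]
GENE_ASE_COLUMNS = [
    "gene_id", "n_snps_evaluable", "n_snps_supporting",
    "ase_score", "status", "high_ase",
]
AGGREGATE_COLUMNS = ["gene_id", "samples_available", "samples_ase", "ase_gene"]


class SnpStatus(str, Enum):
    SUPPORTS_ASE = "SUPPORTS_ASE"
    BIALLELIC = "BIALLELIC"
    NOT_EVALUABLE = "NOT_EVALUABLE"


class GeneStatus(str, Enum):
    ASE = "ASE"
    NOT_ASE = "NOT_ASE"
    NOT_AVAILABLE = "NOT_AVAILABLE"


@dataclass(frozen=True)
class GeneModel:
    """A gene or transcript interval, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    kind: str = "gene"  # "gene" or "transcript"
    exons: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.kind not in ("gene", "transcript"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "transcript":
            if not self.exons:
                raise ValueError(f"{self.gene_id}: transcript model requires exons")
            prev_end = 0
            for s, e in self.exons:
                if s > e or s < self.start or e > self.end:
                    raise ValueError(f"{self.gene_id}: malformed exon [{s},{e}]")
                if s <= prev_end:
                    raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
                prev_end = e

    def contains(self, pos: int) -> bool:
        if not (self.start <= pos <= self.end):
            return False
        if self.kind == "gene":
            return True
        return any(s <= pos <= e for s, e in self.exons)


@dataclass(frozen=True)
class AseParams:
    alpha_ase: float = 0.05
    alpha_fisher: float = 0.05
    min_rna_depth: int = 1
    score_threshold: float = 0.0
    min_samples: int = 1
    high_score_cutoff: float = 0.5
    rna_only: bool = False  # skip the Fisher gate even when DNA counts exist

    def __post_init__(self) -> None:
        for name in ("alpha_ase", "alpha_fisher", "score_threshold", "high_score_cutoff"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass(frozen=True)
class SnpAseResult:
    site: GenomicSite
    rna_ref: int
    rna_alt: int
    dna_ref: Optional[int]
    dna_alt: Optional[int]
    rna_het_pvalue: Optional[float]
    fisher_pvalue: Optional[float]
    status: SnpStatus


@dataclass(frozen=True)
class GeneAseResult:
    gene_id: str
    n_snps_evaluable: int
    n_snps_supporting: int
    ase_score: Optional[float]
    status: GeneStatus
    high_ase: bool


@dataclass(frozen=True)
class AggregateAseResult:
    gene_id: str
    samples_available: int
    samples_ase: int
    ase_gene: bool


def assign_snps_to_genes(
    sites: Sequence[GenomicSite],
    models: Sequence[GeneModel],
) -> dict[str, list[GenomicSite]]:
    """Map every gene/transcript to the input SNPs it contains.

    Gene model: whole [start, end] interval (introns included). Transcript
    model: exon intervals only. Overlapping models each receive the SNP.
    Every model appears in the result, possibly with an empty list, so
    downstream scoring can emit not-available flags.
    """
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        tree.addi(m.start, m.end + 1, m)  # half-open interval tree
    assigned: dict[str, list[GenomicSite]] = {m.gene_id: [] for m in models}
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        hits = sorted(tree[site.pos], key=lambda iv: iv.data.gene_id)
        for iv in hits:
            model: GeneModel = iv.data
            if model.contains(site.pos):
                assigned[model.gene_id].append(site)
    return assigned


def rna_het_test(rna_ref: int, rna_alt: int, params: AseParams = AseParams()
                 ) -> tuple[Optional[float], Optional[bool]]:
    """Exact heterozygosity test on RNA counts with p = q = 0.5.

    Returns (pvalue, is_het); (None, None) below the RNA coverage floor.
    """
    n = rna_ref + rna_alt
    if n < params.min_rna_depth or n == 0:
        return None, None
    pvalue = binom_two_sided_pvalue(BinomialObservation(rna_alt, n, 0.5))
    return pvalue, pvalue >= params.alpha_ase


def call_snp_ase(
    site: GenomicSite,
    rna_counts: tuple[int, int],
    dna_counts: Optional[tuple[int, int]] = None,
    params: AseParams = AseParams(),
) -> SnpAseResult:
    """Classify one heterozygous SNP as supporting ASE or biallelic.

    A SNP supports ASE when the RNA test rejects heterozygosity AND, when
    DNA counts are present and the Fisher gate enabled, the DNA and RNA
    allelic proportions differ significantly. The Fisher gate controls
    false positives from coverage imbalance and can only remove calls.
    """
    rna_ref, rna_alt = rna_counts
    pvalue, is_het = rna_het_test(rna_ref, rna_alt, params)
    if pvalue is None:
        return SnpAseResult(site, rna_ref, rna_alt,
                            dna_counts[0] if dna_counts else None,
                            dna_counts[1] if dna_counts else None,
                            None, None, SnpStatus.NOT_EVALUABLE)
    fisher_p: Optional[float] = None
    supports = not is_het
    if dna_counts is not None and not params.rna_only:
        dna_ref, dna_alt = dna_counts
        fisher_p = fisher_two_sided_pvalue(
            ContingencyTable2x2(dna_ref, dna_alt, rna_ref, rna_alt))
        supports = supports and fisher_p < params.alpha_fisher
    status = SnpStatus.SUPPORTS_ASE if supports else SnpStatus.BIALLELIC
    return SnpAseResult(site, rna_ref, rna_alt,
                        dna_counts[0] if dna_counts else None,
                        dna_counts[1] if dna_counts else None,
                        pvalue, fisher_p, status)


def score_gene_ase(gene_id: str, results: Sequence[SnpAseResult],
                   params: AseParams = AseParams()) -> GeneAseResult:
    """Fraction of evaluable SNPs supporting ASE; strict-threshold call."""
    evaluable = [r for r in results if r.status != SnpStatus.NOT_EVALUABLE]
    supporting = [r for r in evaluable if r.status == SnpStatus.SUPPORTS_ASE]
    if not evaluable:
        return GeneAseResult(gene_id, 0, 0, None, GeneStatus.NOT_AVAILABLE, False)
    score = len(supporting) / len(evaluable)
    status = GeneStatus.ASE if score > params.score_threshold else GeneStatus.NOT_ASE
    return GeneAseResult(gene_id, len(evaluable), len(supporting), score,
                         status, score > params.high_score_cutoff)


def aggregate_across_samples(
    per_sample: Mapping[str, Sequence[GeneAseResult]],
    params: AseParams = AseParams(),
) -> list[AggregateAseResult]:
    """ASE-gene flag: ASE in at least ``min_samples`` of the available samples."""
    gene_ids: list[str] = []
    seen = set()
    for results in per_sample.values():
        for r in results:
            if r.gene_id not in seen:
                seen.add(r.gene_id)
                gene_ids.append(r.gene_id)
    out = []
    for gid in sorted(gene_ids):
        avail = ase = 0
        for results in per_sample.values():
            for r in results:
                if r.gene_id != gid:
                    continue
                if r.status != GeneStatus.NOT_AVAILABLE:
                    avail += 1
                if r.status == GeneStatus.ASE:
                    ase += 1
        out.append(AggregateAseResult(gid, avail, ase, ase >= params.min_samples))
    return out


def run_ase_sample(
    het_calls: pd.DataFrame,
    rna_counts: Mapping[tuple[str, int], tuple[int, int]],
    models: Sequence[GeneModel],
    params: AseParams = AseParams(),
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneAseResult]]:
    """Full per-sample ASE analysis from a het-genotype table.

    ``het_calls`` follows the genotyping output schema (chrom, pos, rsid,
    ref, alt, ref_count, alt_count, ...); its ref/alt counts are the DNA
    evidence for the Fisher gate. ``rna_counts`` maps (chrom, pos) to RNA
    (ref, alt) counts; SNPs missing from it are not evaluable.

    Returns the per-SNP table, the per-gene table, and the per-gene
    results (for aggregation across samples).
    """
    sites = []
    dna_by_pos: dict[tuple[str, int], Optional[tuple[int, int]]] = {}
    has_dna = {"ref_count", "alt_count"} <= set(het_calls.columns)
    for row in het_calls.itertuples(index=False):
        site = GenomicSite(chrom=str(row.chrom), pos=int(row.pos),
                           rsid=None if str(row.rsid) == "NA" else str(row.rsid),
                           ref=None if str(row.ref) == "NA" else str(row.ref),
                           alt=None if str(row.alt) == "NA" else str(row.alt))
        sites.append(site)
        dna_by_pos[(site.chrom, site.pos)] = (
            (int(row.ref_count), int(row.alt_count)) if has_dna else None)

    assigned = assign_snps_to_genes(sites, models)
    snp_rows, gene_rows, gene_results = [], [], []
    for gid in sorted(assigned):
        results = []
        for site in assigned[gid]:
            key = (site.chrom, site.pos)
            rna = rna_counts.get(key, (0, 0))
            res = call_snp_ase(site, rna, dna_by_pos.get(key), params)
            results.append(res)
            snp_rows.append([gid, site.chrom, site.pos, site.rsid or "NA",
                             res.dna_ref, res.dna_alt, res.rna_ref, res.rna_alt,
                             res.rna_het_pvalue, res.fisher_pvalue, res.status.value])
        g = score_gene_ase(gid, results, params)
        gene_results.append(g)
        gene_rows.append([g.gene_id, g.n_snps_evaluable, g.n_snps_supporting,
                          g.ase_score, g.status.value, g.high_ase])
    snp_table = pd.DataFrame(snp_rows, columns=SNP_ASE_COLUMNS)
    gene_table = pd.DataFrame(gene_rows, columns=GENE_ASE_COLUMNS)
    return snp_table, gene_table, gene_results
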