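"""Seeded synthetic datasets with recorded truth.

Generates paired DNA/RNA BAM files (with indexes), a VCF of SNP sites, a
BED of gene intervals and a truth table of planted genotypes and allele
fractions, so the whole pipeline is exercisable without any external
download. The generator emulates the statistical structure the ASE
pipeline assumes — binomial allelic counts at heterozygous sites,
error-driven alternative reads at homozygous sites, mono-allelic
transcription in planted ASE genes — not the physics of sequencing (no
fragmentation model, GC bias or splicing).

Reads are fixed-length single-end records with uniform high base and
mapping qualities by default; per-read quality degradation can be
injected to exercise the pileup filters. Sites are spaced farther apart
than the read length so a read never overlaps two sites. Sequencing
errors are assigned a uniformly random non-truth base, so third-allele
("other") counts occur and exercise their handling. All randomness flows
from a single seed; identical configs yield identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genotype import GenotypeParams, call_genotype
from .pileup import GenomicSite

__all__ = [
    "FixtureConfig",
    "FixtureTruth",
    "simulate_site_counts",
    "build_fixture_dataset",
    "simulate_genotype_benchmark",
]

BASES = ("A", "C", "G", "T")
READ_LENGTH = 50
SITE_SPACING = 200      # > READ_LENGTH: reads at one site never touch the next
GENE_PADDING = 500

DEFAULT_BASE_QUALITY = 30
DEFAULT_MAPPING_QUALITY = 60


@dataclass(frozen=True)
class FixtureConfig:
    n_genes: int = 10
    snps_per_gene: tuple[int, ...] = (1, 2, 3)  # sampled uniformly
    het_fraction: float = 0.6
    dna_depth: int = 30        # Poisson mean per site
    rna_depth: int = 30
    ase_gene_fraction: float = 0.3
    ase_allele_fraction: float = 0.95
    base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_fraction", "ase_gene_fraction",
                     "ase_allele_fraction", "base_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.dna_depth < 1 or self.rna_depth < 1:
            raise ValueError("depth means must be >= 1")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")


@dataclass
class FixtureTruth:
    """Planted truth emitted alongside the synthetic files."""

    sites: pd.DataFrame       # chrom,pos,rsid,ref,alt,gene_id,genotype,rna_alt_fraction
    genes: pd.DataFrame       # gene_id,chrom,start,end,is_ase
    dna_counts: dict          # (chrom,pos) -> (ref, alt, other) written to the DNA BAM
    rna_counts: dict          # same for the RNA BAM
    dna_bam: Optional[Path] = None
    rna_bam: Optional[Path] = None
    vcf: Optional[Path] = None
    bed: Optional[Path] = None


def simulate_site_counts(genotype: str, depth: int, allele_fraction: float,
                         error_rate: float, rng) -> tuple[int, int, int]:
    """Draw (ref, alt, other) counts for one site at fixed total depth.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.

    HET: alt reads ~ Binomial(depth, allele_fraction); each remaining read
    independently becomes an error ("other" base) with ``error_rate``.
    HOM_REF / HOM_ALT: every read carries the true allele unless hit by an
    error, in which case it moves to one of the three non-truth bases
    (uniformly), i.e. alt counts at HOM_REF sites arise at error_rate / 3
    per read per specific base — callers see the aggregated non-ref mass.
    """
    if genotype not in ("HOM_REF", "HET", "HOM_ALT"):
        raise ValueError(f"unknown genotype {genotype!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if genotype == "HET":
        alt = int(rng.binomial(depth, allele_fraction))
        ref = depth - alt
        # errors strike ref and alt reads alike and land on a third base
        ref_err = int(rng.binomial(ref, error_rate)) if ref else 0
        alt_err = int(rng.binomial(alt, error_rate)) if alt else 0
        return ref - ref_err, alt - alt_err, ref_err + alt_err
    n_err = int(rng.binomial(depth, error_rate)) if depth else 0
    # an error lands on alt with probability 1/3, else a third base
    to_alt = int(rng.binomial(n_err, 1.0 / 3.0)) if n_err else 0
    truth = depth - n_err
    if genotype == "HOM_REF":
        return truth, to_alt, n_err - to_alt
    return to_alt, truth, n_err - to_alt


def _layout(config: FixtureConfig, rng: np.random.Generator):
    """Place genes and SNPs on one synthetic contig; assign truth."""
    chrom = "chrS1"
    genes, sites = [], []
    cursor = GENE_PADDING
    snp_idx = 0
    for g in range(config.n_genes):
        n_snps = int(rng.choice(config.snps_per_gene))
        start = cursor
        positions = [start + SITE_SPACING * (j + 1) for j in range(n_snps)]
        end = positions[-1] + SITE_SPACING if positions else start + SITE_SPACING
        gene_id = f"GENE{g + 1:04d}"
        is_ase = bool(rng.random() < config.ase_gene_fraction)
        genes.append(dict(gene_id=gene_id, chrom=chrom, start=start, end=end,
                          is_ase=is_ase))
        for pos in positions:
            snp_idx += 1
            ref, alt = rng.choice(len(BASES), size=2, replace=False)
            u = rng.random()
            if u < config.het_fraction:
                genotype = "HET"
            elif u < config.het_fraction + (1 - config.het_fraction) / 2:
                genotype = "HOM_REF"
            else:
                genotype = "HOM_ALT"
            if genotype == "HET":
                rna_frac = config.ase_allele_fraction if is_ase else 0.5
            else:
                rna_frac = float("nan")
            sites.append(dict(chrom=chrom, pos=pos, rsid=f"snp{snp_idx}",
                              ref=BASES[ref], alt=BASES[alt], gene_id=gene_id,
                              genotype=genotype, rna_alt_fraction=rna_frac))
        cursor = end + GENE_PADDING
    return chrom, genes, sites, cursor + GENE_PADDING


def _emit_reads(bam_path: Path, chrom: str, contig_len: int, sites, counts,
                rng: np.random.Generator) -> None:
    """Write a coordinate-sorted, indexed BAM realizing per-site base counts."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": contig_len}]}
    reads = []
    for s in sites:
        pos0 = s["pos"] - 1  # 0-based
        ref_n, alt_n, other_n = counts[(s["chrom"], s["pos"])]
        alleles = [s["ref"]] * ref_n + [s["alt"]] * alt_n
        others = [b for b in BASES if b not in (s["ref"], s["alt"])]
        alleles += [others[int(rng.integers(len(others)))] for _ in range(other_n)]
        for k, base in enumerate(alleles):
            offset = int(rng.integers(READ_LENGTH))
            start = max(0, pos0 - offset)
            seq = list("A" * READ_LENGTH)
            seq[pos0 - start] = base
            reads.append((start, f"{s['rsid']}_r{k}", "".join(seq),
                          bool(rng.integers(2))))
    reads.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for start, name, seq, reverse in reads:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = DEFAULT_MAPPING_QUALITY
            a.cigarstring = f"{READ_LENGTH}M"
            a.flag = 16 if reverse else 0
            a.query_qualities = pysam.qualitystring_to_array(
                chr(DEFAULT_BASE_QUALITY + 33) * READ_LENGTH)
            bam.write(a)
    pysam.index(str(bam_path))


def _write_vcf(path: Path, chrom: str, contig_len: int, sites) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={contig_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            fh.write(f"{s['chrom']}\t{s['pos']}\t{s['rsid']}\t{s['ref']}\t"
                     f"{s['alt']}\t.\t.\t.\n")


def _write_bed(path: Path, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:  # BED is 0-based half-open
            fh.write(f"{g['chrom']}\t{g['start'] - 1}\t{g['end']}\t{g['gene_id']}\n")


def build_fixture_dataset(config: FixtureConfig, out_dir) -> FixtureTruth:
    """Materialize DNA/RNA BAMs (+ .bai), VCF, BED and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    chrom, genes, sites, contig_len = _layout(config, rng)

    dna_counts, rna_counts = {}, {}
    for s in sites:
        key = (s["chrom"], s["pos"])
        d_depth = max(1, int(rng.poisson(config.dna_depth)))
        dna_counts[key] = simulate_site_counts(
            s["genotype"], d_depth, 0.5, config.base_error_rate, rng)
        r_depth = max(1, int(rng.poisson(config.rna_depth)))
        frac = s["rna_alt_fraction"] if s["genotype"] == "HET" else 0.5
        rna_counts[key] = simulate_site_counts(
            s["genotype"], r_depth, frac, config.base_error_rate, rng)

    truth = FixtureTruth(
        sites=pd.DataFrame(sites),
        genes=pd.DataFrame(genes),
        dna_counts=dna_counts,
        rna_counts=rna_counts,
        dna_bam=out / "dna.bam",
        rna_bam=out / "rna.bam",
        vcf=out / "sites.vcf",
        bed=out / "genes.bed",
    )
    _emit_reads(truth.dna_bam, chrom, contig_len, sites, dna_counts, rng)
    _emit_reads(truth.rna_bam, chrom, contig_len, sites, rna_counts, rng)
    _write_vcf(truth.vcf, chrom, contig_len, sites)
    _write_bed(truth.bed, genes)
    truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1)
    return truth


def simulate_genotype_benchmark(
    n_het: int,
    n_hom: int,
    depth_low: int,
    depth_high: int,
    error_rate: float,
    params_by_method: dict[str, GenotypeParams],
    seed: int,
    het_alt_fraction: float = 0.45,
) -> dict[str, dict[str, float]]:
    """Sensitivity and FDR of heterozygote recovery on count-level draws.

    Heterozygous sites draw alt ~ Binomial(depth, ``het_alt_fraction``)
    (0.45 reflects reference mapping bias); homozygous-reference sites
    draw alt ~ Binomial(depth, error_rate). Depths are uniform integers
    in [depth_low, depth_high]. Returns, per method,
    ``{"sensitivity": ..., "fdr": ..., "n_het_called": ...}`` with
    sensitivity = het sites called HET / n_het and
    FDR = hom sites called HET / all sites called HET (0 when no calls).
    """
    rng = np.random.default_rng(seed)
    het_depth = rng.integers(depth_low, depth_high + 1, size=n_het)
    het_alt = rng.binomial(het_depth, het_alt_fraction)
    hom_depth = rng.integers(depth_low, depth_high + 1, size=n_hom)
    hom_alt = rng.binomial(hom_depth, error_rate)

    out = {}
    for method, params in params_by_method.items():
        cache: dict[tuple[int, int], str] = {}

        def call(ref: int, alt: int) -> str:
            key = (ref, alt)
            if key not in cache:
                cache[key] = call_genotype(ref, alt, params).call.value
            return cache[key]

        tp = sum(call(int(d - a), int(a)) == "HET"
                 for d, a in zip(het_depth, het_alt))
        fp = sum(call(int(d - a), int(a)) == "HET"
                 for d, a in zip(hom_depth, hom_alt))
        called = tp + fp
        out[method] = {
            "sensitivity": tp / n_het if n_het else 0.0,
            "fdr": fp / called if called else 0.0,
            "n_het_called": float(called),
        }
    return out
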