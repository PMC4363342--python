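"""Readers and writers for the standard formats at the package boundary.

Coordinate conventions are pinned here: VCF and everything in-memory are
1-based; BED is 0-based half-open and converted on read. Contig-name
mismatches ("chr1" vs "1") are never silently reconciled — use
``chr_prefix`` to strip or add the prefix explicitly. Missing values in
output tables are rendered as "NA".
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam

from .ase import GeneModel
from .pileup import GenomicSite, PileupRecord, PILEUP_COLUMNS

__all__ = [
    "read_snp_list",
    "read_gene_models",
    "read_pileup_table",
    "write_pileup_table",
    "write_table",
    "apply_chr_prefix",
]

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


def apply_chr_prefix(chrom: str, mode: Optional[str]) -> str:
    """mode: None (leave), "strip" (chr1 -> 1) or "add" (1 -> chr1)."""
    if mode == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    if mode == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


def read_snp_list(path, chr_prefix: Optional[str] = None) -> list[GenomicSite]:
    """Load biallelic SNPs from a VCF; indels and multi-allelic records are
    skipped with a warning. The ID column is preserved as the rsid."""
    sites = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1
                    or rec.ref.upper() not in _VALID_BASES
                    or alts[0].upper() not in _VALID_BASES):
                skipped += 1
                logger.warning("skipping non-SNP record %s:%d (%s>%s)",
                               rec.chrom, rec.pos, rec.ref, ",".join(alts) or ".")
                continue
            rsid = None if rec.id in (None, ".") else rec.id
            sites.append(GenomicSite(
                chrom=apply_chr_prefix(rec.chrom, chr_prefix),
                pos=rec.pos, rsid=rsid,
                ref=rec.ref.upper(), alt=alts[0].upper()))
    if skipped:
        logger.warning("skipped %d non-biallelic-SNP records in %s", skipped, path)
    return sites


def read_gene_models(path, kind: str = "gene",
                     chr_prefix: Optional[str] = None) -> list[GeneModel]:
    """Load gene models.

    kind="gene": BED (>= 4 columns, name = gene_id), 0-based half-open,
    converted to 1-based inclusive. kind="transcript": a tab/whitespace
    table with one exon per row (gene_id, chrom, exon_start, exon_end;
    1-based inclusive), grouped into one model per gene_id.
    """
    if kind == "gene":
        models = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
                chrom, start0, end0, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                if end0 <= start0:
                    raise ValueError(f"{path}:{lineno}: empty interval {start0}-{end0}")
                models.append(GeneModel(
                    gene_id=name, chrom=apply_chr_prefix(chrom, chr_prefix),
                    start=start0 + 1, end=end0, kind="gene"))
        return models
    if kind != "transcript":
        raise ValueError(f"unknown model kind {kind!r}")
    exons: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: exon table needs 4 columns")
            gid, chrom, s, e = fields[0], fields[1], int(fields[2]), int(fields[3])
            if e < s:
                raise ValueError(f"{path}:{lineno}: end {e} < start {s}")
            exons.setdefault(gid, []).append(
                (apply_chr_prefix(chrom, chr_prefix), s, e))
    models = []
    for gid, rows in exons.items():
        chroms = {c for c, _, _ in rows}
        if len(chroms) != 1:
            raise ValueError(f"transcript {gid} spans multiple contigs")
        ivals = tuple(sorted((s, e) for _, s, e in rows))
        models.append(GeneModel(
            gene_id=gid, chrom=rows[0][0],
            start=ivals[0][0], end=ivals[-1][1],
            kind="transcript", exons=ivals))
    return models


def write_pileup_table(records: Sequence[PileupRecord], path) -> None:
    df = pd.DataFrame([r.to_row() for r in records], columns=PILEUP_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pileup_table(path) -> list[PileupRecord]:
    """Re-hydrate pileup records from the TSV written by write_pileup_table."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        site = GenomicSite(chrom=row.chrom, pos=int(row.pos),
                           rsid=None if str(row.rsid) == "NA" else str(row.rsid))
        counts = {b: int(getattr(row, b)) for b in "ACGT"}
        strand = {b: (int(getattr(row, f"{b}_fwd")), int(getattr(row, f"{b}_rev")))
                  for b in "ACGT"}
        records.append(PileupRecord(site=site, counts=counts, strand_counts=strand))
    return records


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV with a single header line, NA for missing."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
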