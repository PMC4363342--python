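"""Genotype calling at known SNP positions from allelic read counts.

Two callers are provided, mirroring the two strategies of the GENOTYPE
mode. Neither discovers variants: a site absent from the input SNP list is
never genotyped.

``htperc``
    Calls heterozygous when the alternative-allele fraction
    alt/(ref+alt) lies in a closed interval, [0.2, 0.8] by default.

``binom``
    Exact two-sided binomial test of the alternative count against the
    expected alternative fraction q. The default p=0.55 / q=0.45 skews
    away from 0.5 to absorb reference mapping bias (reads carrying the
    alternative allele map slightly less well, inflating reference
    counts). Retaining the null (p-value >= alpha) calls heterozygous;
    rejecting it calls the homozygote on the side of the observed
    fraction. By default no heterozygote is called when either allele has
    zero coverage; the guard can be lifted for low-coverage data.

The test is run on n = ref+alt, not on total depth: reads carrying a
third allele say nothing about the ref/alt balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .pileup import GenomicSite, PileupRecord
from .stats import BinomialObservation, binom_two_sided_pvalue

__all__ = [
    "Genotype",
    "GenotypeParams",
    "GenotypeCall",
    "call_genotype_htperc",
    "call_genotype_binom",
    "call_genotype",
    "genotype_sample",
    "GENOTYPE_COLUMNS",
]

logger = logging.getLogger(__name__)

GENOTYPE_COLUMNS = [
    "chrom", "pos", "rsid", "ref", "alt",
    "ref_count", "alt_count", "call", "pvalue", "method",
]


class Genotype(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    NO_CALL = "NO_CALL"


@dataclass(frozen=True)
class GenotypeParams:
    method: str = "binom"
    het_low: float = 0.2
    het_high: float = 0.8
    p_ref: float = 0.55
    alpha: float = 0.05
    min_depth: int = 1
    require_both_alleles: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("htperc", "binom"):
            raise ValueError(f"unknown genotype method {self.method!r}")
        if not (0 <= self.het_low < self.het_high <= 1):
            raise ValueError("need 0 <= het_low < het_high <= 1")
        if not (0 < self.p_ref < 1):
            raise ValueError("p_ref must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def q_alt(self) -> float:
        return 1.0 - self.p_ref


@dataclass(frozen=True)
class GenotypeCall:
    site: Optional[GenomicSite]
    ref_count: int
    alt_count: int
    call: Genotype
    pvalue: Optional[float]
    method: str


def call_genotype_htperc(ref_count: int, alt_count: int,
                         params: GenotypeParams = GenotypeParams(method="htperc")
                         ) -> GenotypeCall:
    """Heterozygous iff the alt fraction falls in the closed het interval."""
    n = ref_count + alt_count
    if n < params.min_depth:
        call = Genotype.NO_CALL
    else:
        frac = alt_count / n
        if params.het_low <= frac <= params.het_high:
            call = Genotype.HET
        elif frac > params.het_high:
            call = Genotype.HOM_ALT
        else:
            call = Genotype.HOM_REF
    return GenotypeCall(None, ref_count, alt_count, call, None, "htperc")


def call_genotype_binom(ref_count: int, alt_count: int,
                        params: GenotypeParams = GenotypeParams(method="binom")
                        ) -> GenotypeCall:
    """Binomial heterozygosity test with reference-bias-adjusted q."""
    n = ref_count + alt_count
    pvalue: Optional[float] = None
    if n < params.min_depth:
        call = Genotype.NO_CALL
    elif params.require_both_alleles and alt_count == 0:
        call = Genotype.HOM_REF
    elif params.require_both_alleles and ref_count == 0:
        call = Genotype.HOM_ALT
    else:
        pvalue = binom_two_sided_pvalue(
            BinomialObservation(alt_count, n, params.q_alt))
        if pvalue >= params.alpha:  # p = alpha retains heterozygosity
            call = Genotype.HET
        elif alt_count / n < params.q_alt:
            call = Genotype.HOM_REF
        else:
            call = Genotype.HOM_ALT
    return GenotypeCall(None, ref_count, alt_count, call, pvalue, "binom")


def call_genotype(ref_count: int, alt_count: int, params: GenotypeParams) -> GenotypeCall:
    if params.method == "htperc":
        return call_genotype_htperc(ref_count, alt_count, params)
    return call_genotype_binom(ref_count, alt_count, params)


def genotype_sample(
    sites: Sequence[GenomicSite],
    pileup_records: Sequence[PileupRecord],
    params: GenotypeParams = GenotypeParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call every site; return (all calls, heterozygous subset) tables.

    ``pileup_records`` are matched to ``sites`` by (chrom, pos); ref/alt
    counts are the pileup counts of the site's ref and alt bases only. A
    site with no pileup record becomes NO_CALL with zero counts.
    """
    by_pos = {(r.site.chrom, r.site.pos): r for r in pileup_records}
    rows = []
    for site in sites:
        rec = by_pos.get((site.chrom, site.pos))
        if rec is None:
            logger.warning("site %s:%d absent from pileup; NO_CALL",
                           site.chrom, site.pos)
            gc = GenotypeCall(site, 0, 0, Genotype.NO_CALL, None, params.method)
        else:
            gc = replace(call_genotype(rec.count(site.ref), rec.count(site.alt),
                                       params), site=site)
        rows.append([site.chrom, site.pos, site.rsid or "NA",
                     site.ref or "NA", site.alt or "NA",
                     gc.ref_count, gc.alt_count, gc.call.value,
                     gc.pvalue, gc.method])
    all_calls = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    het_subset = all_calls[all_calls["call"] == Genotype.HET.value].reset_index(drop=True)
    return all_calls, het_subset
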