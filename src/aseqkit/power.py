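"""Detection power of SNP-based ASE studies.

A gene can only be assayed for allele-specific expression if it carries
at least one heterozygous coding SNP in the individual under study. Given
the distribution D of coding SNPs per gene (D_i = number of genes with
exactly i coding SNPs) and a per-SNP heterozygosity frequency I, and
assuming heterozygous SNPs fall uniformly and independently, the expected
upper bound on the number of ASE-suitable genes is

    T_a = sum_i D_i * (1 - (1 - I)^i)

since (1 - I)^i is the chance a gene with i SNPs has no heterozygous one.

The module also provides the imprinted-gene enrichment test: imprinted
genes are mono-allelically expressed by parental origin, so among genes
available for ASE calculation they should be called ASE far more often
than baseline; a one-sided hypergeometric (Fisher) test quantifies this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .stats import ContingencyTable2x2, fisher_upper_tail_pvalue

__all__ = [
    "SnpPerGeneDistribution",
    "estimate_ase_suitable_genes",
    "power_curve",
    "imprinted_enrichment_test",
]


@dataclass(frozen=True)
class SnpPerGeneDistribution:
    """counts[i] = number of genes carrying exactly i coding SNPs (i >= 1)."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("distribution must be non-empty")
        for i, d in self.counts.items():
            if i < 1 or d < 0:
                raise ValueError(f"invalid distribution entry {i} -> {d}")

    @property
    def total_genes(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_file(cls, path) -> "SnpPerGeneDistribution":
        """Read a two-column whitespace/tab table: i, D_i. '#' starts a comment."""
        counts: dict[int, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                fields = line.split()
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns")
                i, d = int(fields[0]), int(fields[1])
                counts[i] = counts.get(i, 0) + d
        return cls(counts)


def estimate_ase_suitable_genes(dist: SnpPerGeneDistribution, het_freq: float) -> float:
    """Closed-form upper bound T_a on genes with >= 1 heterozygous coding SNP."""
    if not (0.0 <= het_freq <= 1.0):
        raise ValueError(f"heterozygosity frequency {het_freq} outside [0, 1]")
    i = np.array(list(dist.counts.keys()), dtype=float)
    d = np.array(list(dist.counts.values()), dtype=float)
    return float(np.sum(d * (1.0 - (1.0 - het_freq) ** i)))


def power_curve(dist: SnpPerGeneDistribution,
                het_freqs: Sequence[float]) -> list[tuple[float, float]]:
    """T_a evaluated over a grid of heterozygosity frequencies."""
    return [(float(I), estimate_ase_suitable_genes(dist, I)) for I in het_freqs]


def imprinted_enrichment_test(subset_ase: int, subset_total: int,
                              overall_ase: int, overall_total: int
                              ) -> Optional[float]:
    """One-sided enrichment of ASE calls in a gene subset (e.g. imprinted).

    Builds the 2x2 table [[k, K-k], [n-k, (N-K)-(n-k)]] with the subset
    excluded from the comparison group and returns the upper-tail Fisher
    p-value. Returns None (no test) when the subset has zero ASE calls.
    """
    k, K, n, N = subset_ase, subset_total, overall_ase, overall_total
    if not (0 <= k <= K <= N and k <= n <= N and n - k <= N - K):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return None
    table = ContingencyTable2x2(k, K - k, n - k, (N - K) - (n - k))
    return fisher_upper_tail_pvalue(table)
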