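"""Exact small-sample tests used throughout the package.

Every statistical decision in the pipeline reduces to one of three exact
tests: a two-sided binomial test (genotype heterozygosity, RNA allelic
balance), a two-sided Fisher exact test (DNA-vs-RNA allelic proportions),
and a one-sided upper-tail Fisher/hypergeometric test (enrichment of a
gene subset among ASE calls).

Two-sided p-values follow the minimum-likelihood ("minlike") convention:
the p-value is the total probability of all outcomes whose point
probability does not exceed that of the observed outcome. Point-probability
comparisons use a relative tolerance of 1e-7 so that exactly symmetric
outcomes are never excluded by floating-point rounding. Hypergeometric
point probabilities are evaluated with log-space factorials (gammaln) and
remain stable for table totals up to ~1e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import binomtest

__all__ = [
    "BinomialObservation",
    "ContingencyTable2x2",
    "binom_two_sided_pvalue",
    "fisher_two_sided_pvalue",
    "fisher_upper_tail_pvalue",
]

#: relative tolerance for point-probability ties in minlike two-sided sums
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class BinomialObservation:
    """An observed success count out of a fixed number of Bernoulli trials."""

    successes: int
    trials: int
    success_prob: float

    def __post_init__(self) -> None:
        if self.trials <= 0:
            raise ValueError("binomial test undefined for zero trials")
        if not (0 <= self.successes <= self.trials):
            raise ValueError(
                f"successes={self.successes} outside [0, trials={self.trials}]"
            )
        if not (0.0 < self.success_prob < 1.0):
            raise ValueError(f"success_prob={self.success_prob} outside (0, 1)")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; row 1 is the group of interest, column 1 the event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero (no test possible)."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


def binom_two_sided_pvalue(obs: BinomialObservation) -> float:
    """Two-sided (minlike) exact binomial p-value.

    Sums P(j) over all outcomes j in 0..trials with
    P(j) <= P(successes) under Binomial(trials, success_prob).
    """
    # scipy's binomtest implements precisely the minlike convention with a
    # relative tie tolerance; it is the canonical implementation of this sum.
    result = binomtest(obs.successes, obs.trials, obs.success_prob)
    return float(min(1.0, result.pvalue))


def _hypergeom_logpmf_support(table: ContingencyTable2x2):
    """Log point probabilities over the hypergeometric support of a table.

    Conditions on the margins of ``table``: row-1 total K = a+b, column-1
    total n = a+c, grand total N. Returns (support values of the (1,1) cell,
    log pmf array).
    """
    K = table.a + table.b
    n = table.a + table.c
    N = table.total
    lo = max(0, n - (N - K))
    hi = min(K, n)
    x = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(K + 1)
        - gammaln(x + 1)
        - gammaln(K - x + 1)
        + gammaln(N - K + 1)
        - gammaln(n - x + 1)
        - gammaln(N - K - n + x + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return x, logpmf


def fisher_two_sided_pvalue(table: ContingencyTable2x2) -> float:
    """Two-sided (minlike) Fisher exact p-value for a 2x2 table.

    Conditional on the margins, sums hypergeometric point probabilities not
    exceeding the observed table's probability. A degenerate table (an empty
    row or column margin) carries no evidence and returns 1.0.
    """
    if table.degenerate:
        return 1.0
    x, logpmf = _hypergeom_logpmf_support(table)
    log_obs = logpmf[np.searchsorted(x, table.a)]
    include = logpmf <= log_obs + np.log1p(TIE_RTOL)
    return float(min(1.0, np.exp(logpmf[include]).sum()))


def fisher_upper_tail_pvalue(table: ContingencyTable2x2) -> float:
    """One-sided enrichment p-value P(X >= a) for the (1,1) cell.

    X is hypergeometric with the table's margins; small values indicate the
    row-1 group is enriched for the column-1 event.
    """
    if table.degenerate:
        return 1.0
    x, logpmf = _hypergeom_logpmf_support(table)
    if table.a <= x[0]:  # whole support: exactly 1 despite float summation
        return 1.0
    return float(min(1.0, np.exp(logpmf[x >= table.a]).sum()))
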