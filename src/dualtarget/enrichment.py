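"""Hypergeometric enrichment of target lists against curated gene pools.

Given a druggable background universe of N genes, a curated pool of K genes
inside it, a list of n identified targets, and an observed overlap of r
genes, the module reports

* the expected overlap under random draws, ``E = n*K/N``,
* the fold enrichment ``r / E``, and
* the upper-tail probability of drawing at least r pool genes,

      p = 1 - sum_{i=0}^{r-1} C(K,i) * C(N-K, n-i) / C(N,n)
        = P(X >= r),  X ~ Hypergeometric(N, K, n).

The tail convention is P(X >= r) — one minus the sum up to r-1 — not the
P(X > r) convention; an off-by-one here is the classic enrichment bug.
r = 0 therefore yields p = 1 exactly (empty sum).  Binomial coefficients are
evaluated through log-gamma and the tail is summed in log space, since a
background of several thousand genes overflows naive factorials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

from .types import GenePool, ValidationError, normalize_gene


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts (N, K, n, r) of one enrichment problem.

    N: background universe size; K: pool genes within the background;
    n: identified targets; r: observed overlap.
    """

    N: int
    K: int
    n: int
    r: int

    def __post_init__(self):
        if self.N < 1:
            raise ValidationError(f"background N must be positive, got {self.N}")
        if not (0 <= self.K <= self.N):
            raise ValidationError(f"need 0 <= K <= N, got K={self.K}, N={self.N}")
        if not (0 <= self.n <= self.N):
            raise ValidationError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")
        if not (0 <= self.r <= min(self.n, self.K)):
            raise ValidationError(
                f"need 0 <= r <= min(n, K), got r={self.r}, n={self.n}, K={self.K}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Expected overlap, fold enrichment and upper-tail p for one input."""

    input: EnrichmentInput
    expected: float
    fold: float
    p_value: float
    overlap_genes: tuple[str, ...] = field(default=())


def _log_comb(a: int, b) -> np.ndarray:
    """log C(a, b), elementwise over b (b assumed within [0, a])."""
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def log_hypergeom_pmf(input_: EnrichmentInput, i) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeometric(N, K, n), elementwise over i."""
    N, K, n = input_.N, input_.K, input_.n
    i = np.asarray(i, dtype=float)
    return _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)


def hypergeom_upper_tail(input_: EnrichmentInput) -> float:
    """P(X >= r), summed in log space and clamped to [0, 1]."""
    r = input_.r
    if r == 0:
        return 1.0
    hi = min(input_.n, input_.K)
    if r > hi:  # unreachable given input validation, kept as a guard
        return 0.0
    support = np.arange(r, hi + 1)
    log_p = logsumexp(log_hypergeom_pmf(input_, support))
    return float(min(1.0, max(0.0, np.exp(log_p))))


def hypergeom_enrichment(input_: EnrichmentInput) -> EnrichmentResult:
    """Expected overlap, fold enrichment and P(X >= r) for one count input."""
    expected = input_.n * input_.K / input_.N
    if input_.r == 0:
        fold = 0.0
    elif expected == 0:
        raise ValidationError(
            f"r={input_.r} observed but expected overlap is 0 (n={input_.n}, K={input_.K})"
        )
    else:
        fold = input_.r / expected
    return EnrichmentResult(
        input=input_,
        expected=expected,
        fold=fold,
        p_value=hypergeom_upper_tail(input_),
    )


def overlap_and_test(targets: Iterable[str], pool: GenePool) -> EnrichmentResult:
    """Intersect a target list with a pool and run the enrichment test.

    Targets are case-normalized and deduplicated; N is taken from the pool's
    ``background_size``.  The result carries the overlapping symbols.
    """
    target_set = {normalize_gene(g) for g in targets}
    if not target_set:
        raise ValidationError("overlap_and_test: empty target list")
    if not pool.genes:
        raise ValidationError(f"overlap_and_test: pool {pool.name!r} is empty")
    if pool.background_size < max(len(target_set), len(pool.genes)):
        raise ValidationError(
            f"pool {pool.name!r}: background_size {pool.background_size} smaller "
            f"than inputs (|targets|={len(target_set)}, |pool|={len(pool.genes)})"
        )
    overlap = sorted(target_set & pool.genes)
    inp = EnrichmentInput(
        N=pool.background_size, K=len(pool.genes), n=len(target_set), r=len(overlap)
    )
    base = hypergeom_enrichment(inp)
    return EnrichmentResult(
        input=inp,
        expected=base.expected,
        fold=base.fold,
        p_value=base.p_value,
        overlap_genes=tuple(overlap),
    )
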