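"""Intersection of DE and bound gene sets, overlap statistics, and gene-set
enrichment of the resulting direct targets.

A direct target is a gene that both responds to the knockdown and carries a
binding site within the assignment window.  Whether that intersection is
larger than chance is an exact hypergeometric question: draw |DE| genes
from the universe of tested genes, of which |bound| are marked, and ask for
the upper-tail probability of the observed overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust
from .models import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "TargetReport",
    "EnrichmentRow",
    "hypergeometric_overlap",
    "build_target_report",
    "gene_set_overlap",
    "term_enrichment",
]


@dataclass
class TargetReport:
    universe: frozenset[str]
    de_set: frozenset[str]
    bound_set: frozenset[str]
    direct_targets: frozenset[str] = field(init=False)
    overlap_p: float = field(init=False)

    def __post_init__(self) -> None:
        self.direct_targets = frozenset(self.de_set & self.bound_set)
        self.overlap_p = hypergeometric_overlap(
            k=len(self.direct_targets),
            K=len(self.de_set),
            n=len(self.bound_set),
            N=len(self.universe),
        )


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    k: int  # targets carrying the term
    K: int  # universe genes carrying the term
    n: int  # targets
    N: int  # universe
    p_value: float
    bh_fdr: float
    significant: bool


def _log_choose(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeometric_overlap(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N genes in the universe, K carrying the property, n drawn; summed in
    log space so tiny tails at genome scale do not underflow to garbage.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k <= max(0, n + K - N):
        return 1.0  # at or below the support minimum: the tail is everything
    i = np.arange(k, min(K, n) + 1, dtype=float)
    log_terms = _log_choose(K, i) + _log_choose(N - K, n - i) - _log_choose(N, np.array([float(n)]))
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def build_target_report(
    de_set: Iterable[str], bound_set: Iterable[str], universe: Iterable[str]
) -> TargetReport:
    """Direct targets = DE intersect bound, with the overlap's hypergeometric
    upper-tail p over the tested universe.  Bound genes outside the universe
    (no ortholog, untested) are dropped with a logged count."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    de_set = frozenset(de_set)
    if not de_set <= universe:
        raise ValueError(f"{len(de_set - universe)} DE gene(s) outside the universe")
    bound = frozenset(bound_set)
    dropped = len(bound - universe)
    if dropped:
        logger.info("build_target_report: dropped %d bound gene(s) outside the universe", dropped)
    return TargetReport(universe=universe, de_set=de_set, bound_set=frozenset(bound & universe))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def gene_set_overlap(
    targets: Iterable[str], reference_set: Iterable[str], universe: Iterable[str]
) -> tuple[int, int | None, float]:
    """Overlap of the targets with a reference list (count, integer percent
    of targets, hypergeometric upper-tail p).  Percent is None when there
    are no targets."""
    universe = frozenset(universe)
    targets = frozenset(targets) & universe
    reference = frozenset(reference_set) & universe
    count = len(targets & reference)
    if not targets:
        return count, None, 1.0
    percent = _round_half_away(100.0 * count / len(targets))
    p = hypergeometric_overlap(k=count, K=len(reference), n=len(targets), N=len(universe))
    return count, percent, p


def term_enrichment(
    targets: Iterable[str],
    terms: GeneSetCollection,
    universe: Iterable[str],
    bh_threshold: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of every term with >= 1 target hit, BH
    corrected across the tested terms, sorted by adjusted FDR."""
    universe = frozenset(universe)
    targets = frozenset(targets) & universe
    tested: list[tuple[str, int, int]] = []
    for name, members in sorted(terms.items()):
        members = frozenset(members) & universe
        k = len(members & targets)
        if k >= 1:
            tested.append((name, k, len(members)))
    if not tested:
        return []
    n, N = len(targets), len(universe)
    pvals = [hypergeometric_overlap(k=k, K=K, n=n, N=N) for _, k, K in tested]
    fdrs = bh_adjust(pvals)
    rows = [
        EnrichmentRow(
            term_id=name, k=k, K=K, n=n, N=N,
            p_value=p, bh_fdr=float(q), significant=bool(q < bh_threshold),
        )
        for (name, k, K), p, q in zip(tested, pvals, fdrs)
    ]
    rows.sort(key=lambda r: (r.bh_fdr, r.p_value, r.term_id))
    return rows
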