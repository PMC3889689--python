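"""Peak selection and peak-to-gene assignment.

A peak survives if it is significant by FDR or strongly enriched; surviving
peaks are linked to every gene whose longest-transcript interval lies
within a fixed base-pair window of the peak interval.  Assignment is
many-to-many: a promoter-proximal peak between two divergent genes counts
for both, and a gene with several peaks is bound once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from intervaltree import IntervalTree

from .models import GeneModel, Peak

__all__ = ["PeakGeneAssignment", "select_peaks", "assign_peaks_to_genes", "bound_gene_set"]


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak_id: str
    gene_id: str
    distance: int  # interval gap in bases; 0 when peak and gene overlap

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def select_peaks(peaks: Iterable[Peak], fdr_max: float = 0.05, fold_min: float = 20.0) -> list[Peak]:
    """Peaks with fdr < fdr_max (strict) OR fold_enrichment > fold_min
    (strict); input order preserved.  A peak sitting exactly on both
    boundaries is dropped."""
    if fdr_max < 0 or fold_min < 0:
        raise ValueError("thresholds must be >= 0")
    return [p for p in peaks if p.fdr < fdr_max or p.fold_enrichment > fold_min]


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def assign_peaks_to_genes(
    peaks: Iterable[Peak], genes: Iterable[GeneModel], window: int = 10_000
) -> list[PeakGeneAssignment]:
    """All (peak, gene) pairs on one scaffold whose interval gap is <= window.

    The gap is between the peak interval and the gene's longest-transcript
    interval, 0 when they overlap; strand is ignored.  Uses a per-scaffold
    interval index so the cost is near-linear in peaks + genes rather than
    all-pairs.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.scaffold_id, IntervalTree()).addi(g.start, g.end, g.gene_id)
    out: list[PeakGeneAssignment] = []
    for p in peaks:
        tree = trees.get(p.scaffold_id)
        if tree is None:
            continue
        # widen by window+1 on each side so gap == window cases are retrieved
        hits = tree.overlap(p.start - window - 1, p.end + window + 1)
        for iv in hits:
            d = _gap(iv.begin, iv.end, p.start, p.end)
            if d <= window:
                out.append(PeakGeneAssignment(peak_id=p.peak_id, gene_id=iv.data, distance=d))
    out.sort(key=lambda a: (a.peak_id, a.gene_id))
    return out


def bound_gene_set(assignments: Iterable[PeakGeneAssignment]) -> set[str]:
    """Distinct genes with at least one assigned peak."""
    return {a.gene_id for a in assignments}
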