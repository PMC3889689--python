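"""Differential expression between control and knockdown count libraries.

The model: per-gene counts are negative binomial with a common dispersion
phi (variance mu + phi * mu^2), library depth enters as a multiplicative
size factor, and total-count normalization is used throughout (the depth a
library contributes is the total reads mapped onto a gene model, not a
trimmed-mean factor).  Testing conditions on the per-gene total after
equalizing library sizes, giving an exact two-sided p-value that reduces to
a binomial split test in the Poisson limit.  Significance calls combine a
strict fold-change cut with a strict Benjamini-Hochberg FDR cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .models import CountMatrix, GeneModel

__all__ = [
    "DispersionEstimate",
    "compute_rpkm",
    "replicate_correlation",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "de_table",
    "call_de",
]


@dataclass(frozen=True)
class DispersionEstimate:
    common_dispersion: float
    n_genes_used: int

    def __post_init__(self) -> None:
        if self.common_dispersion < 0:
            raise ValueError("common_dispersion must be >= 0")


def compute_rpkm(counts: CountMatrix, genes: list[GeneModel]) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[g, s] = 1e9 * count[g, s] / (transcript_length[g] * library_size[s]).
    """
    lengths = {g.gene_id: g.transcript_length for g in genes}
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise ValueError(f"no transcript_length for gene(s): {missing[:5]}")
    length_vec = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    lib = counts.library_size.to_numpy(dtype=float)
    rpkm = 1e9 * counts.counts.to_numpy(dtype=float) / (length_vec[:, None] * lib[None, :])
    return pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_ids)


def replicate_correlation(rpkm: pd.DataFrame, group: dict[str, str]) -> dict[str, float | None]:
    """Per-group Pearson correlation of log2(RPKM + 1) between replicates.

    With exactly two replicates this is the usual scatter-plot r; with more,
    the mean over all pairwise correlations.  A constant column makes r
    undefined and is reported as ``None``.
    """
    out: dict[str, float | None] = {}
    for grp in sorted(set(group.values())):
        samples = [s for s in rpkm.columns if group[s] == grp]
        if len(samples) < 2:
            out[grp] = None
            continue
        mat = np.log2(rpkm[samples].to_numpy(dtype=float) + 1.0)
        rs = []
        undefined = False
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                x, y = mat[:, i], mat[:, j]
                if np.std(x) == 0 or np.std(y) == 0:
                    undefined = True
                    continue
                rs.append(float(np.corrcoef(x, y)[0, 1]))
        out[grp] = None if (undefined and not rs) else (float(np.mean(rs)) if rs else None)
    return out


def _equalized_counts(counts: CountMatrix) -> np.ndarray:
    """Counts rescaled to the geometric-mean library size, rounded
    half-to-even so downstream conditioning sees integers."""
    lib = counts.library_size.to_numpy(dtype=float)
    if (lib == 0).any():
        raise ValueError("a library has zero total counts")
    target = float(np.exp(np.mean(np.log(lib))))
    scaled = counts.counts.to_numpy(dtype=float) * (target / lib)[None, :]
    return np.round(scaled).astype(np.int64)  # numpy rounds half to even


def estimate_common_dispersion(
    counts: CountMatrix, mean_floor: float = 5.0
) -> DispersionEstimate:
    """Moment-based common NB dispersion across genes.

    After scaling all samples to the geometric-mean library size, the
    within-group sample variance s^2 (pooled over the two groups) estimates
    mu + phi * mu^2 for each gene.  The per-gene moment estimate
    max(0, (s^2 - m) / m^2) is summarized by its median over genes whose
    mean exceeds ``mean_floor``; because the median of s^2 at d pooled
    degrees of freedom sits at median(chi2_d)/d of the true variance, the
    pooled s^2 is divided by that factor first so the median across genes
    is an approximately unbiased estimate of phi.
    """
    eq = _equalized_counts(counts).astype(float)
    groups = [counts.samples_in(g) for g in CountMatrix.GROUPS]
    cols = {s: i for i, s in enumerate(counts.sample_ids)}

    df_total = 0
    ss = np.zeros(eq.shape[0])
    for samples in groups:
        if len(samples) < 2:
            continue
        idx = [cols[s] for s in samples]
        sub = eq[:, idx]
        ss += sub.var(axis=1, ddof=1) * (len(samples) - 1)
        df_total += len(samples) - 1
    if df_total == 0:
        raise ValueError("need >= 2 samples in at least one group to estimate dispersion")

    # median-of-moments bias correction: median(chi2_d) / d
    correction = float(chi2.median(df_total) / df_total)
    s2 = ss / df_total / correction
    m = eq.mean(axis=1)
    eligible = m > mean_floor
    if not eligible.any():
        raise ValueError(
            f"no gene has mean scaled count above the floor {mean_floor}; lower mean_floor"
        )
    phi_per_gene = np.maximum(0.0, (s2[eligible] - m[eligible]) / m[eligible] ** 2)
    return DispersionEstimate(
        common_dispersion=float(np.median(phi_per_gene)),
        n_genes_used=int(eligible.sum()),
    )


def _conditional_log_pmf(total: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """Log pmf of the group-A sum given the grand total, under equal means
    after library equalization.

    For NB counts with common dispersion phi, group sums are NB with sizes
    r_a = n_a/phi and r_b = n_b/phi and a shared success probability, so the
    conditional law of the split is negative hypergeometric with weights
    C(k + r_a - 1, k) * C(t - k + r_b - 1, t - k); at phi = 0 it degenerates
    to Binomial(t, n_a / (n_a + n_b)).
    """
    k = np.arange(total + 1, dtype=float)
    if dispersion == 0.0:
        log_w = (
            gammaln(total + 1.0)
            - gammaln(k + 1.0)
            - gammaln(total - k + 1.0)
            + k * np.log(n_a / (n_a + n_b))
            + (total - k) * np.log(n_b / (n_a + n_b))
        )
    else:
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        log_w = (
            gammaln(k + r_a)
            - gammaln(k + 1.0)
            - gammaln(r_a)
            + gammaln(total - k + r_b)
            - gammaln(total - k + 1.0)
            - gammaln(r_b)
        )
    return log_w - logsumexp(log_w)


def nb_exact_test(counts: CountMatrix, dispersion: float) -> pd.Series:
    """Two-sided exact NB test of equal means between the two groups.

    Per gene, libraries are equalized to a common size, the total count is
    held fixed, and the p-value is the summed probability of every split of
    the total at most as probable as the observed one (the classical exact
    two-sided convention, ties included).  Genes with total 0 carry no
    information and get p = 1.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    eq = _equalized_counts(counts)
    cols = {s: i for i, s in enumerate(counts.sample_ids)}
    idx_a = [cols[s] for s in counts.samples_in("knockdown")]
    idx_b = [cols[s] for s in counts.samples_in("control")]
    n_a, n_b = len(idx_a), len(idx_b)

    sum_a = eq[:, idx_a].sum(axis=1)
    totals = sum_a + eq[:, idx_b].sum(axis=1)

    pvals = np.ones(eq.shape[0])
    cache: dict[int, np.ndarray] = {}
    for i in range(eq.shape[0]):
        t = int(totals[i])
        if t == 0:
            continue
        log_pmf = cache.get(t)
        if log_pmf is None:
            log_pmf = _conditional_log_pmf(t, n_a, n_b, dispersion)
            if len(cache) < 4096:
                cache[t] = log_pmf
        obs = log_pmf[int(sum_a[i])]
        mask = log_pmf <= obs + 1e-12  # relative tie tolerance in log space
        pvals[i] = min(1.0, float(np.exp(logsumexp(log_pmf[mask]))))
    return pd.Series(pvals, index=counts.gene_ids, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    counts: CountMatrix,
    genes: list[GeneModel],
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full per-gene DE summary.

    Columns: log2_fold_change (knockdown vs control, from library-equalized
    group means with a 0.5 pseudocount on each mean), mean_rpkm, p_value,
    fdr, testable, is_de (strict |log2FC| > 1 and fdr < 0.05 defaults).
    """
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts).common_dispersion
    eq = _equalized_counts(counts).astype(float)
    cols = {s: i for i, s in enumerate(counts.sample_ids)}
    mean_kd = eq[:, [cols[s] for s in counts.samples_in("knockdown")]].mean(axis=1)
    mean_ctrl = eq[:, [cols[s] for s in counts.samples_in("control")]].mean(axis=1)
    log2fc = np.log2(mean_kd + 0.5) - np.log2(mean_ctrl + 0.5)

    rpkm = compute_rpkm(counts, genes)
    p = nb_exact_test(counts, dispersion)
    fdr = bh_adjust(p.to_numpy())
    table = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "mean_rpkm": rpkm.mean(axis=1).to_numpy(),
            "p_value": p.to_numpy(),
            "fdr": fdr,
            "testable": (mean_kd + mean_ctrl) > 0,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    table["is_de"] = (
        table["testable"]
        & (np.abs(table["log2_fold_change"]) > 1.0)
        & (table["fdr"] < 0.05)
    )
    return table


def call_de(
    table: pd.DataFrame, fold_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> set[str]:
    """Genes passing both cuts, strictly: |log2FC| > log2(fold_threshold)
    and fdr < fdr_threshold.  A gene at exactly twofold, or at exactly the
    FDR cut, is excluded."""
    if fold_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    keep = (
        table["testable"]
        & (np.abs(table["log2_fold_change"]) > np.log2(fold_threshold))
        & (table["fdr"] < fdr_threshold)
    )
    return set(table.index[keep])
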