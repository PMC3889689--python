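"""Synthetic input bundles with known ground truth.

Every generator emulates the statistical structure the analysis assumes:
negative-binomial counts for a 2 control + 2 knockdown design with unequal
library depths, planted fold-changes safely outside the twofold ambiguity
band, ChIP peaks planted near the 5' (first-exon) end of truly bound genes
with attributes that pass the selection rule, a two-homeologs-per-ortholog
duplication structure, and a weighted network with planted cohesive modules
mixing genes of known and unknown function.  A master seed plus a per-stage
tag seeds one RNG per generator, so any stage can be regenerated on its own
and identical seeds give byte-identical output files.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .models import (
    CountMatrix,
    GeneModel,
    GeneSetCollection,
    OrthologMap,
    Peak,
    ScaffoldSet,
    WeightedNetwork,
)

__all__ = [
    "stage_rng",
    "generate_annotation",
    "generate_counts",
    "generate_peaks",
    "generate_network",
    "plant_modules",
    "generate_gene_sets",
    "generate_function_sets",
]

_STAGE_TAGS = {
    "annotation": 1,
    "counts": 2,
    "peaks": 3,
    "network": 4,
    "gene_sets": 5,
    "modules": 6,
    "bound": 7,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One independent RNG per generator stage, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_TAGS[stage],)))


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    n_scaffolds: int,
    n_genes: int,
    homeolog_fraction: float = 0.5,
    seed: int = 0,
    short_scaffold_fraction: float = 0.2,
    intergenic_gap_range: tuple[int, int] = (15_500, 20_000),
    max_scaffold_length: Optional[int] = None,
) -> tuple[ScaffoldSet, list[GeneModel], OrthologMap]:
    """Scaffolded annotation with a homeolog duplication structure.

    ``homeolog_fraction`` of human orthologs receive two frog gene copies
    (suffixed ``.L``/``.S``), the rest one.  Genes are placed sequentially
    without overlap on the long scaffolds; ``short_scaffold_fraction`` of
    scaffolds (at least 10%) are gene-free and shorter than 10 kb, so the
    scaffold filter has something to remove.  The default intergenic gap
    keeps neighbouring genes more than window + window/2 + peak-width apart
    for the default 10 kb assignment window, so a peak planted near one
    gene's 5' end can never fall within the window of the next gene and
    planted binding truth stays exactly recoverable.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0.0 <= homeolog_fraction <= 1.0):
        raise ValueError("homeolog_fraction must be in [0, 1]")
    short_scaffold_fraction = max(short_scaffold_fraction, 0.1)
    rng = stage_rng(seed, "annotation")

    n_short = max(1, round(short_scaffold_fraction * n_scaffolds))
    n_long = n_scaffolds - n_short
    if n_long < 1:
        raise ValueError("n_scaffolds too small: no long scaffold left to hold genes")

    n_human = round(n_genes / (1.0 + homeolog_fraction))
    n_dup = n_genes - n_human
    if not (0 <= n_dup <= n_human):
        raise ValueError("inconsistent homeolog_fraction for this n_genes")
    human_ids = [f"HGENE{i + 1:05d}" for i in range(n_human)]
    dup_idx = set(rng.choice(n_human, size=n_dup, replace=False).tolist())
    frog_to_human: dict[str, str] = {}
    frog_ids: list[str] = []
    for i, hid in enumerate(human_ids):
        suffixes = (".L", ".S") if i in dup_idx else (".L",)
        for sfx in suffixes:
            fid = f"xgene{i + 1:05d}{sfx}"
            frog_ids.append(fid)
            frog_to_human[fid] = hid
    order = rng.permutation(len(frog_ids))
    frog_ids = [frog_ids[i] for i in order]

    per_scaffold = np.array_split(np.arange(len(frog_ids)), n_long)
    scaffold_lengths: dict[str, int] = {}
    genes: list[GeneModel] = []
    for s, idxs in enumerate(per_scaffold):
        sid = f"scaffold_{s + 1:04d}"
        cursor = int(rng.integers(200, 2000))
        for gi in idxs:
            tl = int(rng.integers(500, 3001))
            intron = int(rng.integers(0, 501))
            span = tl + intron
            start = cursor
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=frog_ids[gi],
                    scaffold_id=sid,
                    start=start,
                    end=end,
                    strand=strand,
                    transcript_length=tl,
                    human_ortholog=frog_to_human[frog_ids[gi]],
                )
            )
            cursor = end + int(rng.integers(intergenic_gap_range[0], intergenic_gap_range[1] + 1))
        length = max(cursor + int(rng.integers(500, 2000)), 10_001 + int(rng.integers(0, 5000)))
        if max_scaffold_length is not None and length > max_scaffold_length:
            raise ValueError(
                f"cannot place genes within max_scaffold_length={max_scaffold_length}; "
                "use fewer genes per scaffold or larger scaffolds"
            )
        scaffold_lengths[sid] = length
    for s in range(n_short):
        sid = f"scaffold_{n_long + s + 1:04d}"
        scaffold_lengths[sid] = int(rng.integers(1000, 10_001))
    return ScaffoldSet(scaffold_lengths), genes, OrthologMap(frog_to_human)


# ---------------------------------------------------------------------------
# counts


def generate_counts(
    genes: Sequence[GeneModel],
    n_ctrl: int = 2,
    n_kd: int = 2,
    de_fraction: float = 0.1,
    fold_change_range: tuple[float, float] = (4.0, 8.0),
    dispersion: float = 0.1,
    mean_expression_distribution: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    min_baseline_mean: float = 0.0,
    library_factors: Optional[Sequence[float]] = None,
    allow_borderline_effects: bool = False,
    balance_composition: bool = True,
    seed: int = 0,
) -> tuple[CountMatrix, dict]:
    """NB count matrix with planted fold-changes.

    Knockdown means are baseline * fold-change; fold magnitudes are drawn
    from ``fold_change_range`` and applied up or down, so planted effects
    sit entirely outside the [1/2, 2] ambiguity band unless
    ``allow_borderline_effects`` is set.  With ``balance_composition`` the
    up/down directions are assigned so the planted effects conserve the
    expected total transcriptome output; total-count normalization cannot
    correct a net composition shift, so an unbalanced plant would bleed a
    spurious shift into every null gene.  ``library_factors`` scale the
    per-sample expected depth; the default gives the last knockdown
    replicate 30/72 of the depth of the others, mirroring one shallow
    library in an otherwise balanced design.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if not (0.0 <= de_fraction <= 1.0):
        raise ValueError("de_fraction must be in [0, 1]")
    lo, hi = fold_change_range
    if not allow_borderline_effects and not (lo > 2.0 or hi < 0.5):
        raise ValueError(
            "fold_change_range must lie entirely above 2 or below 1/2 so planted truth "
            "is recoverable at the twofold threshold (or pass allow_borderline_effects=True)"
        )
    rng = stage_rng(seed, "counts")
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)

    if mean_expression_distribution is None:
        baseline = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    else:
        baseline = np.asarray(mean_expression_distribution(rng, n_genes), dtype=float)
    if min_baseline_mean > 0:
        # floor for deterministic-recovery scenarios: a planted fourfold
        # effect on a mean-2 gene is statistically invisible at 2+2 depth
        baseline = np.maximum(baseline, min_baseline_mean)

    n_de = round(de_fraction * n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    fold = np.ones(n_genes)
    magnitudes = rng.uniform(lo, hi, size=n_de)
    if balance_composition and n_de:
        # assign directions greedily so sum(baseline * (fold - 1)) stays
        # near zero: the knockdown's expected total output is conserved
        contrib_up = baseline[de_idx] * (magnitudes - 1.0)
        contrib_dn = baseline[de_idx] * (1.0 / magnitudes - 1.0)
        order = np.argsort(-np.abs(contrib_up))
        running = 0.0
        up = np.zeros(n_de, dtype=bool)
        for t in order:
            if abs(running + contrib_up[t]) < abs(running + contrib_dn[t]):
                up[t] = True
                running += contrib_up[t]
            else:
                running += contrib_dn[t]
    else:
        up = rng.random(n_de) < 0.5
    fold[de_idx] = np.where(up, magnitudes, 1.0 / magnitudes)

    sample_ids = [f"ctrl_{i + 1}" for i in range(n_ctrl)] + [f"kd_{i + 1}" for i in range(n_kd)]
    group = {s: ("control" if s.startswith("ctrl") else "knockdown") for s in sample_ids}
    if library_factors is None:
        library_factors = [1.0] * (n_ctrl + n_kd)
        library_factors[-1] = 30.0 / 72.0  # one shallow knockdown replicate
    library_factors = list(library_factors)
    if len(library_factors) != n_ctrl + n_kd:
        raise ValueError("library_factors must have one entry per sample")

    counts = np.empty((n_genes, n_ctrl + n_kd), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        mu = baseline * library_factors[j]
        if group[sample] == "knockdown":
            mu = mu * fold
        if dispersion == 0.0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    import pandas as pd

    matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), group)
    truth = {
        "true_de_genes": {gene_ids[i] for i in de_idx},
        "planted_fold_changes": {gene_ids[i]: float(fold[i]) for i in sorted(de_idx)},
        "nb_dispersion": float(dispersion),
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# peaks


def generate_peaks(
    genes: Sequence[GeneModel],
    true_bound_genes: Iterable[str],
    n_noise_peaks: int = 0,
    window: int = 10_000,
    attribute_noise: float = 0.1,
    seed: int = 0,
    scaffolds: Optional[ScaffoldSet] = None,
    noise_scaffold_ids: Optional[Sequence[str]] = None,
) -> list[Peak]:
    """Peak list in which exactly the true bound genes are recoverable.

    Every truly bound gene receives at least one peak centred within
    ``window/2`` of its 5' end with attributes passing the selection rule
    (most via the FDR branch, some only via the fold-enrichment branch).
    Noise peaks either carry passing attributes but sit on gene-free
    scaffolds (so no gene lies within the window) or sit anywhere with
    attributes failing both branches.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    true_bound = set(true_bound_genes)
    by_id = {g.gene_id: g for g in genes}
    missing = true_bound - set(by_id)
    if missing:
        raise ValueError(f"true_bound_genes not among genes: {sorted(missing)[:5]}")
    rng = stage_rng(seed, "peaks")
    peaks: list[Peak] = []
    counter = 0

    def passing_attributes() -> tuple[float, float]:
        if rng.random() < 0.3:  # pass only by the fold-enrichment branch
            fdr = float(rng.uniform(0.06, 0.5))
            fold = float(rng.uniform(21.0, 60.0) * (1.0 + attribute_noise * rng.normal()))
            fold = max(fold, 20.5)
        else:  # pass by the FDR branch
            fdr = float(rng.uniform(0.0, 0.045))
            fold = float(max(0.0, rng.uniform(5.0, 40.0) * (1.0 + attribute_noise * rng.normal())))
        return fdr, fold

    for gene_id in sorted(true_bound):
        g = by_id[gene_id]
        n_here = 1 + (1 if rng.random() < 0.2 else 0)
        for _ in range(n_here):
            counter += 1
            width = int(rng.integers(150, 400))
            five_prime = g.start if g.strand == "+" else g.end
            offset = int(rng.integers(-window // 2, window // 2 + 1)) if window > 0 else 0
            center = five_prime + offset
            start = max(0, center - width // 2)
            end = start + width
            if scaffolds is not None:
                limit = scaffolds.length_of(g.scaffold_id)
                if end > limit:
                    end = limit
                    start = max(0, end - width)
            fdr, fold = passing_attributes()
            peaks.append(
                Peak(
                    peak_id=f"true_peak_{counter:05d}",
                    scaffold_id=g.scaffold_id,
                    start=start,
                    end=end,
                    fdr=fdr,
                    fold_enrichment=fold,
                )
            )

    if n_noise_peaks:
        if noise_scaffold_ids is None and scaffolds is not None:
            gene_scaffolds = {g.scaffold_id for g in genes}
            noise_scaffold_ids = sorted(set(scaffolds) - gene_scaffolds)
        n_far = n_noise_peaks // 2
        sorted_gene_ids = sorted(by_id)
        for k in range(n_noise_peaks):
            width = int(rng.integers(150, 400))
            far = k < n_far and noise_scaffold_ids
            if far:
                sid = noise_scaffold_ids[k % len(noise_scaffold_ids)]
                limit = scaffolds.length_of(sid) if scaffolds is not None else 10_000
                start = int(rng.integers(0, max(1, limit - width)))
                fdr, fold = passing_attributes()
            else:
                g = by_id[sorted_gene_ids[int(rng.integers(0, len(by_id)))]]
                sid = g.scaffold_id
                start = max(0, g.start + int(rng.integers(-window, window)))
                fdr = float(rng.uniform(0.06, 0.9))
                fold = float(rng.uniform(0.0, 19.5))
            peaks.append(
                Peak(
                    peak_id=f"noise_peak_{k + 1:05d}",
                    scaffold_id=sid,
                    start=start,
                    end=start + width,
                    fdr=fdr,
                    fold_enrichment=fold,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# network


def _decode_pair_indices(t: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map lexicographic pair indices in [0, C(n,2)) to (i, j) with i < j."""
    t = t.astype(np.float64)
    i = np.floor(((2 * n - 1) - np.sqrt((2 * n - 1) ** 2 - 8 * t)) / 2).astype(np.int64)
    offset = i * (2 * n - i - 1) // 2
    j = (t.astype(np.int64) - offset) + i + 1
    return i, j


def generate_network(
    ortholog_ids: Sequence[str],
    planted_modules: Sequence[dict],
    p_in: float = 0.9,
    p_out: float = 0.02,
    weight_in_range: tuple[float, float] = (0.8, 1.0),
    weight_out_range: tuple[float, float] = (0.05, 0.2),
    seed: int = 0,
) -> WeightedNetwork:
    """Weighted network with planted cohesive modules.

    Within-module pairs get an edge with probability ``p_in`` and a high
    weight; all other pairs with probability ``p_out`` and a low weight.
    Modules may overlap; a pair inside two modules is sampled once.
    """
    if not (p_in > p_out):
        raise ValueError("require p_in > p_out")
    if not (min(weight_in_range) > max(weight_out_range)):
        raise ValueError("weight_in_range must lie entirely above weight_out_range")
    ids = list(ortholog_ids)
    idx = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    for mod in planted_modules:
        members = set(mod["known"]) | set(mod["uncharacterized"])
        missing = members - set(idx)
        if missing:
            raise ValueError(f"module member(s) absent from ortholog_ids: {sorted(missing)[:5]}")
    rng = stage_rng(seed, "network")

    module_pairs: set[tuple[int, int]] = set()
    for mod in planted_modules:
        members = sorted(set(mod["known"]) | set(mod["uncharacterized"]))
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = sorted((idx[members[a]], idx[members[b]]))
                module_pairs.add((i, j))

    edges: list[tuple[str, str, float]] = []
    for i, j in sorted(module_pairs):
        if rng.random() < p_in:
            w = float(rng.uniform(*weight_in_range))
            edges.append((ids[i], ids[j], w))

    total_pairs = n * (n - 1) // 2
    n_bg_pairs = total_pairs - len(module_pairs)
    if n_bg_pairs > 0 and p_out > 0:
        m = int(rng.binomial(n_bg_pairs, p_out))
        chosen: set[int] = set()
        while len(chosen) < m:
            need = m - len(chosen)
            draw = rng.integers(0, total_pairs, size=max(16, int(need * 1.3)))
            for t in draw.tolist():
                if t in chosen:
                    continue
                ii, jj = _decode_pair_indices(np.array([t]), n)
                if (int(ii[0]), int(jj[0])) in module_pairs:
                    continue
                chosen.add(t)
                if len(chosen) == m:
                    break
        arr = np.fromiter(sorted(chosen), dtype=np.int64)
        i_arr, j_arr = _decode_pair_indices(arr, n)
        w_arr = rng.uniform(*weight_out_range, size=len(arr))
        for i, j, w in zip(i_arr.tolist(), j_arr.tolist(), w_arr.tolist()):
            edges.append((ids[i], ids[j], float(w)))
    return WeightedNetwork(edges, nodes=ids)


def plant_modules(
    candidate_ids: Sequence[str],
    n_modules: int = 4,
    size_range: tuple[int, int] = (6, 9),
    known_fraction: float = 0.67,
    seed: int = 0,
) -> list[dict]:
    """Disjoint module assignments with 'known'/'uncharacterized' role labels.

    Each module holds >= 2 known-function genes (so guilt-by-association is
    allowed to fire) and >= 1 uncharacterized gene (so it has something to
    predict).
    """
    rng = stage_rng(seed, "modules")
    pool = list(candidate_ids)
    modules: list[dict] = []
    for _ in range(n_modules):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if len(pool) < size:
            break
        pick = rng.choice(len(pool), size=size, replace=False)
        members = sorted(pool[i] for i in pick)
        pool = [g for i, g in enumerate(pool) if i not in set(pick.tolist())]
        n_known = min(size - 1, max(2, round(known_fraction * size)))
        known = set(members[:n_known])
        modules.append({"known": known, "uncharacterized": set(members[n_known:])})
    return modules


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    ortholog_ids: Sequence[str],
    true_target_ids: Sequence[str],
    ciliary_fraction_of_targets: float = 0.2,
    n_terms: int = 5,
    seed: int = 0,
) -> GeneSetCollection:
    """Reference proteome-like set plus GO-like term sets.

    The reference set contains exactly
    round(ciliary_fraction_of_targets * n_targets) true targets plus
    background genes.  ``term_001`` is enriched among the true targets by
    construction; remaining terms are random background draws.
    """
    if not (0.0 <= ciliary_fraction_of_targets <= 1.0):
        raise ValueError("ciliary_fraction_of_targets must be in [0, 1]")
    rng = stage_rng(seed, "gene_sets")
    targets = sorted(set(true_target_ids))
    others = sorted(set(ortholog_ids) - set(targets))

    n_in = round(ciliary_fraction_of_targets * len(targets))
    ref_targets = [targets[i] for i in rng.choice(len(targets), size=n_in, replace=False)] if n_in else []
    n_bg = min(len(others), max(20, 2 * n_in))
    ref_bg = [others[i] for i in rng.choice(len(others), size=n_bg, replace=False)] if n_bg else []
    sets = {"reference_proteome": ref_targets + ref_bg}
    descriptions = {"reference_proteome": "compiled reference proteome list (synthetic)"}

    for t in range(n_terms):
        name = f"term_{t + 1:03d}"
        if t == 0 and targets:
            n_hit = max(2, round(0.5 * len(targets)))
            hit = [targets[i] for i in rng.choice(len(targets), size=min(n_hit, len(targets)), replace=False)]
            n_miss = min(len(others), max(5, len(hit) // 2))
            miss = [others[i] for i in rng.choice(len(others), size=n_miss, replace=False)] if n_miss else []
            members = hit + miss
            descriptions[name] = "planted enriched term (synthetic)"
        else:
            universe = sorted(set(ortholog_ids))
            size = min(len(universe), int(rng.integers(15, 40)))
            members = [universe[i] for i in rng.choice(len(universe), size=size, replace=False)]
            descriptions[name] = "background term (synthetic)"
        sets[name] = members
    return GeneSetCollection(sets, descriptions)


def generate_function_sets(planted_modules: Sequence[dict]) -> GeneSetCollection:
    """Known-function annotation sets, one per planted module, for
    guilt-by-association: the 'known' members are annotated, the
    'uncharacterized' members are the genes the analysis should flag."""
    sets = {}
    descriptions = {}
    for k, mod in enumerate(planted_modules):
        name = f"function_{k + 1:03d}"
        sets[name] = sorted(mod["known"])
        descriptions[name] = "known-function genes of a planted module (synthetic)"
    return GeneSetCollection(sets, descriptions)
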