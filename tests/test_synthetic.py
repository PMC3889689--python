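"""Ground-truth generators: determinism, duplication structure, NB moments,
planted peaks and networks."""

import numpy as np
import pytest

from tfdirect import synthetic
from tfdirect.peaks import assign_peaks_to_genes, bound_gene_set, select_peaks


# ---------------------------------------------------------------------------
# annotation


def test_homeolog_fraction_zero_gives_bijection():
    _, genes, om = synthetic.generate_annotation(6, 40, homeolog_fraction=0.0, seed=1)
    humans = [om.human_for(g.gene_id) for g in genes]
    assert len(set(humans)) == len(genes) == 40


def test_homeolog_fraction_one_pairs_every_ortholog():
    _, genes, om = synthetic.generate_annotation(4, 10, homeolog_fraction=1.0, seed=1)
    assert len(genes) == 10
    assert len(om.human_gene_ids) == 5
    for h in om.human_gene_ids:
        assert len(om.frogs_for(h)) == 2


def test_annotation_is_deterministic_given_seed():
    a1 = synthetic.generate_annotation(6, 50, 0.5, seed=9)
    a2 = synthetic.generate_annotation(6, 50, 0.5, seed=9)
    assert a1[0] == a2[0] and a1[1] == a2[1] and a1[2] == a2[2]
    b = synthetic.generate_annotation(6, 50, 0.5, seed=10)
    assert a1[1] != b[1]


def test_short_scaffolds_present_and_gene_free():
    scaffolds, genes, _ = synthetic.generate_annotation(20, 100, 0.5, seed=0)
    short = [s for s in scaffolds if scaffolds.length_of(s) <= 10_000]
    assert len(short) >= 2  # >= 10% of scaffolds
    assert not {g.scaffold_id for g in genes} & set(short)


def test_genes_do_not_overlap_and_fit_scaffolds():
    scaffolds, genes, _ = synthetic.generate_annotation(8, 120, 0.5, seed=3)
    by_scaffold: dict[str, list] = {}
    for g in genes:
        assert g.end <= scaffolds.length_of(g.scaffold_id)
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for gs in by_scaffold.values():
        gs.sort(key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            assert a.end <= b.start


# ---------------------------------------------------------------------------
# counts


def _genes(n, seed=0):
    return synthetic.generate_annotation(6, n, 0.5, seed=seed)[1]


def test_zero_dispersion_counts_are_poisson_like():
    genes = _genes(1000)
    cm, _ = synthetic.generate_counts(
        genes, de_fraction=0.0, dispersion=0.0, library_factors=[1, 1, 1, 1], seed=4
    )
    arr = cm.counts.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    keep = mean > 20  # the ratio estimator is stable only for decent means
    ratio = arr[keep].var(axis=1, ddof=1) / mean[keep]
    # the dispersion index (variance/mean) averages to 1 for Poisson;
    # s^2/m has ~chi2_3/3 spread, SE of the mean over n genes = sqrt(2/3/n)
    assert abs(ratio.mean() - 1.0) < 3 * np.sqrt(2 / 3 / keep.sum())


def test_de_fraction_zero_gives_empty_truth():
    cm, truth = synthetic.generate_counts(_genes(50), de_fraction=0.0, seed=1)
    assert truth["true_de_genes"] == set()
    assert truth["planted_fold_changes"] == {}


def test_nb_moments_match_dispersion_within_3_se():
    genes = _genes(1000)
    phi = 0.2
    cm, _ = synthetic.generate_counts(
        genes,
        de_fraction=0.0,
        dispersion=phi,
        mean_expression_distribution=lambda rng, n: np.full(n, 100.0),
        library_factors=[1, 1, 1, 1],
        seed=5,
    )
    arr = cm.counts.to_numpy(dtype=float).ravel()
    assert abs(arr.mean() - 100.0) < 3 * arr.std() / np.sqrt(arr.size)
    expected_var = 100.0 + phi * 100.0**2
    # SE of the sample variance for NB via the fourth-moment bound; 3 SD band
    assert abs(arr.var(ddof=1) - expected_var) < 0.2 * expected_var


def test_planted_fourfold_shifts_knockdown_means():
    genes = _genes(400, seed=2)
    cm, truth = synthetic.generate_counts(
        genes,
        de_fraction=0.5,
        fold_change_range=(4.0, 4.0),
        dispersion=0.05,
        mean_expression_distribution=lambda rng, n: np.full(n, 100.0),
        library_factors=[1, 1, 1, 1],
        seed=6,
    )
    kd = cm.counts[cm.samples_in("knockdown")].mean(axis=1)
    for g, fc in truth["planted_fold_changes"].items():
        assert fc in (4.0, 0.25)
        expected = 100.0 * fc
        se = np.sqrt((expected + 0.05 * expected**2) / 2)
        assert abs(kd[g] - expected) < 4 * se  # per-gene 4 SE band


def test_fold_range_inside_ambiguity_band_rejected():
    with pytest.raises(ValueError, match="fold_change_range"):
        synthetic.generate_counts(_genes(10), fold_change_range=(1.5, 3.0))


def test_counts_deterministic_given_seed():
    genes = _genes(100)
    c1, t1 = synthetic.generate_counts(genes, seed=11)
    c2, t2 = synthetic.generate_counts(genes, seed=11)
    assert c1 == c2 and t1 == t2


# ---------------------------------------------------------------------------
# peaks


def test_noise_free_peaks_recover_exactly_true_bound():
    scaffolds, genes, _ = synthetic.generate_annotation(10, 200, 0.5, seed=7)
    rng = np.random.default_rng(7)
    bound = {genes[i].gene_id for i in rng.choice(len(genes), 40, replace=False)}
    peaks = synthetic.generate_peaks(genes, bound, n_noise_peaks=0, seed=7, scaffolds=scaffolds)
    selected = select_peaks(peaks)
    assert len(selected) == len(peaks)
    assert bound_gene_set(assign_peaks_to_genes(selected, genes)) == bound


def test_failing_attribute_peak_never_selected():
    scaffolds, genes, _ = synthetic.generate_annotation(6, 40, 0.5, seed=8)
    peaks = synthetic.generate_peaks(genes, set(), n_noise_peaks=40, seed=8, scaffolds=scaffolds)
    near = [p for p in peaks if p.peak_id.startswith("noise") and p.scaffold_id in {g.scaffold_id for g in genes}]
    assert near, "generator should place failing-attribute noise near genes"
    assert select_peaks(near) == []


def test_true_and_far_noise_peaks_give_perfect_precision_recall():
    scaffolds, genes, _ = synthetic.generate_annotation(12, 100, 0.5, seed=9)
    rng = np.random.default_rng(9)
    bound = {genes[i].gene_id for i in rng.choice(len(genes), 50, replace=False)}
    peaks = synthetic.generate_peaks(genes, bound, n_noise_peaks=100, seed=9, scaffolds=scaffolds)
    recovered = bound_gene_set(assign_peaks_to_genes(select_peaks(peaks), genes))
    assert recovered == bound  # recall 1.0 and precision 1.0


# ---------------------------------------------------------------------------
# network and gene sets


def _modules(ids, sizes=(5, 5)):
    out, cursor = [], 0
    for s in sizes:
        members = ids[cursor : cursor + s]
        out.append({"known": set(members[:-1]), "uncharacterized": {members[-1]}})
        cursor += s
    return out


def test_p_out_zero_components_contain_planted_modules():
    ids = [f"H{i:03d}" for i in range(40)]
    mods = _modules(ids)
    net = synthetic.generate_network(ids, mods, p_in=1.0, p_out=0.0, seed=10)
    import networkx as nx

    comps = list(nx.connected_components(net.graph))
    for m in mods:
        members = m["known"] | m["uncharacterized"]
        assert any(members <= c for c in comps)


def test_edge_count_matches_binomial_expectation():
    ids = [f"H{i:03d}" for i in range(120)]
    mods = _modules(ids, sizes=(8, 8))
    p_in, p_out = 0.9, 0.05
    net = synthetic.generate_network(ids, mods, p_in=p_in, p_out=p_out, seed=11)
    n_mod_pairs = 2 * (8 * 7 // 2)
    n_bg = 120 * 119 // 2 - n_mod_pairs
    expected = p_in * n_mod_pairs + p_out * n_bg
    sd = np.sqrt(n_mod_pairs * p_in * (1 - p_in) + n_bg * p_out * (1 - p_out))
    assert abs(net.n_edges - expected) <= 3 * sd


def test_module_member_absent_from_ids_raises():
    with pytest.raises(ValueError, match="absent"):
        synthetic.generate_network(["H1", "H2"], [{"known": {"H1", "HX"}, "uncharacterized": set()}])


def test_network_weights_separate_in_from_out():
    ids = [f"H{i:03d}" for i in range(30)]
    mods = _modules(ids, sizes=(6,))
    net = synthetic.generate_network(ids, mods, seed=12)
    members = mods[0]["known"] | mods[0]["uncharacterized"]
    for a, b, w in net.edges():
        if a in members and b in members:
            assert w >= 0.8
        else:
            assert w <= 0.2


def test_reference_set_contains_exact_target_fraction():
    ids = [f"H{i:03d}" for i in range(500)]
    targets = ids[:100]
    sets = synthetic.generate_gene_sets(ids, targets, ciliary_fraction_of_targets=0.2, seed=13)
    assert len(set(targets) & sets["reference_proteome"]) == 20


def test_no_terms_leaves_only_reference_set():
    ids = [f"H{i:03d}" for i in range(50)]
    sets = synthetic.generate_gene_sets(ids, ids[:10], n_terms=0, seed=14)
    assert list(sets) == ["reference_proteome"]


def test_function_sets_expose_known_members_only():
    mods = [{"known": {"a", "b"}, "uncharacterized": {"c"}}]
    fs = synthetic.generate_function_sets(mods)
    assert fs["function_001"] == frozenset({"a", "b"})
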