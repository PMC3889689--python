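"""Ortholog collapse, cohesiveness clustering and guilt-by-association."""

import itertools

import numpy as np
import pytest

from tfdirect.models import GeneSetCollection, OrthologMap, WeightedNetwork
from tfdirect.netmod import (
    cohesiveness,
    collapse_to_orthologs,
    detect_modules,
    extract_subnetwork,
    grow_module,
    guilt_by_association,
    omega_overlap,
)


# ---------------------------------------------------------------------------
# ortholog collapse


def test_evidence_transfers_from_either_alloallele():
    om = OrthologMap({"g.L": "G", "g.S": "G"})
    table = collapse_to_orthologs({"g.L": (True, False), "g.S": (False, False)}, om)
    assert bool(table.loc["G", "bound"]) is True
    assert bool(table.loc["G", "differential"]) is False


def test_direct_target_needs_one_copy_with_both_flags():
    om = OrthologMap({"g.L": "G", "g.S": "G"})
    # one copy bound, the other differential: the human gene is both marked
    # but no single copy was a direct target
    split = collapse_to_orthologs({"g.L": (True, False), "g.S": (False, True)}, om)
    assert bool(split.loc["G", "direct_target"]) is False
    joint = collapse_to_orthologs({"g.L": (True, True), "g.S": (False, False)}, om)
    assert bool(joint.loc["G", "direct_target"]) is True


def test_double_evidence_counts_once():
    om = OrthologMap({"g.L": "G", "g.S": "G"})
    table = collapse_to_orthologs({"g.L": (True, True), "g.S": (True, True)}, om)
    assert len(table) == 1


def test_unmapped_frog_genes_are_dropped_and_counted():
    om = OrthologMap({"g.L": "G"})
    table = collapse_to_orthologs({"g.L": (True, True), "orphan": (True, True)}, om)
    assert list(table.index) == ["G"]
    assert table.attrs["n_unmapped_dropped"] == 1


# ---------------------------------------------------------------------------
# subnetwork extraction


def test_extract_identity_and_empty():
    net = WeightedNetwork([("a", "b", 1.0), ("b", "c", 1.0)])
    assert extract_subnetwork(net, {"a", "b", "c"}).edges() == net.edges()
    assert extract_subnetwork(net, set()).n_nodes == 0


def test_extract_induced_subgraph_by_hand():
    net = WeightedNetwork(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "e", 1.0), ("a", "c", 1.0)]
    )
    sub = extract_subnetwork(net, {"a", "b", "c"})
    assert sub.n_nodes == 3 and sub.n_edges == 3
    sub2 = extract_subnetwork(net, {"a", "b", "d"})
    assert sub2.n_nodes == 3 and sub2.n_edges == 1


# ---------------------------------------------------------------------------
# cohesiveness


def _triangle():
    return WeightedNetwork([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])


def test_isolated_triangle_scores():
    assert cohesiveness({"a", "b", "c"}, _triangle(), penalty=0.0) == pytest.approx(1.0)
    assert cohesiveness({"a", "b", "c"}, _triangle(), penalty=2.0) == pytest.approx(1 / 3)


def test_isolated_node_scores_zero():
    net = WeightedNetwork(nodes=["x"])
    assert cohesiveness({"x"}, net, penalty=2.0) == 0.0


def test_member_not_in_network_raises():
    with pytest.raises(ValueError, match="not in network"):
        cohesiveness({"zz"}, _triangle())


def test_boundary_weight_lowers_score():
    net = WeightedNetwork([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0), ("c", "out", 2.0)])
    # w_in=3, w_bound=2, penalty 0: f = 3/5
    assert cohesiveness({"a", "b", "c"}, net, penalty=0.0) == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# greedy growth and its exhaustive oracle


def _clique(ids, w=1.0):
    return [(a, b, w) for a, b in itertools.combinations(ids, 2)]


def test_seed_in_isolated_4_clique_returns_clique():
    net = WeightedNetwork(_clique("abcd"))
    mod = grow_module("a", net, penalty=2.0)
    assert mod.member_ids == frozenset("abcd")
    assert mod.cohesiveness == pytest.approx(6 / 14)  # 6/(6+0+8) = 3/7


def test_isolated_seed_stays_alone():
    net = WeightedNetwork([("a", "b", 1.0)], nodes=["x"])
    mod = grow_module("x", net)
    assert mod.member_ids == frozenset({"x"})
    assert mod.cohesiveness == 0.0


def test_barbell_growth_stays_on_one_side():
    edges = _clique("abcd") + _clique("efgh") + [("d", "e", 0.1)]
    net = WeightedNetwork(edges)
    for seed, side in [("a", set("abcd")), ("h", set("efgh"))]:
        assert grow_module(seed, net, penalty=2.0).member_ids == frozenset(side)


def _scratch_f(members, net, penalty):
    members = set(members)
    w_in = w_bound = 0.0
    for a, b, w in net.edges():
        inside = (a in members) + (b in members)
        if inside == 2:
            w_in += w
        elif inside == 1:
            w_bound += w
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom else 0.0


def _oracle_greedy(seed, net, penalty):
    """From-scratch greedy with the same move set and tie-breaking, scoring
    every candidate subset independently of the incremental implementation."""
    members = {seed}
    nodes = set(net.graph.nodes)
    while True:
        current = _scratch_f(members, net, penalty)
        best_gain, best = 0.0, None
        neighbors = sorted(
            {v for m in members for v in net.graph[m]} - members
        )
        for v in neighbors:
            gain = _scratch_f(members | {v}, net, penalty) - current
            if gain > best_gain + 1e-12:
                best_gain, best = gain, ("add", v)
        if len(members) > 1:
            for v in sorted(members):
                gain = _scratch_f(members - {v}, net, penalty) - current
                if gain > best_gain + 1e-12:
                    best_gain, best = gain, ("rm", v)
        if best is None:
            return frozenset(members), current
        op, v = best
        members = members | {v} if op == "add" else members - {v}


@pytest.mark.parametrize("trial", range(12))
def test_growth_matches_scratch_greedy_on_small_random_graphs(trial):
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(4, 9))
    ids = [chr(ord("a") + i) for i in range(n)]
    edges = [
        (a, b, float(rng.uniform(0.1, 1.0)))
        for a, b in itertools.combinations(ids, 2)
        if rng.random() < 0.5
    ]
    net = WeightedNetwork(edges, nodes=ids)
    penalty = float(rng.uniform(0.0, 3.0))
    for seed in ids:
        mod = grow_module(seed, net, penalty=penalty)
        members, f = _oracle_greedy(seed, net, penalty)
        assert mod.member_ids == members
        assert mod.cohesiveness == pytest.approx(f, abs=1e-12)
        # local optimum: no single move improves the score
        for v in sorted(set(ids) - set(mod.member_ids)):
            assert _scratch_f(mod.member_ids | {v}, net, penalty) <= f + 1e-12
        if len(mod.member_ids) > 1:
            for v in mod.member_ids:
                assert _scratch_f(mod.member_ids - {v}, net, penalty) <= f + 1e-12


# ---------------------------------------------------------------------------
# omega overlap and module detection


def test_omega_overlap_values():
    assert omega_overlap({"a", "b"}, {"a", "b"}) == 1.0
    assert omega_overlap({"a"}, {"b"}) == 0.0
    assert omega_overlap({"a", "b", "c", "d"}, {"a", "b"}) == pytest.approx(0.5)


def test_two_disjoint_cliques_detected_exactly():
    net = WeightedNetwork(_clique("abcd") + _clique("efgh"))
    modules = detect_modules(net, penalty=2.0)
    assert {m.member_ids for m in modules} == {frozenset("abcd"), frozenset("efgh")}


def test_tiny_network_yields_no_modules():
    net = WeightedNetwork([("a", "b", 1.0)])
    assert detect_modules(net, min_size=3) == []


def test_empty_network_yields_no_modules():
    assert detect_modules(WeightedNetwork()) == []


def test_detection_is_deterministic():
    rng = np.random.default_rng(5)
    ids = [f"n{i}" for i in range(30)]
    edges = [
        (a, b, float(rng.uniform(0.1, 1.0)))
        for a, b in itertools.combinations(ids, 2)
        if rng.random() < 0.2
    ]
    net = WeightedNetwork(edges, nodes=ids)
    first = detect_modules(net)
    second = detect_modules(net)
    assert [(m.member_ids, m.cohesiveness) for m in first] == [
        (m.member_ids, m.cohesiveness) for m in second
    ]


def test_heavily_overlapping_modules_merge():
    modules = detect_modules(WeightedNetwork(_clique("abcde")), merge_overlap=0.8)
    assert len(modules) == 1


# ---------------------------------------------------------------------------
# guilt by association


def test_unannotated_module_member_becomes_candidate():
    net = WeightedNetwork(_clique(["ift88", "ttc30a", "X"]))
    (mod,) = detect_modules(net)
    sets = GeneSetCollection({"IFT": ["ift88", "ttc30a"]})
    table = guilt_by_association([mod], sets)
    assert list(table["gene"]) == ["X"]
    assert table.loc[0, "score"] == pytest.approx(1.0)  # 2 known / (3 - 1)
    assert table.loc[0, "function"] == "IFT"


def test_fully_annotated_module_yields_no_candidates():
    net = WeightedNetwork(_clique("abc"))
    (mod,) = detect_modules(net)
    table = guilt_by_association([mod], GeneSetCollection({"F": ["a", "b", "c"]}))
    assert table.empty


def test_single_known_member_is_not_enough():
    net = WeightedNetwork(_clique("abc"))
    (mod,) = detect_modules(net)
    table = guilt_by_association([mod], GeneSetCollection({"F": ["a"]}), min_known=2)
    assert table.empty
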