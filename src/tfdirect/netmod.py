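"""Ortholog-space network analysis of the target evidence.

The duplicated (homeologous) frog genes are collapsed onto single human
orthologs, binding/DE evidence transferring from either copy.  The evidence
genes induce a subnetwork of the weighted functional network, which is
clustered into overlapping cohesive modules by a greedy growth procedure:
a module's cohesiveness

    f(M) = w_in / (w_in + w_bound + penalty * |M|)

rewards internal edge weight, punishes boundary weight, and the penalty
term models unobserved false-negative edges per member.  Uncharacterized
genes that cluster tightly with genes of known function are then ranked as
functional candidates (guilt by association).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .models import GeneSetCollection, Module, OrthologMap, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_to_orthologs",
    "extract_subnetwork",
    "cohesiveness",
    "grow_module",
    "detect_modules",
    "omega_overlap",
    "guilt_by_association",
    "write_graphml",
]


def collapse_to_orthologs(
    frog_evidence: Mapping[str, tuple[bool, bool]], orthologs: OrthologMap
) -> pd.DataFrame:
    """OR-transfer per-frog-gene (bound, differential) flags to human orthologs.

    A human gene is bound/differential if either alloallele is; it is a
    direct target if either alloallele is itself both bound and
    differential.  Frog genes without an ortholog are dropped (the network
    namespace is human-only); the dropped count is logged and stored in
    ``result.attrs["n_unmapped_dropped"]``.
    """
    flags: dict[str, dict[str, bool]] = {}
    dropped = 0
    for frog_id, (bound, differential) in sorted(frog_evidence.items()):
        human = orthologs.human_for(frog_id)
        if human is None:
            dropped += 1
            continue
        row = flags.setdefault(human, {"bound": False, "differential": False, "direct_target": False})
        row["bound"] = row["bound"] or bool(bound)
        row["differential"] = row["differential"] or bool(differential)
        row["direct_target"] = row["direct_target"] or (bool(bound) and bool(differential))
    if dropped:
        logger.info("collapse_to_orthologs: dropped %d frog gene(s) without an ortholog", dropped)
    table = pd.DataFrame.from_dict(flags, orient="index").astype(bool)
    if table.empty:
        table = pd.DataFrame(columns=["bound", "differential", "direct_target"], dtype=bool)
    table = table.sort_index()
    table.index.name = "human_gene_id"
    table.attrs["n_unmapped_dropped"] = dropped
    return table


def extract_subnetwork(network: WeightedNetwork, evidence_ids: Iterable[str]) -> WeightedNetwork:
    """Subgraph induced by the evidence genes present in the network."""
    evidence = set(evidence_ids)
    absent = evidence - set(network.graph.nodes)
    sub = network.induced(evidence)
    logger.info(
        "extract_subnetwork: %d nodes, %d edges (%d evidence gene(s) absent from the network)",
        sub.n_nodes, sub.n_edges, len(absent),
    )
    return sub


def _weights(network: WeightedNetwork, members: set[str]) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    g = network.graph
    for u in members:
        for v, data in g[u].items():
            w = data["weight"]
            if v in members:
                w_in += w / 2.0
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(members: Iterable[str], network: WeightedNetwork, penalty: float = 2.0) -> float:
    """f = w_in / (w_in + w_bound + penalty * |members|), in [0, 1]."""
    members = set(members)
    if not members:
        raise ValueError("members must be non-empty")
    missing = members - set(network.graph.nodes)
    if missing:
        raise ValueError(f"member(s) not in network: {sorted(missing)[:5]}")
    w_in, w_bound = _weights(network, members)
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


class _GrowState:
    """Incremental cohesiveness bookkeeping for greedy growth.

    ``conn[v]`` is the total edge weight from node v to the current
    members, maintained for members and their neighbors alike, so every
    candidate add/remove is scored in O(1).
    """

    def __init__(self, network: WeightedNetwork, penalty: float):
        self.g = network.graph
        self.penalty = penalty
        self.members: set[str] = set()
        self.conn: dict[str, float] = {}
        self.w_in = 0.0
        self.w_deg = 0.0  # sum of weighted degrees of members
        self._degw: dict[str, float] = {}

    def degw(self, v: str) -> float:
        w = self._degw.get(v)
        if w is None:
            w = sum(d["weight"] for d in self.g[v].values())
            self._degw[v] = w
        return w

    def add(self, v: str) -> None:
        self.members.add(v)
        self.w_in += self.conn.get(v, 0.0)
        self.w_deg += self.degw(v)
        for u, d in self.g[v].items():
            self.conn[u] = self.conn.get(u, 0.0) + d["weight"]

    def remove(self, v: str) -> None:
        self.members.discard(v)
        for u, d in self.g[v].items():
            self.conn[u] -= d["weight"]
        self.w_in -= self.conn.get(v, 0.0)
        self.w_deg -= self.degw(v)

    def f(self) -> float:
        w_bound = self.w_deg - 2.0 * self.w_in
        denom = self.w_in + w_bound + self.penalty * len(self.members)
        return self.w_in / denom if denom > 0 else 0.0

    def f_after_add(self, v: str) -> float:
        c = self.conn.get(v, 0.0)
        w_in = self.w_in + c
        w_bound = (self.w_deg + self.degw(v)) - 2.0 * w_in
        denom = w_in + w_bound + self.penalty * (len(self.members) + 1)
        return w_in / denom if denom > 0 else 0.0

    def f_after_remove(self, v: str) -> float:
        c = self.conn.get(v, 0.0)  # for a member: weight to the other members
        w_in = self.w_in - c
        w_bound = (self.w_deg - self.degw(v)) - 2.0 * w_in
        denom = w_in + w_bound + self.penalty * (len(self.members) - 1)
        return w_in / denom if denom > 0 else 0.0


def grow_module(
    seed_gene: str,
    network: WeightedNetwork,
    penalty: float = 2.0,
    max_size: int | None = None,
) -> Module:
    """Greedy cohesive module around a seed.

    From {seed}, repeatedly apply the single-node addition (any neighbor of
    the module) or removal that most increases cohesiveness; stop at a
    local optimum.  Ties break toward the lexicographically smallest gene
    id, so the result is deterministic.

    ``max_size`` truncates runaway growth: on a graph whose background
    weights are near-uniform, cohesiveness can keep increasing until the
    module swallows a whole connected component (the boundary term goes to
    zero).  A truncated result is generally not a local optimum; callers
    that need the local-optimum guarantee should leave ``max_size`` unset
    or discard modules that hit the cap (as :func:`detect_modules` does via
    its density filter).
    """
    if seed_gene not in network.graph.nodes:
        raise ValueError(f"seed {seed_gene!r} not in network")
    state = _GrowState(network, penalty)
    state.add(seed_gene)
    while True:
        current = state.f()
        best_gain = 0.0
        best_move: tuple[int, str] | None = None  # (0 add / 1 remove, node)
        allow_add = max_size is None or len(state.members) < max_size
        if allow_add:
            candidates_add = sorted(
                v for v in state.conn if v not in state.members and state.conn[v] > 0
            )
            for v in candidates_add:
                gain = state.f_after_add(v) - current
                if gain > best_gain + 1e-12:
                    best_gain, best_move = gain, (0, v)
        if len(state.members) > 1:
            for v in sorted(state.members):
                gain = state.f_after_remove(v) - current
                if gain > best_gain + 1e-12:
                    best_gain, best_move = gain, (1, v)
        if best_move is None:
            break
        op, node = best_move
        if op == 0:
            state.add(node)
        else:
            state.remove(node)
    return Module(
        member_ids=frozenset(state.members),
        cohesiveness=state.f(),
        seed_id=seed_gene,
    )


def omega_overlap(a: Iterable[str], b: Iterable[str]) -> float:
    """Match coefficient omega(A, B) = |A & B|^2 / (|A| * |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _weighted_density(members: frozenset[str], network: WeightedNetwork) -> float:
    n = len(members)
    if n < 2:
        return 0.0
    w_in, _ = _weights(network, set(members))
    return w_in / (n * (n - 1) / 2.0)


def detect_modules(
    network: WeightedNetwork,
    penalty: float = 2.0,
    min_size: int = 3,
    min_density: float = 0.3,
    merge_overlap: float = 0.8,
    growth_cap: int | None = 50,
) -> list[Module]:
    """Overlapping cohesive modules of the whole network.

    Seeds are taken in decreasing weighted-degree order (lexicographic tie
    break), skipping nodes already inside a retained module; each seed is
    grown greedily; modules smaller than ``min_size`` or with weighted
    density w_in / C(|V|, 2) below ``min_density`` are discarded; finally,
    pairs with omega overlap >= ``merge_overlap`` are merged (union) until
    none qualify.  Deterministic for a given input.

    ``growth_cap`` bounds each greedy growth (see :func:`grow_module`); a
    growth that hits the cap is a runaway over near-uniform background
    weight and is far too sparse to survive the density filter, so the cap
    changes runtime, not results, for any module denser than the
    background.
    """
    if min_size < 1 or not (0 <= min_density) or not (0 < merge_overlap <= 1):
        raise ValueError("invalid clustering parameters")
    g = network.graph
    if g.number_of_nodes() == 0:
        return []
    degw = {v: sum(d["weight"] for d in g[v].values()) for v in g.nodes}
    seeds = sorted(g.nodes, key=lambda v: (-degw[v], v))
    retained: list[Module] = []
    covered: set[str] = set()
    for seed in seeds:
        if seed in covered:
            continue
        mod = grow_module(seed, network, penalty=penalty, max_size=growth_cap)
        if mod.size < min_size:
            continue
        if _weighted_density(mod.member_ids, network) < min_density:
            continue
        retained.append(mod)
        covered |= mod.member_ids

    # iterative merging of heavily overlapping modules
    merged = True
    while merged:
        merged = False
        retained.sort(key=lambda m: (-m.cohesiveness, sorted(m.member_ids)))
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                if omega_overlap(retained[i].member_ids, retained[j].member_ids) >= merge_overlap:
                    union = retained[i].member_ids | retained[j].member_ids
                    new = Module(
                        member_ids=union,
                        cohesiveness=cohesiveness(union, network, penalty=penalty),
                        seed_id=retained[i].seed_id,
                    )
                    retained = [m for k, m in enumerate(retained) if k not in (i, j)] + [new]
                    merged = True
                    break
            if merged:
                break
    retained.sort(key=lambda m: (-m.cohesiveness, sorted(m.member_ids)))
    return retained


def guilt_by_association(
    modules: list[Module],
    known_function_sets: GeneSetCollection,
    min_known: int = 2,
) -> pd.DataFrame:
    """Rank unannotated module members by the company they keep.

    For every (module, function set) pair with at least ``min_known``
    annotated members inside the module, each member *not* in the set
    becomes a candidate for that function with score
    known_in_module / (module_size - 1), i.e. the fraction of its module
    partners carrying the annotation.  Requiring two known members keeps a
    single annotated gene from driving a prediction.
    """
    rows = []
    for idx, mod in enumerate(modules):
        module_id = f"module_{idx + 1:03d}"
        for name, members in sorted(known_function_sets.items()):
            known = mod.member_ids & members
            if len(known) < min_known or mod.size < 2:
                continue
            score = len(known) / (mod.size - 1)
            for gene in sorted(mod.member_ids - members):
                rows.append(
                    {
                        "gene": gene,
                        "function": name,
                        "score": score,
                        "n_known_in_module": len(known),
                        "module_id": module_id,
                        "module_cohesiveness": mod.cohesiveness,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["gene", "function", "score", "n_known_in_module", "module_id", "module_cohesiveness"],
    )
    if not table.empty:
        table = table.sort_values(
            ["score", "module_cohesiveness", "gene", "function"],
            ascending=[False, False, True, True],
        ).reset_index(drop=True)
    return table


def write_graphml(network: WeightedNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
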