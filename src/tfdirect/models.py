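"""Domain types shared across the pipeline.

Coordinate convention: every interval in memory is 0-based, half-open
``[start, end)`` on its scaffold.  Converters to and from 1-based closed
formats (GFF3) live at the I/O boundary in :mod:`tfdirect.annotation_io`;
nothing outside that module ever does coordinate arithmetic for a format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx

__all__ = [
    "ScaffoldSet",
    "GeneModel",
    "Peak",
    "CountMatrix",
    "OrthologMap",
    "WeightedNetwork",
    "GeneSetCollection",
    "Module",
    "TruthRecord",
]


class ScaffoldSet:
    """The scaffolds of a draft genome assembly with their lengths in bases.

    Draft amphibian assemblies are highly fragmented; very short scaffolds
    carry unreliable gene models and are removed before any analysis (see
    :meth:`filter`).
    """

    def __init__(self, lengths: Mapping[str, int]):
        lengths = dict(lengths)
        for sid, length in lengths.items():
            if not isinstance(length, (int,)) or isinstance(length, bool):
                raise TypeError(f"scaffold {sid!r}: length must be an integer, got {length!r}")
            if length <= 0:
                raise ValueError(f"scaffold {sid!r}: length must be positive, got {length}")
        self._lengths = lengths

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ScaffoldSet) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"ScaffoldSet({len(self)} scaffolds)"

    def length_of(self, scaffold_id: str) -> int:
        return self._lengths[scaffold_id]

    def filter(self, min_length: int = 10_000) -> "ScaffoldSet":
        """Keep scaffolds strictly longer than ``min_length`` bases.

        The inequality is strict: a scaffold of exactly ``min_length``
        bases is removed.  Idempotent, and monotone in ``min_length``.
        """
        if min_length < 0:
            raise ValueError("min_length must be >= 0")
        return ScaffoldSet({s: l for s, l in self._lengths.items() if l > min_length})


@dataclass(frozen=True)
class GeneModel:
    """One gene, represented by its longest transcript's genomic interval.

    ``transcript_length`` is the summed exonic length of the longest
    transcript and is the length used for RPKM; it can be smaller than
    ``end - start`` when the transcript has introns.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    transcript_length: int
    human_ortholog: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.transcript_length < 1:
            raise ValueError(f"gene {self.gene_id!r}: transcript_length must be >= 1")
        if self.transcript_length > self.end - self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: transcript_length {self.transcript_length} exceeds "
                f"genomic span {self.end - self.start}"
            )


@dataclass(frozen=True)
class Peak:
    """A ChIP enrichment interval with its significance attributes.

    ``fdr`` is stored as a fraction in [0, 1] regardless of the on-disk
    dialect; ``fold_enrichment`` is the treatment/control signal ratio.
    """

    peak_id: str
    scaffold_id: str
    start: int
    end: int
    fdr: float
    fold_enrichment: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.peak_id!r}: start must be < end")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"peak {self.peak_id!r}: fdr must be in [0, 1], got {self.fdr}")
        if self.fold_enrichment < 0:
            raise ValueError(f"peak {self.peak_id!r}: fold_enrichment must be >= 0")


class CountMatrix:
    """Per-gene read counts for a two-condition replicated design.

    Wraps a genes x samples integer ``pandas.DataFrame``; ``group`` maps
    each sample to ``"control"`` or ``"knockdown"``.  Library sizes are the
    column sums (total reads mapped onto a gene model), the quantity the
    normalization divides by.
    """

    GROUPS = ("control", "knockdown")

    def __init__(self, counts, group: Mapping[str, str]):
        import numpy as np
        import pandas as pd

        counts = pd.DataFrame(counts)
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        group = dict(group)
        missing = set(counts.columns) - set(group)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = {s: g for s, g in group.items() if g not in self.GROUPS}
        if bad:
            raise ValueError(f"group labels must be one of {self.GROUPS}: {bad}")
        labels = [group[s] for s in counts.columns]
        for g in self.GROUPS:
            if labels.count(g) < 1:
                raise ValueError(f"need at least one {g!r} sample")
        self.counts = counts
        self.group = {s: group[s] for s in counts.columns}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_size(self):
        return self.counts.sum(axis=0)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group[s] == group]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.group == other.group
        )


class OrthologMap:
    """Many-to-one map from duplicated frog genes to single human orthologs.

    The allotetraploid frog genome typically carries two homeologous copies
    (alloalleles, suffixed ``.L``/``.S``) of each ancestral gene; both map
    to the same human gene.
    """

    def __init__(self, frog_to_human: Mapping[str, str]):
        self._map = dict(frog_to_human)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, frog_gene_id: str) -> bool:
        return frog_gene_id in self._map

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OrthologMap) and self._map == other._map

    def human_for(self, frog_gene_id: str) -> Optional[str]:
        return self._map.get(frog_gene_id)

    def items(self):
        return self._map.items()

    @property
    def frog_gene_ids(self) -> list[str]:
        return list(self._map)

    @property
    def human_gene_ids(self) -> list[str]:
        return sorted(set(self._map.values()))

    def frogs_for(self, human_gene_id: str) -> list[str]:
        return sorted(f for f, h in self._map.items() if h == human_gene_id)


class WeightedNetwork:
    """Undirected functional gene network with positive confidence weights.

    Edge weights are log-likelihood scores (LLS): the log odds that two
    genes share function given the evidence behind the link.  Backed by a
    :class:`networkx.Graph`; no self-loops, no duplicate edges.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, w in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if w <= 0:
                raise ValueError(f"edge ({a!r}, {b!r}): weight must be > 0, got {w}")
            if g.has_edge(a, b):
                raise ValueError(f"duplicate edge ({a!r}, {b!r})")
            g.add_edge(a, b, weight=float(w))
        self.graph = g

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "WeightedNetwork":
        net = cls.__new__(cls)
        net.graph = graph
        return net

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, data["weight"]))
        return sorted(out)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WeightedNetwork) and self.edges() == other.edges() and set(
            self.graph.nodes
        ) == set(other.graph.nodes)

    def induced(self, node_ids: Iterable[str]) -> "WeightedNetwork":
        keep = set(node_ids) & set(self.graph.nodes)
        return WeightedNetwork.from_graph(self.graph.subgraph(keep).copy())


class GeneSetCollection:
    """Named gene sets (reference proteome lists, GO-like term sets)."""

    def __init__(self, sets: Mapping[str, Iterable[str]], descriptions: Optional[Mapping[str, str]] = None):
        self._sets = {name: frozenset(members) for name, members in sets.items()}
        self._desc = {name: (descriptions or {}).get(name, "") for name in self._sets}

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self._sets == other._sets

    def description(self, name: str) -> str:
        return self._desc[name]

    def items(self):
        return self._sets.items()


@dataclass(frozen=True)
class Module:
    """An (overlapping) cohesive cluster of network genes."""

    member_ids: frozenset[str]
    cohesiveness: float
    seed_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("module must have at least one member")
        if not (0.0 <= self.cohesiveness <= 1.0):
            raise ValueError(f"cohesiveness must be in [0, 1], got {self.cohesiveness}")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside every synthetic input bundle."""

    true_de_genes: set[str] = field(default_factory=set)
    true_bound_genes: set[str] = field(default_factory=set)
    planted_fold_changes: dict[str, float] = field(default_factory=dict)
    nb_dispersion: float = 0.0
    planted_modules: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def true_target_genes(self) -> set[str]:
        return self.true_de_genes & self.true_bound_genes

    def validate(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for mod in self.planted_modules:
            if len(mod["known"]) + len(mod["uncharacterized"]) < 3:
                raise ValueError("every planted module must have >= 3 members")

    def to_json(self, path) -> None:
        self.validate()
        payload = {
            "true_de_genes": sorted(self.true_de_genes),
            "true_bound_genes": sorted(self.true_bound_genes),
            "true_target_genes": sorted(self.true_target_genes),
            "planted_fold_changes": {g: self.planted_fold_changes[g] for g in sorted(self.planted_fold_changes)},
            "nb_dispersion": self.nb_dispersion,
            "planted_modules": [
                {"known": sorted(m["known"]), "uncharacterized": sorted(m["uncharacterized"])}
                for m in self.planted_modules
            ],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        rec = cls(
            true_de_genes=set(payload["true_de_genes"]),
            true_bound_genes=set(payload["true_bound_genes"]),
            planted_fold_changes=dict(payload["planted_fold_changes"]),
            nb_dispersion=float(payload["nb_dispersion"]),
            planted_modules=[
                {"known": set(m["known"]), "uncharacterized": set(m["uncharacterized"])}
                for m in payload["planted_modules"]
            ],
            seed=int(payload["seed"]),
        )
        rec.validate()
        return rec
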