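"""Causal DAG utilities: d-separation and backdoor adjustment sets.

The road-mortality risk analysis estimates the direct effect of each
road/landscape feature on mortality by conditioning on a backdoor
adjustment set identified from a hypothesized causal DAG.  The default DAG
(reconstructed from the study-system's structural model; shipped as an
editable edge list in ``data/default_dag.csv``) links distance to city
center to population density, forest cover, fragmentation and morph
abundance; population density to building density, speed limits and
traffic; building density and forest cover to above-ground crossings;
fragmentation to habitat split; and the five road-level factors to
mortality risk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import pandas as pd

__all__ = [
    "CausalDAG",
    "d_separated",
    "backdoor_sets",
    "default_risk_dag",
    "EXPOSURES",
    "OUTCOME",
]

EXPOSURES = ("speed", "traffic", "crossings", "habitat_split")
OUTCOME = "mortality"


@dataclass(frozen=True)
class CausalDAG:
    """Directed acyclic graph over named nodes."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("graph contains a directed cycle")

    @classmethod
    def from_edges(cls, edges, extra_nodes=()) -> "CausalDAG":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        g.add_nodes_from(extra_nodes)
        return cls(g)

    @classmethod
    def from_csv(cls, path) -> "CausalDAG":
        frame = pd.read_csv(path)
        missing = {"parent", "child"} - set(frame.columns)
        if missing:
            raise ValueError(f"DAG file is missing columns {sorted(missing)}")
        return cls.from_edges(frame[["parent", "child"]].itertuples(index=False, name=None))

    def to_csv(self, path) -> None:
        pd.DataFrame(sorted(self.graph.edges), columns=["parent", "child"]).to_csv(
            path, index=False)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    def require_nodes(self, *node_sets) -> None:
        unknown = set().union(*map(set, node_sets)) - set(self.graph.nodes)
        if unknown:
            raise KeyError(f"unknown DAG nodes {sorted(unknown)}")


def default_risk_dag() -> CausalDAG:
    """The shipped (reconstructed) mortality-risk DAG."""
    path = resources.files("roadcline").joinpath("data/default_dag.csv")
    with resources.as_file(path) as p:
        return CausalDAG.from_csv(p)


def d_separated(dag: CausalDAG, x, y, z=()) -> bool:
    """True iff every path between node sets X and Y is blocked by Z."""
    x, y, z = set(x), set(y), set(z)
    dag.require_nodes(x, y, z)
    if (x & y) or (x & z) or (y & z):
        raise ValueError("X, Y and Z must be disjoint")
    return nx.is_d_separator(dag.graph, x, y, z)


def backdoor_sets(dag: CausalDAG, exposure: str, outcome: str) -> list[frozenset]:
    """All minimal backdoor adjustment sets for exposure -> outcome.

    A candidate Z (non-descendants of the exposure, excluding both nodes) is
    valid when it d-separates exposure from outcome in the graph with the
    exposure's outgoing edges removed; minimal sets contain no valid proper
    subset.  Returned sorted by size then lexicographically.
    """
    dag.require_nodes({exposure, outcome})
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    g = dag.graph
    backdoor_graph = CausalDAG(nx.restricted_view(g, [], list(g.out_edges(exposure))))
    allowed = sorted(set(g.nodes) - nx.descendants(g, exposure) - {exposure, outcome})

    minimal: list[frozenset] = []
    for size in range(len(allowed) + 1):
        for combo in itertools.combinations(allowed, size):
            z = frozenset(combo)
            if any(kept <= z for kept in minimal):
                continue
            if d_separated(backdoor_graph, {exposure}, {outcome}, z):
                minimal.append(z)
    return sorted(minimal, key=lambda s: (len(s), tuple(sorted(s))))
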