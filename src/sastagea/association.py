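"""Hypergeometric overlap testing and per-phase tissue association networks.

Two directional gene sets drawn from a common universe of N genes, of sizes M
and K with x genes in common, are tested against the hypergeometric null:
the p-value is P(X >= x) for X ~ Hypergeometric(N, M, K), i.e. one minus the
probability that a random K-subset hits the M-set in 0, 1, ..., x-1 genes.

Within one age phase, every pair of nodes from different tissues is tested in
all four directional combinations (up-up, down-down, up-down, down-up).  Pairs
with p strictly below the configured threshold become edges: *synchronous*
when the directions agree (genes rising, or falling, together in both
tissues), *asynchronous* when they disagree.  Nodes left without any edge are
the *stochastic* tissues of that phase — their changed genes show no
significant spatial association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .change_detection import PhaseChangeSet

__all__ = [
    "OverlapTest",
    "AssociationEdge",
    "AssociationNetwork",
    "NetworkSummary",
    "hypergeometric_tail_p",
    "test_pair",
    "build_phase_network",
    "summarize_network",
    "edge_table",
    "write_graphml",
]


def hypergeometric_tail_p(N: int, M: int, K: int, x: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts the overlap between a fixed M-subset and a uniformly random
    K-subset of an N-element universe.  Evaluated through the survival
    function (stable for N up to at least 1e5); always in (0, 1] for valid
    parameters (P(X >= 0) = 1 exactly).
    """
    N, M, K, x = int(N), int(M), int(K), int(x)
    if N < 0 or M < 0 or K < 0 or x < 0:
        raise ValueError("all parameters must be non-negative")
    if M > N or K > N:
        raise ValueError(f"set sizes M={M}, K={K} exceed universe N={N}")
    if x > min(M, K):
        raise ValueError(f"overlap x={x} exceeds min(M, K)={min(M, K)}")
    if x == 0:
        return 1.0
    p = float(hypergeom.sf(x - 1, N, M, K))
    # guard against underflow to exactly 0 for extreme overlaps
    return max(p, 5e-324)


@dataclass(frozen=True)
class OverlapTest:
    """One (N, M, K, x) hypergeometric contrast and its tail p-value."""

    N: int
    M: int
    K: int
    x: int
    p: float

    @classmethod
    def from_sets(cls, a: frozenset, b: frozenset, N: int) -> "OverlapTest":
        M, K, x = len(a), len(b), len(a & b)
        return cls(N=N, M=M, K=K, x=x, p=hypergeometric_tail_p(N, M, K, x))


def test_pair(a: PhaseChangeSet, b: PhaseChangeSet, N: int) -> OverlapTest:
    """Overlap test between two directional gene sets on a shared universe."""
    if a is b or (a.node_name == b.node_name):
        raise ValueError("a node is never tested against itself")
    return OverlapTest.from_sets(a.genes, b.genes, N)


def _relation(a: PhaseChangeSet, b: PhaseChangeSet) -> str:
    return "synchronous" if a.direction == b.direction else "asynchronous"


@dataclass(frozen=True)
class AssociationEdge:
    node_a: PhaseChangeSet
    node_b: PhaseChangeSet
    relation: str  # synchronous | asynchronous
    test: OverlapTest
    edge_class: str | None = None  # set in 4D networks


@dataclass
class AssociationNetwork:
    """Nodes, significant edges, and the testing conditions that produced them."""

    phase_scope: str  # a phase label, or "4D"
    nodes: list[PhaseChangeSet]
    edges: list[AssociationEdge]
    threshold: float
    universe_size: int
    #: node-name pairs actually tested (empty sets are never tested)
    tested_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def connected_node_names(self) -> set[str]:
        names: set[str] = set()
        for e in self.edges:
            names.add(e.node_a.node_name)
            names.add(e.node_b.node_name)
        return names

    @property
    def stochastic_node_names(self) -> set[str]:
        """Nodes with no significant edge at the threshold."""
        return {n.node_name for n in self.nodes} - self.connected_node_names


def build_phase_network(
    sets: list[PhaseChangeSet], N: int, threshold: float = 0.005
) -> AssociationNetwork:
    """Test all cross-tissue node pairs of one age phase and keep p < threshold.

    All four directional combinations per tissue pair are tested.  The up and
    down sets of the same tissue are disjoint by construction and are not
    tested.  Nodes with empty gene sets are carried but never tested, so they
    end up isolated (stochastic).  The threshold comparison is strict.
    """
    windows = {s.phase.window for s in sets}
    if len(windows) > 1:
        raise ValueError(f"sets span multiple phase windows: {sorted(windows)}")
    names = [s.node_name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate node names in input sets")

    edges: list[AssociationEdge] = []
    tested: list[tuple[str, str]] = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            if a.code == b.code:  # same tissue: up vs down, structurally disjoint
                continue
            if not a.genes or not b.genes:
                continue
            t = test_pair(a, b, N)
            tested.append((a.node_name, b.node_name))
            if t.p < threshold:
                edges.append(AssociationEdge(a, b, _relation(a, b), t))
    scope = sets[0].phase.label if sets else "empty"
    return AssociationNetwork(
        phase_scope=scope, nodes=list(sets), edges=edges,
        threshold=threshold, universe_size=N, tested_pairs=tested,
    )


@dataclass(frozen=True)
class NetworkSummary:
    phase_scope: str
    n_nodes: int
    synchronous_edges: int
    asynchronous_edges: int
    connected_nodes: int
    stochastic_nodes: int

    @property
    def n_edges(self) -> int:
        return self.synchronous_edges + self.asynchronous_edges


def summarize_network(net: AssociationNetwork) -> NetworkSummary:
    """Edge and node counts behind the synchrony/asynchrony/stochasticity reading."""
    sync = sum(1 for e in net.edges if e.relation == "synchronous")
    asyn = sum(1 for e in net.edges if e.relation == "asynchronous")
    connected = len(net.connected_node_names)
    return NetworkSummary(
        phase_scope=net.phase_scope,
        n_nodes=len(net.nodes),
        synchronous_edges=sync,
        asynchronous_edges=asyn,
        connected_nodes=connected,
        stochastic_nodes=len(net.nodes) - connected,
    )


def edge_table(net: AssociationNetwork) -> pd.DataFrame:
    """Edge list as a DataFrame (TSV-ready): node_a, node_b, relation, N, M, K, x, p."""
    rows = []
    for e in net.edges:
        row = {
            "node_a": e.node_a.node_name,
            "node_b": e.node_b.node_name,
            "relation": e.relation,
            "N": e.test.N,
            "M": e.test.M,
            "K": e.test.K,
            "x": e.test.x,
            "p": e.test.p,
        }
        if e.edge_class is not None:
            row["edge_class"] = e.edge_class
        rows.append(row)
    cols = ["node_a", "node_b", "relation", "N", "M", "K", "x", "p"]
    if any(e.edge_class is not None for e in net.edges):
        cols.append("edge_class")
    return pd.DataFrame(rows, columns=cols)


def to_networkx(net: AssociationNetwork) -> nx.Graph:
    g = nx.Graph()
    g.graph["phase_scope"] = net.phase_scope
    g.graph["threshold"] = net.threshold
    g.graph["universe_N"] = net.universe_size
    for n in net.nodes:
        g.add_node(
            n.node_name,
            tissue=n.code,
            phase=n.phase.label,
            direction=n.direction,
            size=len(n.genes),
        )
    for e in net.edges:
        attrs = {"relation": e.relation, "p": e.test.p, "overlap": e.test.x}
        if e.edge_class is not None:
            attrs["edge_class"] = e.edge_class
        g.add_edge(e.node_a.node_name, e.node_b.node_name, **attrs)
    return g


def write_graphml(net: AssociationNetwork, path: str | Path) -> None:
    """GraphML export for external viewers (node colour = direction etc.)."""
    nx.write_graphml(to_networkx(net), str(path))
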