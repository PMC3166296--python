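"""The global four-dimensional (space x time) association network.

Where the per-phase networks compare tissues within one temporal window, the
4D network tests *every* pair of directional change sets across all tissues
and all phases.  Edges therefore fall into three classes:

- ``same-tissue cross-phase`` — genes altered in one tissue recurring in a
  different phase of the same tissue (temporal association);
- ``cross-tissue same-phase`` — the per-phase spatial associations;
- ``cross-tissue cross-phase`` — genes recurring at another time AND place.

Restricting 4D edges to same-phase pairs reproduces the per-phase networks
exactly at the same threshold.  From a node's incident edge classes the four
behavioural categories are derived: nodes whose genes recur across time and
space, nodes with same-phase (and possibly temporal) associations only,
nodes associated only within their own tissue, and fully isolated nodes whose
alteration is specific to one time and place.
"""

from __future__ import annotations

import pandas as pd

from .association import (
    AssociationEdge,
    AssociationNetwork,
    _relation,
    test_pair,
)
from .change_detection import PhaseChangeSet

__all__ = ["build_4d_network", "classify_4d_node", "node_category_table", "EDGE_CLASSES"]

EDGE_CLASSES = (
    "same-tissue cross-phase",
    "cross-tissue same-phase",
    "cross-tissue cross-phase",
)

NODE_CATEGORIES = (
    "temporal-associated",
    "spatio-temporal-associated",
    "tissue-specific-temporal",
    "specific",
)


def _edge_class(a: PhaseChangeSet, b: PhaseChangeSet) -> str:
    same_tissue = a.code == b.code
    same_phase = a.phase.window == b.phase.window
    if same_tissue:
        return "same-tissue cross-phase"
    return "cross-tissue same-phase" if same_phase else "cross-tissue cross-phase"


def build_4d_network(
    sets: list[PhaseChangeSet], N: int, threshold: float = 0.0001
) -> AssociationNetwork:
    """Test all unordered pairs of distinct nodes across tissues and phases.

    The up and down sets of the same tissue-phase are excluded (their overlap
    is structurally zero, a forced p = 1).  Empty sets are carried untested.
    Each significant edge carries its tissue/phase relation class.
    """
    names = [s.node_name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate node names in input sets")
    edges: list[AssociationEdge] = []
    tested: list[tuple[str, str]] = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            if a.code == b.code and a.phase.window == b.phase.window:
                continue  # up vs down of one node: disjoint by construction
            if not a.genes or not b.genes:
                continue
            t = test_pair(a, b, N)
            tested.append((a.node_name, b.node_name))
            if t.p < threshold:
                edges.append(
                    AssociationEdge(a, b, _relation(a, b), t, edge_class=_edge_class(a, b))
                )
    return AssociationNetwork(
        phase_scope="4D", nodes=list(sets), edges=edges,
        threshold=threshold, universe_size=N, tested_pairs=tested,
    )


def classify_4d_node(net: AssociationNetwork, node: PhaseChangeSet | str) -> str:
    """Behavioural category of a node from its incident 4D edge classes.

    - ``specific``: no edge at all — the alteration occurs at exactly one
      time and place.
    - ``tissue-specific-temporal``: only same-tissue edges — the genes recur
      over time but never in another tissue.
    - ``spatio-temporal-associated``: edges in another tissue at another
      phase (cross-tissue cross-phase), with or without other classes.
    - ``temporal-associated``: the remaining connected nodes — associated
      with other tissues within the same phase and/or with own-tissue phases,
      but never across both tissue and phase simultaneously.
    """
    name = node if isinstance(node, str) else node.node_name
    if name not in {n.node_name for n in net.nodes}:
        raise KeyError(f"node {name!r} not in network")
    classes = {
        e.edge_class
        for e in net.edges
        if name in (e.node_a.node_name, e.node_b.node_name)
    }
    if not classes:
        return "specific"
    if "cross-tissue cross-phase" in classes:
        return "spatio-temporal-associated"
    if classes == {"same-tissue cross-phase"}:
        return "tissue-specific-temporal"
    if "same-tissue cross-phase" in classes and "cross-tissue same-phase" in classes:
        return "spatio-temporal-associated"
    return "temporal-associated"


def node_category_table(net: AssociationNetwork) -> pd.DataFrame:
    """Per-node category assignments as a DataFrame (TSV-ready)."""
    rows = [
        {
            "node": n.node_name,
            "tissue": n.code,
            "phase": n.phase.label,
            "direction": n.direction,
            "size": len(n.genes),
            "category": classify_4d_node(net, n),
        }
        for n in net.nodes
    ]
    return pd.DataFrame(rows, columns=["node", "tissue", "phase", "direction", "size", "category"])
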