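"""Disease-disease networks from shared association bands.

Once several disease queries have each been categorized against the same
factor universe, two diseases are linked by the factors they share: the
edge weight is the Jaccard overlap of their associated-factor sets (either
established only, or established ∪ potential — the latter is the default,
since candidate hypotheses live in the weakly-positive region). Export is
GraphML (via networkx) and a plain edge-list TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .disease_model import AssociationCategories
from .errors import InputError, UndefinedScoreError

__all__ = ["DiseaseNetwork", "edge_weight", "build_network",
           "write_graphml", "write_edgelist", "EDGE_RULES"]

EDGE_RULES = ("jaccard_established", "jaccard_assoc")


def _band_set(bands: AssociationCategories, rule: str) -> set[str]:
    if rule == "jaccard_established":
        return set(bands.established)
    if rule == "jaccard_assoc":
        return set(bands.established) | set(bands.potential)
    raise InputError(f"unknown edge rule {rule!r}; choose from {EDGE_RULES}")


def edge_weight(
    bands_a: AssociationCategories,
    bands_b: AssociationCategories,
    rule: str = "jaccard_assoc",
) -> tuple[float, set[str]]:
    """Jaccard overlap of the two diseases' associated-factor sets.

    Returns (weight, shared factor set). Undefined (raised) when both sets
    are empty — the edge is then omitted, never weighted 0.
    """
    if bands_a.all_factors() != bands_b.all_factors():
        raise InputError("categorizations cover different factor universes")
    set_a, set_b = _band_set(bands_a, rule), _band_set(bands_b, rule)
    union = set_a | set_b
    if not union:
        raise UndefinedScoreError(
            "both factor sets empty; edge weight undefined"
        )
    shared = set_a & set_b
    return len(shared) / len(union), shared


@dataclass
class DiseaseNetwork:
    """Undirected weighted graph over disease queries."""

    nodes: list[str]
    # (node_a, node_b) with node_a < node_b -> (weight, shared factors)
    edges: dict[tuple[str, str], tuple[float, frozenset[str]]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        for (a, b), (w, _) in self.edges.items():
            if a == b:
                raise InputError(f"self-edge on {a!r}")
            if not (0.0 <= w <= 1.0):
                raise InputError(f"edge weight {w} outside [0, 1]")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), (w, shared) in sorted(self.edges.items()):
            g.add_edge(a, b, weight=w, shared_factors=";".join(sorted(shared)))
        return g


def build_network(
    categorized: Mapping[str, AssociationCategories],
    rule: str = "jaccard_assoc",
    min_weight: float = 0.0,
) -> DiseaseNetwork:
    """All pairwise edges with weight >= min_weight.

    Nodes without qualifying edges are retained (absence of overlap is
    itself a finding). Output ordering is deterministic: nodes sorted,
    edge keys sorted.
    """
    if len(categorized) < 2:
        raise InputError("need at least 2 categorized queries to build a network")
    nodes = sorted(categorized)
    edges: dict[tuple[str, str], tuple[float, frozenset[str]]] = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            try:
                w, shared = edge_weight(categorized[a], categorized[b], rule)
            except UndefinedScoreError:
                continue
            if w >= min_weight:
                edges[(a, b)] = (w, frozenset(shared))
    return DiseaseNetwork(nodes=nodes, edges=edges)


def write_graphml(network: DiseaseNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), str(path))


def write_edgelist(network: DiseaseNetwork, path: str | Path) -> None:
    """TSV: node_a, node_b, weight, shared factors (semicolon-joined)."""
    lines = ["# node_a\tnode_b\tweight\tshared_factors"]
    for (a, b), (w, shared) in sorted(network.edges.items()):
        lines.append(f"{a}\t{b}\t{w:.6f}\t{';'.join(sorted(shared))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
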