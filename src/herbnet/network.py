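"""Bipartite compound-target and target-function networks and their degree reports.

Networks carry typed nodes (herb / compound / target / function_module) on a
networkx graph; edges only ever join distinct classes. Degree statistics for a
class pair divide the number of edges of that pair by the node count of each
class, which is the convention behind summary figures like "average degree of
50.4 per compound and 89.2 per target".
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .chem import FormulaTable
from .errors import IntegrityError, ValidationError
from .fishing import CompoundTargetMap
from .util import round_half_up

log = logging.getLogger(__name__)

NODE_CLASSES = ("herb", "compound", "target", "function_module")


class BipartiteNetwork:
    """Typed-node undirected network; edges must join two different classes."""

    def __init__(self):
        self.graph = nx.Graph()

    def add_node(self, node_id: str, node_class: str) -> None:
        if node_class not in NODE_CLASSES:
            raise ValidationError(f"unknown node class {node_class!r}")
        existing = self.graph.nodes.get(node_id)
        if existing and existing["node_class"] != node_class:
            raise IntegrityError(f"node {node_id!r} already present with another class")
        self.graph.add_node(node_id, node_class=node_class)

    def add_edge(self, u: str, v: str, score: float | None = None) -> None:
        if u == v:
            raise IntegrityError(f"self-edge on {u!r}")
        for n in (u, v):
            if n not in self.graph:
                raise IntegrityError(f"edge endpoint {n!r} is not a node")
        if self.graph.nodes[u]["node_class"] == self.graph.nodes[v]["node_class"]:
            raise IntegrityError(f"edge {u!r}-{v!r} joins two {self.node_class(u)!r} nodes")
        if self.graph.has_edge(u, v):
            raise IntegrityError(f"duplicate edge {u!r}-{v!r}")
        attrs = {} if score is None else {"score": float(score)}
        self.graph.add_edge(u, v, **attrs)

    def node_class(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_class"]

    def nodes_of_class(self, node_class: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["node_class"] == node_class]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            counts[d["node_class"]] = counts.get(d["node_class"], 0) + 1
        return counts

    def edges_between(self, class_a: str, class_b: str) -> list[tuple[str, str]]:
        pair = {class_a, class_b}
        return [
            (u, v) for u, v in self.graph.edges
            if {self.node_class(u), self.node_class(v)} == pair
        ]

    # -- export -------------------------------------------------------------
    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, d["node_class"]) for n, d in self.graph.nodes(data=True)],
            columns=["id", "class"],
        )

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d.get("score", float("nan"))) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "score"])

    def write_tables(self, prefix: str | Path) -> tuple[Path, Path]:
        """Cytoscape-loadable node and edge TSVs at <prefix>_nodes/_edges.tsv."""
        prefix = Path(prefix)
        node_path = prefix.with_name(prefix.name + "_nodes.tsv")
        edge_path = prefix.with_name(prefix.name + "_edges.tsv")
        self.node_table().to_csv(node_path, sep="\t", index=False)
        self.edge_table().to_csv(edge_path, sep="\t", index=False, float_format="%.4f")
        return node_path, edge_path

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


@dataclass(frozen=True)
class DegreeReport:
    """Degree summary for one edge class of a bipartite network."""

    edge_class: tuple[str, str]
    n_edges: int
    class_node_counts: dict[str, int]
    mean_degree: dict[str, float]  # rounded for reporting (half-up)
    degree_table: pd.DataFrame  # columns id, class, degree; degree descending


# ---------------------------------------------------------------------------
# Builders

def build_ct_network(formula: FormulaTable, ctmap: CompoundTargetMap) -> BipartiteNetwork:
    """Herb + compound + target network from formula membership and associations.

    Only compounds with at least one association become nodes; herb-compound
    membership edges are added alongside the scored compound-target edges.
    """
    net = BipartiteNetwork()
    for herb in formula.herb_codes:
        net.add_node(herb, "herb")
    compounds = sorted(ctmap.compound_ids)
    for cid in compounds:
        if cid not in formula:
            raise IntegrityError(f"compound {cid!r} has associations but no herb in formula")
        net.add_node(cid, "compound")
        net.add_edge(formula.herb_of(cid), cid)
    for t in sorted(ctmap.predicted_targets):
        net.add_node(t, "target")
    for c, t, s in ctmap.associations:
        net.add_edge(c, t, score=s)
    return net


def degree_stats(
    net: BipartiteNetwork,
    edge_class: tuple[str, str] = ("compound", "target"),
    decimals: int = 1,
) -> DegreeReport:
    """Mean degree per class (edges of the class pair / class node count)."""
    class_a, class_b = edge_class
    counts = net.class_counts()
    for c in edge_class:
        if counts.get(c, 0) == 0:
            raise ValidationError(f"network has no nodes of class {c!r}")
    edges = net.edges_between(class_a, class_b)
    deg: dict[str, int] = {n: 0 for c in edge_class for n in net.nodes_of_class(c)}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    table = pd.DataFrame(
        [(n, net.node_class(n), d) for n, d in deg.items()],
        columns=["id", "class", "degree"],
    ).sort_values(["degree", "id"], ascending=[False, True], ignore_index=True)
    mean = {
        c: round_half_up(len(edges) / counts[c], decimals) if counts[c] else 0.0
        for c in edge_class
    }
    return DegreeReport(
        edge_class=edge_class,
        n_edges=len(edges),
        class_node_counts={c: counts[c] for c in edge_class},
        mean_degree=mean,
        degree_table=table,
    )


def extract_subnetwork(net: BipartiteNetwork, node_ids: Iterable[str]) -> BipartiteNetwork:
    """Induced subgraph on the chosen nodes plus their target-class neighbours."""
    node_ids = list(node_ids)
    for n in node_ids:
        if n not in net.graph:
            raise ValidationError(f"unknown node id {n!r}")
    keep = set(node_ids)
    for n in node_ids:
        keep.update(v for v in net.graph.neighbors(n) if net.node_class(v) == "target")
    sub = BipartiteNetwork()
    for n in sorted(keep):
        sub.add_node(n, net.node_class(n))
    for u, v, d in net.graph.edges(data=True):
        if u in keep and v in keep:
            sub.add_edge(u, v, score=d.get("score"))
    return sub


def build_tf_network(
    targets: Iterable[str], module_annotation: Mapping[str, Iterable[str]]
) -> BipartiteNetwork:
    """Target-function network: one edge per (target, functional module) pair.

    Targets absent from the annotation are dropped with a logged count.
    """
    if not module_annotation:
        raise ValidationError("module annotation is empty")
    targets = sorted(set(targets))
    annotated = [t for t in targets if module_annotation.get(t)]
    dropped = len(targets) - len(annotated)
    if dropped:
        log.info("build_tf_network: %d unannotated target(s) dropped", dropped)
    net = BipartiteNetwork()
    modules = sorted({m for t in annotated for m in module_annotation[t]})
    for t in annotated:
        net.add_node(t, "target")
    for m in modules:
        net.add_node(m, "function_module")
    for t in annotated:
        for m in sorted(set(module_annotation[t])):
            net.add_edge(t, m)
    return net


def mean_modules_per_target(net: BipartiteNetwork, decimals: int = 2) -> float:
    """Edges divided by annotated target count, rounded half-up."""
    n_targets = len(net.nodes_of_class("target"))
    if n_targets == 0:
        raise ValidationError("network has no target nodes")
    return round_half_up(net.n_edges / n_targets, decimals)
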