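"""The hypothesis DSL: graphs of observed/latent nodes and typed edges.

A model is a directed graph whose nodes are cohort variables or latent
factors and whose edges are regressions (``~``), factor loadings (``=~``) or
covariances (``~~``).  Graphs are built from a JSON document, validated
against a cohort, and serialized to a canonical structural-equation text in
the lavaan syntax family (``Y ~ X``, ``F =~ I1 + I2``, ``a ~~ b``) for
interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .cohort import Cohort

REGRESSION = "regression"
LOADING = "loading"
COVARIANCE = "covariance"
_EDGE_TYPES = (REGRESSION, LOADING, COVARIANCE)


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class Node:
    id: str
    kind: str = "observed"  # observed | latent
    variable: str | None = None  # cohort variable id; defaults to node id

    def __post_init__(self):
        if self.kind not in ("observed", "latent"):
            raise GraphError(f"node {self.id!r}: kind must be observed or latent")

    @property
    def var_id(self) -> str:
        return self.variable or self.id


@dataclass(frozen=True)
class Edge:
    src: str
    dst: str
    type: str = REGRESSION
    fixed_value: float | None = None

    def __post_init__(self):
        if self.type not in _EDGE_TYPES:
            raise GraphError(f"edge {self.src}->{self.dst}: unknown type {self.type!r}")

    def key(self) -> tuple:
        if self.type == COVARIANCE:  # undirected
            return (COVARIANCE,) + tuple(sorted((self.src, self.dst)))
        return (self.type, self.src, self.dst)


class ModelGraph:
    """Validated hypothesis graph (may contain cycles)."""

    def __init__(self, nodes: Iterable[Node], edges: Iterable[Edge], name: str = "model",
                 derived: Sequence[Mapping] = (), auto_covary_exogenous: bool = True):
        self.name = name
        self.nodes: dict[str, Node] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise GraphError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        self.edges: list[Edge] = []
        seen: set[tuple] = set()
        for edge in edges:
            for end in (edge.src, edge.dst):
                if end not in self.nodes:
                    raise GraphError(f"edge endpoint {end!r} is not a node")
            if edge.key() in seen:
                raise GraphError(f"duplicate edge {edge.src!r}->{edge.dst!r} ({edge.type})")
            seen.add(edge.key())
            if edge.type == LOADING:
                if self.nodes[edge.src].kind != "latent":
                    raise GraphError(f"loading {edge.src!r}=~{edge.dst!r}: src must be latent")
            self.edges.append(edge)
        self.derived = list(derived)
        self.auto_covary_exogenous = auto_covary_exogenous
        orphans = [
            n.id for n in self.nodes.values()
            if n.kind == "latent" and not self.loadings(n.id)
        ]
        if orphans:
            raise GraphError(f"latent node(s) without indicators: {orphans}")

    # -- views ---------------------------------------------------------------

    def node_order(self) -> list[str]:
        """Canonical order: insertion order (dict preserves it)."""
        return list(self.nodes)

    def regressions(self) -> list[Edge]:
        return [e for e in self.edges if e.type == REGRESSION]

    def covariances(self) -> list[Edge]:
        return [e for e in self.edges if e.type == COVARIANCE]

    def loadings(self, latent: str | None = None) -> list[Edge]:
        out = [e for e in self.edges if e.type == LOADING]
        if latent is not None:
            out = [e for e in out if e.src == latent]
        return out

    def latent_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.kind == "latent"]

    def observed_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.kind == "observed"]

    def parents(self, node_id: str) -> list[str]:
        return [e.src for e in self.regressions() if e.dst == node_id]

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (e.src, e.dst) for e in self.edges if e.type in (REGRESSION, LOADING)
        )
        return g

    def is_recursive(self) -> bool:
        return nx.is_directed_acyclic_graph(self.directed_graph())

    # -- serialization -------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": [
                {"id": n.id, "kind": n.kind,
                 **({"variable": n.variable} if n.variable else {})}
                for n in self.nodes.values()
            ],
            "edges": [
                {"src": e.src, "dst": e.dst, "type": e.type,
                 **({"fixed_value": e.fixed_value} if e.fixed_value is not None else {})}
                for e in self.edges
            ],
            "derived": self.derived,
            "auto_covary_exogenous": self.auto_covary_exogenous,
        }


def build_graph(spec: Mapping | str) -> ModelGraph:
    """Build and validate a :class:`ModelGraph` from a JSON document or dict."""
    if isinstance(spec, str):
        spec = json.loads(spec)
    nodes = [Node(d["id"], d.get("kind", "observed"), d.get("variable"))
             for d in spec.get("nodes", ())]
    edges = [Edge(d["src"], d["dst"], d.get("type", REGRESSION), d.get("fixed_value"))
             for d in spec.get("edges", ())]
    return ModelGraph(
        nodes, edges,
        name=spec.get("name", "model"),
        derived=spec.get("derived", ()),
        auto_covary_exogenous=spec.get("auto_covary_exogenous", True),
    )


@dataclass
class ValidationReport:
    findings: list[dict] = field(default_factory=list)

    def add(self, level: str, code: str, message: str) -> None:
        self.findings.append({"level": level, "code": code, "message": message})

    @property
    def errors(self) -> list[dict]:
        return [f for f in self.findings if f["level"] == "error"]

    def ok(self) -> bool:
        return not self.errors


def validate_graph(graph: ModelGraph, cohort: Cohort | None = None) -> ValidationReport:
    """Structural and (optionally) data-resolution checks; side-effect free.

    Cycles are allowed but flagged (a cyclic path matrix must be stable to be
    estimable); survival nodes may only be regression sinks.
    """
    report = ValidationReport()
    report.add(
        "info", "recursive" if graph.is_recursive() else "nonrecursive",
        "model graph is acyclic" if graph.is_recursive()
        else "model graph contains cycles; estimation requires spectral radius < 1",
    )
    derived_ids = {d.get("id") for d in graph.derived}
    for node in graph.nodes.values():
        if node.kind != "observed":
            continue
        if cohort is not None:
            if node.var_id in cohort:
                var = cohort.variable(node.var_id)
                if var.dtype == "survival":
                    for e in graph.edges:
                        if e.src == node.id and e.type == REGRESSION:
                            report.add("error", "survival-source",
                                       f"survival node {node.id!r} may only be a sink")
                        if e.type == COVARIANCE and node.id in (e.src, e.dst):
                            report.add("error", "survival-covariance",
                                       f"survival node {node.id!r} cannot carry covariances")
            elif node.var_id not in derived_ids:
                report.add("error", "unresolved",
                           f"observed node {node.id!r} has no cohort variable {node.var_id!r}")
    return report


def to_model_text(graph: ModelGraph) -> str:
    """Canonical structural-equation text (one response per line).

    ``F =~ i1 + i2`` for factor definitions, ``y ~ x1 + x2`` for regressions,
    ``a ~~ b`` for covariances; deterministic ordering makes the export
    round-trippable.
    """
    lines = []
    for latent in graph.latent_ids():
        inds = [e.dst for e in graph.loadings(latent)]
        lines.append(f"{latent} =~ " + " + ".join(inds))
    responses = []
    for node_id in graph.node_order():
        srcs = graph.parents(node_id)
        if srcs:
            responses.append(f"{node_id} ~ " + " + ".join(srcs))
    lines.extend(responses)
    for e in graph.covariances():
        lines.append(f"{e.src} ~~ {e.dst}")
    return "\n".join(lines) + ("\n" if lines else "")


def from_model_text(text: str, name: str = "model") -> ModelGraph:
    """Parse the canonical text back into a graph (inverse of to_model_text)."""
    nodes: dict[str, Node] = {}
    edges: list[Edge] = []

    def ensure(node_id: str, kind: str = "observed") -> None:
        if node_id not in nodes or (kind == "latent" and nodes[node_id].kind != "latent"):
            nodes[node_id] = Node(node_id, kind)

    deferred: list[tuple[str, str, str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=~" in line:
            lhs, rhs = (s.strip() for s in line.split("=~", 1))
            ensure(lhs, "latent")
            for ind in (s.strip() for s in rhs.split("+")):
                ensure(ind)
                edges.append(Edge(lhs, ind, LOADING))
        elif "~~" in line:
            a, b = (s.strip() for s in line.split("~~", 1))
            deferred.append((a, b, COVARIANCE))
        elif "~" in line:
            lhs, rhs = (s.strip() for s in line.split("~", 1))
            for src in (s.strip() for s in rhs.split("+")):
                deferred.append((src, lhs, REGRESSION))
        else:
            raise GraphError(f"cannot parse model line: {raw!r}")
    for a, b, etype in deferred:
        ensure(a) if a not in nodes else None
        ensure(b) if b not in nodes else None
        edges.append(Edge(a, b, etype))
    return ModelGraph(nodes.values(), edges, name=name)
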