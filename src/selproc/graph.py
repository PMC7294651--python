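"""Time-indexed causal DAGs with epidemiological role annotations.

Nodes represent binary variables observed in discrete time windows
(``E1`` = exposure in window 1, ``D2`` = disease outcome in window 2, ...).
Every arrow is simultaneously a direct causal effect and a directed
selection process: the arrow ``C0 -> E1`` makes C-positive individuals
over-represented among the exposed. Boxed (``conditioned``) nodes mark
conditioning — by nature at the population level (survival, disease
incidence) or by design in a study.

Graph-theoretic work (acyclicity, ancestors, topological order) is
delegated to :mod:`networkx`; this module owns the domain semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import GraphError

__all__ = [
    "Role",
    "TimedNode",
    "Edge",
    "CausalGraph",
    "build_graph",
]

#: Admissible node roles.
ROLES = (
    "exposure",
    "outcome",
    "covariate",
    "unknown_cause",
    "selection",
    "side_effect",
)
Role = str


@dataclass(frozen=True)
class TimedNode:
    """A binary variable at a time window.

    Parameters
    ----------
    id : str
        Unique label, conventionally variable symbol + time index ("E1").
    variable : str
        Base symbol shared by repeated measurements ("E").
    time : int
        Non-negative ordinal time-window index. Indices order events;
        they carry no duration.
    role : str
        One of ``exposure, outcome, covariate, unknown_cause, selection,
        side_effect``. ``unknown_cause`` nodes are structurally ordinary;
        the flag only controls their visibility to estimators.
    conditioned : bool
        A "boxed" node: the population under study is restricted to one
        of its levels (conditioning by nature or by design).
    study_specific : bool
        The process creating this node's value arises from the study
        itself rather than from the underlying population.
    condition_value : int
        The retained level when the node is conditioned (default 1).
        Depletion-of-susceptibles conditions on the *absence* of an early
        outcome, i.e. ``condition_value=0``.
    """

    id: str
    variable: str
    time: int
    role: Role = "covariate"
    conditioned: bool = False
    study_specific: bool = False
    condition_value: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise GraphError(f"node {self.id!r}: unknown role {self.role!r}")
        if self.time < 0:
            raise GraphError(f"node {self.id!r}: negative time index {self.time}")
        if self.role == "selection" and not self.conditioned:
            raise GraphError(
                f"node {self.id!r}: role 'selection' requires conditioned=True"
            )
        if self.conditioned and self.role not in ("selection", "outcome"):
            # Only the boxed-outcome combination (depletion of susceptibles)
            # is admitted besides plain selection nodes.
            raise GraphError(
                f"node {self.id!r}: conditioning is only allowed on selection "
                f"or outcome nodes, not role {self.role!r}"
            )
        if self.condition_value not in (0, 1):
            raise GraphError(f"node {self.id!r}: condition_value must be 0 or 1")


@dataclass(frozen=True)
class Edge:
    """Directed arrow ``tail -> head`` between node ids."""

    tail: str
    head: str


def _node_sort_key(node: TimedNode) -> tuple:
    return (node.time, node.variable, node.id)


class CausalGraph:
    """A validated, time-respecting DAG of :class:`TimedNode` objects.

    Construction validates all structural invariants; instances are
    immutable in intent (mutate by building a new graph). Node order is
    canonical: sorted by ``(time, variable)``.
    """

    def __init__(self, nodes: Iterable[TimedNode], edges: Iterable[Edge]):
        nodes = list(nodes)
        edges = [e if isinstance(e, Edge) else Edge(*e) for e in edges]

        ids = [n.id for n in nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GraphError(f"duplicate node ids: {dupes}")
        vt = [(n.variable, n.time) for n in nodes]
        if len(set(vt)) != len(vt):
            dupes = sorted({p for p in vt if vt.count(p) > 1})
            raise GraphError(f"duplicate (variable, time) pairs: {dupes}")

        self._nodes: dict[str, TimedNode] = {
            n.id: n for n in sorted(nodes, key=_node_sort_key)
        }

        for role in ("exposure", "outcome"):
            variables = {n.variable for n in nodes if n.role == role}
            if len(variables) > 1:
                raise GraphError(
                    f"more than one {role} variable: {sorted(variables)} "
                    f"(multiple time indices of a single variable are allowed)"
                )

        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for e in edges:
            for end in (e.tail, e.head):
                if end not in self._nodes:
                    raise GraphError(f"edge ({e.tail}->{e.head}) references unknown node {end!r}")
            if e.tail == e.head:
                raise GraphError(f"self-edge on {e.tail!r}")
            t, h = self._nodes[e.tail], self._nodes[e.head]
            if t.time > h.time:
                raise GraphError(
                    f"backward-in-time edge {e.tail}(t={t.time}) -> {e.head}(t={h.time})"
                )
            if t.time == h.time:
                warnings.warn(
                    f"same-time-window edge {e.tail} -> {e.head} "
                    f"(simultaneous processes); permitted but check intent",
                    stacklevel=3,
                )
            g.add_edge(e.tail, e.head)

        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise GraphError(f"graph contains a cycle: {cycle}")

        self._g = g
        self._edges = sorted(
            (Edge(t, h) for t, h in g.edges), key=lambda e: (e.tail, e.head)
        )

    # -- accessors ---------------------------------------------------------

    @property
    def nodes(self) -> tuple[TimedNode, ...]:
        """Nodes in canonical (time, variable) order."""
        return tuple(self._nodes.values())

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(self._edges)

    def node(self, node_id: str) -> TimedNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise GraphError(f"unknown node {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def nodes_with_role(self, role: Role) -> tuple[TimedNode, ...]:
        return tuple(n for n in self.nodes if n.role == role)

    def conditioned_nodes(self) -> tuple[TimedNode, ...]:
        return tuple(n for n in self.nodes if n.conditioned)

    def resolve(self, name: str) -> str:
        """Resolve a node id or a bare variable symbol to a node id.

        A bare variable resolves only when exactly one node carries it.
        """
        if name in self._nodes:
            return name
        hits = [n.id for n in self.nodes if n.variable == name]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise GraphError(f"unknown node or variable {name!r}")
        raise GraphError(
            f"variable {name!r} is ambiguous ({hits}); use a node id"
        )

    # -- relations ---------------------------------------------------------

    def parents(self, node_id: str) -> set[str]:
        self.node(node_id)
        return set(self._g.predecessors(node_id))

    def children(self, node_id: str) -> set[str]:
        self.node(node_id)
        return set(self._g.successors(node_id))

    def ancestors(self, node_id: str) -> set[str]:
        self.node(node_id)
        return set(nx.ancestors(self._g, node_id))

    def descendants(self, node_id: str) -> set[str]:
        self.node(node_id)
        return set(nx.descendants(self._g, node_id))

    def colliders(self) -> set[str]:
        """Node ids with in-degree >= 2 — where directed selection
        mechanisms collide."""
        return {n for n in self._g if self._g.in_degree(n) >= 2}

    def topological_order(self) -> tuple[str, ...]:
        """Deterministic topological order, keyed by (time, variable)."""
        key = {n.id: _node_sort_key(n) for n in self.nodes}
        return tuple(nx.lexicographical_topological_sort(self._g, key=key.get))

    # -- serialization -----------------------------------------------------

    def to_spec(self) -> dict:
        """Structured-dict form; inverse of :func:`build_graph` up to
        canonical ordering."""
        nodes = []
        for n in self.nodes:
            d = {"id": n.id, "variable": n.variable, "time": n.time, "role": n.role}
            if n.conditioned:
                d["conditioned"] = True
            if n.study_specific:
                d["study_specific"] = True
            if n.condition_value != 1:
                d["condition_value"] = n.condition_value
            nodes.append(d)
        return {"nodes": nodes, "edges": [[e.tail, e.head] for e in self.edges]}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"CausalGraph({len(self)} nodes, {len(self._edges)} edges: "
            + ", ".join(f"{e.tail}->{e.head}" for e in self._edges)
            + ")"
        )


def build_graph(spec: Mapping) -> CausalGraph:
    """Build and validate a :class:`CausalGraph` from a structured spec.

    The spec dialect: ``{"nodes": [{"id", "variable", "time", "role",
    "conditioned", "study_specific"}, ...], "edges": [[tail, head], ...]}``.
    ``variable``/``time`` default to being parsed from the id (trailing
    digits = time); ``role`` defaults to "covariate"; booleans default
    false.
    """
    nodes = []
    for i, nd in enumerate(spec.get("nodes", [])):
        if isinstance(nd, TimedNode):
            nodes.append(nd)
            continue
        if "id" not in nd:
            raise GraphError(f"nodes[{i}]: missing 'id'")
        nid = str(nd["id"])
        variable = nd.get("variable")
        time = nd.get("time")
        if variable is None or time is None:
            sym = nid.rstrip("0123456789")
            digits = nid[len(sym):]
            if variable is None:
                variable = sym or nid
            if time is None:
                if not digits:
                    raise GraphError(
                        f"nodes[{i}] ({nid!r}): 'time' missing and not inferable from id"
                    )
                time = int(digits)
        nodes.append(
            TimedNode(
                id=nid,
                variable=str(variable),
                time=int(time),
                role=nd.get("role", "covariate"),
                conditioned=bool(nd.get("conditioned", False)),
                study_specific=bool(nd.get("study_specific", False)),
                condition_value=int(nd.get("condition_value", 1)),
            )
        )
    edges = [Edge(str(t), str(h)) for t, h in spec.get("edges", [])]
    return CausalGraph(nodes, edges)
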