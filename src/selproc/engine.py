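"""Binary structural causal models: exact enumeration, conditioning by
nature, expected-count cohorts and seeded ancestral sampling.

Every node of a :class:`~selproc.graph.CausalGraph` gets a conditional
Bernoulli table P(node=1 | parents). The joint law factorizes over the
DAG and is enumerated exactly over all 2^k configurations (k <= 20; all
builtin scenarios have k <= 6), so there is no inference approximation
anywhere: selection effects seen downstream are consequences of the
model, not of sampling noise. Monte-Carlo cohorts are available for
finite-sample work and are reproducible for a fixed seed
(numpy PCG64 via ``numpy.random.default_rng``).

"Conditioning by nature" — restriction of all downstream causal action
to the subpopulation selected by a boxed node (survivors, incident
cases) — is implemented by :func:`condition` on joint tables and
:func:`apply_selection` on cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptySelectionError, GraphError, SpecError, ZeroProbabilityError
from .graph import CausalGraph

__all__ = [
    "ConditionalTable",
    "StructuralModel",
    "JointTable",
    "Cohort",
    "enumerate_joint",
    "condition",
    "marginal",
    "prob",
    "expected_cohort",
    "sample_cohort",
    "apply_selection",
]

MAX_NODES = 20  # exact enumeration cap: 2^20 configurations


def _configs(k: int) -> np.ndarray:
    """All 0/1 configurations of k variables, first variable = most
    significant bit; shape (2**k, k)."""
    idx = np.arange(2**k, dtype=np.int64)
    return ((idx[:, None] >> np.arange(k - 1, -1, -1)) & 1).astype(np.int8)


@dataclass(frozen=True)
class ConditionalTable:
    """P(node = 1 | parent configuration), one probability per
    configuration of the parents in ``parent_order``."""

    node: str
    parent_order: tuple[str, ...]
    probabilities: Mapping[tuple[int, ...], float]

    def __post_init__(self) -> None:
        k = len(self.parent_order)
        expected = set(product((0, 1), repeat=k))
        got = set(self.probabilities)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise SpecError(
                f"needs one entry per parent configuration "
                f"(missing {missing}, unexpected {extra})",
                path=f"tables.{self.node}",
            )
        for cfg, p in self.probabilities.items():
            if not 0.0 <= float(p) <= 1.0:
                raise SpecError(
                    f"probability {p} for configuration {cfg} outside [0, 1]",
                    path=f"tables.{self.node}",
                )

    def p1(self, parent_values: tuple[int, ...]) -> float:
        return float(self.probabilities[tuple(parent_values)])


@dataclass(frozen=True)
class StructuralModel:
    """A CausalGraph plus one ConditionalTable per node and a cohort size N.

    ``parent_order`` of each table must equal the node's parents in the
    graph's canonical (time, variable) order.
    """

    graph: CausalGraph
    tables: Mapping[str, ConditionalTable]
    cohort_size: float = 1.0

    def __post_init__(self) -> None:
        if self.cohort_size < 0:
            raise SpecError("cohort_size must be non-negative", path="cohort_size")
        for n in self.graph.nodes:
            if n.id not in self.tables:
                raise SpecError(f"no conditional table for node", path=f"tables.{n.id}")
            table = self.tables[n.id]
            canonical = self.canonical_parents(n.id)
            if tuple(table.parent_order) != canonical:
                raise SpecError(
                    f"parent_order {table.parent_order} != canonical parents {canonical}",
                    path=f"tables.{n.id}.parents",
                )
        extra = set(self.tables) - set(self.graph.node_ids)
        if extra:
            raise SpecError(f"tables for unknown nodes {sorted(extra)}", path="tables")

    def canonical_parents(self, node_id: str) -> tuple[str, ...]:
        parents = self.graph.parents(node_id)
        return tuple(i for i in self.graph.node_ids if i in parents)

    def with_probability(self, node_id: str, assignment: Mapping[str, int] | None,
                         value: float) -> "StructuralModel":
        """Copy of the model with P(node=1 | configs matching assignment)
        replaced by ``value``. ``assignment`` may fix any subset of the
        node's parents; unmentioned parents are broadcast over."""
        node_id = self.graph.resolve(node_id)
        if not 0.0 <= value <= 1.0:
            raise SpecError(f"override probability {value} outside [0, 1]",
                            path=f"tables.{node_id}")
        table = self.tables[node_id]
        assignment = {self.graph.resolve(k): int(v) for k, v in (assignment or {}).items()}
        unknown = set(assignment) - set(table.parent_order)
        if unknown:
            raise SpecError(
                f"override mentions non-parents {sorted(unknown)} of {node_id}",
                path=f"tables.{node_id}",
            )
        probs = dict(table.probabilities)
        for cfg in probs:
            named = dict(zip(table.parent_order, cfg))
            if all(named[k] == v for k, v in assignment.items()):
                probs[cfg] = value
        tables = dict(self.tables)
        tables[node_id] = ConditionalTable(node_id, table.parent_order, probs)
        return replace(self, tables=tables)


@dataclass(frozen=True)
class JointTable:
    """Exact probability mass over all 2^k configurations of ``variables``
    (canonical order, first variable = most significant bit)."""

    variables: tuple[str, ...]
    mass: np.ndarray  # shape (2**k,)

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", mass)
        if mass.shape != (2 ** len(self.variables),):
            raise ValueError("mass length must be 2**len(variables)")
        if (mass < -1e-15).any():
            raise ValueError("negative probability mass")
        if abs(mass.sum() - 1.0) > 1e-12:
            raise ValueError(f"mass sums to {mass.sum()!r}, not 1")

    def configs(self) -> np.ndarray:
        return _configs(len(self.variables))

    def column(self, name: str) -> np.ndarray:
        return self.configs()[:, self.variables.index(name)]

    def _mask(self, assignment: Mapping[str, int]) -> np.ndarray:
        mask = np.ones(len(self.mass), dtype=bool)
        for name, value in assignment.items():
            if name not in self.variables:
                raise GraphError(f"unknown variable {name!r} in joint table")
            mask &= self.column(name) == int(value)
        return mask

    def as_dict(self) -> dict[tuple[int, ...], float]:
        return {tuple(cfg): float(m) for cfg, m in zip(self.configs(), self.mass)}


def enumerate_joint(model: StructuralModel) -> JointTable:
    """Exact joint distribution: the product of the conditional tables
    over every configuration. No sampling."""
    order = model.graph.node_ids
    k = len(order)
    if k > MAX_NODES:
        raise SpecError(
            f"{k} nodes exceeds the exact-enumeration cap of {MAX_NODES}"
        )
    cfg = _configs(k)
    mass = np.ones(2**k, dtype=float)
    col = {v: i for i, v in enumerate(order)}
    for node_id in order:
        table = model.tables[node_id]
        pidx = [col[p] for p in table.parent_order]
        # vectorized lookup of P(node=1 | parents) for each global config
        p1 = np.empty(2**k, dtype=float)
        if pidx:
            key = np.zeros(2**k, dtype=np.int64)
            for j in pidx:
                key = (key << 1) | cfg[:, j]
            lut = np.array(
                [
                    table.p1(c)
                    for c in product((0, 1), repeat=len(pidx))
                ]
            )
            p1 = lut[key]
        else:
            p1[:] = table.p1(())
        v = cfg[:, col[node_id]]
        mass *= np.where(v == 1, p1, 1.0 - p1)
    return JointTable(order, mass)


def condition(joint: JointTable, assignment: Mapping[str, int]) -> JointTable:
    """Renormalized restriction of the joint to an assignment.

    Raises :class:`ZeroProbabilityError` if the event has zero mass.
    """
    mask = joint._mask(assignment)
    total = float(joint.mass[mask].sum())
    if total <= 0.0:
        raise ZeroProbabilityError(
            f"conditioning event {dict(assignment)} has probability 0"
        )
    mass = np.where(mask, joint.mass, 0.0) / total
    return JointTable(joint.variables, mass)


def marginal(joint: JointTable, variables: Sequence[str]) -> JointTable:
    """Sum out every variable not in ``variables`` (original order kept)."""
    keep = [v for v in joint.variables if v in set(variables)]
    unknown = set(variables) - set(joint.variables)
    if unknown:
        raise GraphError(f"unknown variables {sorted(unknown)} in marginal()")
    k = len(joint.variables)
    drop_axes = tuple(
        i for i, v in enumerate(joint.variables) if v not in set(keep)
    )
    mass = joint.mass.reshape((2,) * k).sum(axis=drop_axes) if drop_axes else joint.mass
    return JointTable(tuple(keep), np.asarray(mass).reshape(-1))


def prob(
    joint: JointTable,
    event: Mapping[str, int],
    given: Mapping[str, int] | None = None,
) -> float:
    """P(event | given) from an exact joint table."""
    if given:
        joint = condition(joint, given)
    return float(joint.mass[joint._mask(event)].sum())


@dataclass(frozen=True)
class Cohort:
    """Per-configuration counts on which estimators run.

    ``counts`` are real-valued in expected mode (N x mass, no rounding)
    and integer-valued in sampled mode. ``conditioned`` carries the
    boxed variables and their retained levels so that
    :func:`apply_selection` needs no further model access;
    ``excluded_counts`` retains the filtered-out configurations after
    selection so pre/post contrasts stay computable.
    """

    variables: tuple[str, ...]
    counts: np.ndarray
    mode: str = "expected"  # expected | sampled
    selected_only: bool = False
    conditioned: tuple[tuple[str, int], ...] = ()
    symbols: tuple[str, ...] = ()
    excluded_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2 ** len(self.variables),):
            raise ValueError("counts length must be 2**len(variables)")
        if (counts < 0).any():
            raise ValueError("negative counts")
        if not self.symbols:
            object.__setattr__(
                self,
                "symbols",
                tuple(v.rstrip("0123456789") or v for v in self.variables),
            )

    # -- bookkeeping -------------------------------------------------------

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def configs(self) -> np.ndarray:
        return _configs(len(self.variables))

    def resolve(self, name: str) -> str:
        """Node id, or bare variable symbol when unambiguous."""
        if name in self.variables:
            return name
        hits = [v for v, s in zip(self.variables, self.symbols) if s == name]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise GraphError(f"unknown variable {name!r} in cohort")
        raise GraphError(f"variable {name!r} is ambiguous ({hits}); use a node id")

    def column(self, name: str) -> np.ndarray:
        return self.configs()[:, self.variables.index(self.resolve(name))]

    def mask(self, assignment: Mapping[str, int]) -> np.ndarray:
        mask = np.ones(len(self.counts), dtype=bool)
        for name, value in assignment.items():
            mask &= self.column(name) == int(value)
        return mask

    def count(self, assignment: Mapping[str, int] | None = None) -> float:
        """Total count of individuals matching the assignment."""
        if not assignment:
            return self.total
        return float(self.counts[self.mask(assignment)].sum())

    def scaled(self, factor: float) -> "Cohort":
        return replace(self, counts=self.counts * factor)

    def to_frame(self):
        """One row per configuration (canonical binary order): variable
        columns, count, selected flag."""
        import pandas as pd

        df = pd.DataFrame(self.configs(), columns=list(self.variables))
        df["count"] = self.counts
        if self.excluded_counts is not None:
            excl = pd.DataFrame(self.configs(), columns=list(self.variables))
            excl["count"] = self.excluded_counts
            df["selected"] = True
            excl["selected"] = False
            df = pd.concat([df, excl], ignore_index=True)
            df = df[df["count"] > 0].reset_index(drop=True) if False else df
        else:
            df["selected"] = True
        return df


def expected_cohort(model: StructuralModel) -> Cohort:
    """Deterministic cohort: count(config) = N * P(config). Counts are
    real-valued; rounding is a display concern only."""
    joint = enumerate_joint(model)
    return Cohort(
        variables=joint.variables,
        counts=model.cohort_size * joint.mass,
        mode="expected",
        conditioned=tuple(
            (n.id, n.condition_value) for n in model.graph.conditioned_nodes()
        ),
        symbols=tuple(model.graph.node(v).variable for v in joint.variables),
    )


def sample_cohort(model: StructuralModel, n: int, seed: int) -> Cohort:
    """Monte-Carlo cohort of ``n`` individuals by ancestral sampling in
    canonical topological order; reproducible for a fixed seed."""
    if n <= 0:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    order = model.graph.node_ids
    values: dict[str, np.ndarray] = {}
    for node_id in model.graph.topological_order():
        table = model.tables[node_id]
        if table.parent_order:
            lut = np.array(
                [table.p1(c) for c in product((0, 1), repeat=len(table.parent_order))]
            )
            key = np.zeros(n, dtype=np.int64)
            for p in table.parent_order:
                key = (key << 1) | values[p]
            p1 = lut[key]
        else:
            p1 = table.p1(())
        values[node_id] = (rng.random(n) < p1).astype(np.int64)

    idx = np.zeros(n, dtype=np.int64)
    for v in order:
        idx = (idx << 1) | values[v]
    counts = np.bincount(idx, minlength=2 ** len(order)).astype(float)
    return Cohort(
        variables=order,
        counts=counts,
        mode="sampled",
        conditioned=tuple(
            (nd.id, nd.condition_value) for nd in model.graph.conditioned_nodes()
        ),
        symbols=tuple(model.graph.node(v).variable for v in order),
    )


def apply_selection(cohort: Cohort) -> Cohort:
    """Restrict the cohort to its selected subpopulation.

    Configurations where any conditioned node differs from its retained
    level are removed from ``counts`` and kept in ``excluded_counts``.
    A cohort without conditioned nodes is returned unchanged.
    """
    if cohort.selected_only:
        raise ValueError("selection already applied to this cohort")
    if not cohort.conditioned:
        return cohort
    mask = np.ones(len(cohort.counts), dtype=bool)
    for name, value in cohort.conditioned:
        mask &= cohort.column(name) == value
    kept = np.where(mask, cohort.counts, 0.0)
    if kept.sum() <= 0:
        raise EmptySelectionError("selection removed the entire cohort")
    return replace(
        cohort,
        counts=kept,
        excluded_counts=np.where(mask, 0.0, cohort.counts),
        selected_only=True,
    )
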