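"""Ready-made structural models for the canonical selection phenomena.

One scenario per fundamental mechanism: selection in exposure vs. in
population composition, unifactorial vs. multifactorial, acting at
exposure entry, during exposure, or post-outcome — plus the worked
hypothetical cohort with multifactorial selection in exposure whose
expected counts the engine reproduces exactly (``table1``).

Only the ``table1`` scenario carries probabilities taken from published
worked numbers. Every other default parameterization is an artifact
constant chosen here (documented in docs/methods.md): probabilities lie
in [0.05, 0.95] and were picked so the scenario's qualitative bias
signature holds under exact enumeration. Selection-node tables are
risk-additive rather than multiplicative on purpose — a multiplicative
P(S | causes) factorizes, and conditioning on a collider whose table
factorizes induces no association at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import product
from typing import Callable, Mapping

import pandas as pd

from .engine import (
    Cohort,
    ConditionalTable,
    StructuralModel,
    apply_selection,
    condition,
    enumerate_joint,
    expected_cohort,
    prob,
)
from .errors import SpecError
from .estimators import (
    EffectEstimate,
    ipw_risk_ratio,
    mh_risk_ratio,
    odds_ratio,
    risk,
    risk_ratio,
    standardized_risk_ratio,
)
from .graph import CausalGraph, build_graph

__all__ = [
    "Scenario",
    "Signature",
    "BiasReport",
    "table1_model",
    "make_scenario",
    "bias_report",
    "scenario_names",
    "lookup_labels",
]


@dataclass(frozen=True)
class Signature:
    """A machine-checkable qualitative expectation about a scenario,
    evaluated under exact enumeration (no sampling noise)."""

    description: str
    check: Callable[["Scenario"], bool]

    def holds(self, scenario: "Scenario") -> bool:
        return bool(self.check(scenario))


@dataclass(frozen=True)
class Scenario:
    """A named structural model with its expected framework cells and
    qualitative bias signature."""

    name: str
    description: str
    model: StructuralModel
    expected_cells: dict  # target node id -> "L.M.T" cell code
    labels: dict = field(default_factory=dict)  # target -> canonical name
    exposure: str | None = None
    outcome: str | None = None
    bias_signature: tuple[Signature, ...] = ()

    def check_signatures(self) -> list[tuple[str, bool]]:
        return [(s.description, s.holds(self)) for s in self.bias_signature]

    def analysis_cohort(self) -> Cohort:
        """Expected cohort after conditioning by nature (if any)."""
        cohort = expected_cohort(self.model)
        if self.model.graph.conditioned_nodes():
            cohort = apply_selection(cohort)
        return cohort


# ---------------------------------------------------------------------------
# model-building helpers


def _model(nodes, edges, probs: Mapping, cohort_size: float) -> StructuralModel:
    with warnings.catch_warnings():
        # same-time-window arrows in builtin scenarios are deliberate
        warnings.simplefilter("ignore", UserWarning)
        graph = build_graph({"nodes": nodes, "edges": edges})
    tables = {}
    for n in graph.nodes:
        parents = tuple(i for i in graph.node_ids if i in graph.parents(n.id))
        spec = probs[n.id]
        table = {}
        for cfg in product((0, 1), repeat=len(parents)):
            p = spec(dict(zip(parents, cfg))) if callable(spec) else spec
            table[cfg] = float(p)
        tables[n.id] = ConditionalTable(n.id, parents, table)
    return StructuralModel(graph, tables, cohort_size)


def _sel_joint(scenario: Scenario):
    """Joint law conditioned by nature on every boxed node."""
    joint = enumerate_joint(scenario.model)
    assignment = {
        n.id: n.condition_value for n in scenario.model.graph.conditioned_nodes()
    }
    return condition(joint, assignment) if assignment else joint


def _crude_rr(cohort: Cohort, e: str, d: str) -> float | None:
    return risk_ratio(cohort, e, d)[0].value


# ---------------------------------------------------------------------------
# the worked hypothetical cohort (multifactorial selection in exposure)

#: P(E = 1 | C, U): becoming exposed depends on a known cause C and an
#: unknown cause U, generated independently with P(C)=P(U)=1/2.
_T1_P_EXPOSED = {(0, 0): 0.10, (1, 0): 0.30, (0, 1): 0.20, (1, 1): 0.50}


def _t1_p_disease(v: Mapping[str, int]) -> float:
    # Baseline risk 10%; exposure doubles it; C multiplies it by 1.5 when
    # U is absent but by 4.0 when U is present (C x U interaction), so the
    # exposure effect is homogeneous (RR 2.0) yet C-only adjustment is
    # biased by the unmeasured U.
    return 0.10 * 2 ** v["E1"] * (1.5 * (1 - v["U0"]) + 4.0 * v["U0"]) ** v["C0"]


def table1_model(cohort_size: float = 4000) -> StructuralModel:
    """The hypothetical cohort with multifactorial selection in exposure.

    Structure: C0 -> E1 <- U0, with C0, U0 and E1 all causing the disease
    outcome D2. With N = 4000 the expected cohort reproduces the worked
    cell counts exactly (four strata of 1000, e.g. 400 exposed cases in
    the C=1, U=1 stratum).
    """
    return _model(
        nodes=[
            {"id": "C0", "role": "covariate"},
            {"id": "U0", "role": "unknown_cause"},
            {"id": "E1", "role": "exposure"},
            {"id": "D2", "role": "outcome"},
        ],
        edges=[["C0", "E1"], ["U0", "E1"], ["E1", "D2"], ["C0", "D2"], ["U0", "D2"]],
        probs={
            "C0": 0.5,
            "U0": 0.5,
            "E1": lambda v: _T1_P_EXPOSED[(v["C0"], v["U0"])],
            "D2": _t1_p_disease,
        },
        cohort_size=cohort_size,
    )


# ---------------------------------------------------------------------------
# signature constructors


def _sig_or_unity(a, b, given=None, desc=None):
    def check(s: Scenario) -> bool:
        est = odds_ratio(expected_cohort(s.model), a, b, given)
        return est.defined and abs(est.value - 1.0) < 1e-9

    return Signature(desc or f"OR({a},{b}) = 1 marginally", check)


def _sig_or_selected_lt1(a, b, desc=None):
    def check(s: Scenario) -> bool:
        est = odds_ratio(s.analysis_cohort(), a, b)
        return est.defined and est.value < 1.0 - 1e-9

    return Signature(
        desc or f"OR({a},{b} | selected) < 1: induced inverse association", check
    )


def _sig(desc: str, fn: Callable[[Scenario], bool]) -> Signature:
    return Signature(desc, fn)


# ---------------------------------------------------------------------------
# scenario builders (default probabilities are artifact constants)


def _fig2a(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "C0", "role": "covariate"},
            {"id": "E1", "role": "exposure"},
            {"id": "D2", "role": "outcome"},
        ],
        edges=[["C0", "E1"], ["C0", "D2"], ["E1", "D2"]],
        probs={
            "C0": 0.5,
            "E1": lambda v: (0.2, 0.6)[v["C0"]],
            "D2": lambda v: 0.1 * 2 ** v["E1"] * 2 ** v["C0"],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig2a",
        description=(
            "Unifactorial selection in exposure at exposure entry: a known "
            "cause C of the outcome also selects who becomes exposed "
            "(healthy worker hire effect); classical confounding."
        ),
        model=model,
        expected_cells={"E1": "1.1.1"},
        labels={"E1": "self-selection / healthy worker hire effect"},
        exposure="E1",
        outcome="D2",
        bias_signature=(
            _sig(
                "RR(E->D) = 2.0 within each stratum of C (homogeneous effect)",
                lambda s: all(
                    e.defined and abs(e.value - 2.0) < 1e-9
                    for e in risk_ratio(expected_cohort(s.model), "E1", "D2", ["C0"])
                ),
            ),
            _sig(
                "crude RR(E->D) > conditional RR: confounding by C",
                lambda s: _crude_rr(expected_cohort(s.model), "E1", "D2") > 2.0 + 1e-9,
            ),
        ),
    )


def _fig2b(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "C0", "role": "covariate"},
            {"id": "S1", "role": "selection", "conditioned": True},
            {"id": "E1", "role": "exposure"},
            {"id": "D2", "role": "outcome"},
        ],
        edges=[["C0", "S1"], ["C0", "D2"], ["E1", "D2"]],
        probs={
            "C0": 0.5,
            "S1": lambda v: (0.3, 0.8)[v["C0"]],
            "E1": 0.4,
            "D2": lambda v: 0.1 * 2 ** v["E1"] * 2 ** v["C0"],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig2b",
        description=(
            "Unifactorial selection in population composition at exposure "
            "entry: C selects who remains eligible (boxed S); the selected "
            "population is enriched in C but the relative exposure effect "
            "is untouched (external, not internal, validity is at stake)."
        ),
        model=model,
        expected_cells={"S1": "1.2.1"},
        labels={"S1": "self-selection (population composition)"},
        exposure="E1",
        outcome="D2",
        bias_signature=(
            _sig(
                "P(C=1 | S=1) > P(C=1): selected population enriched in C",
                lambda s: prob(enumerate_joint(s.model), {"C0": 1}, {"S1": 1})
                > prob(enumerate_joint(s.model), {"C0": 1}) + 1e-9,
            ),
            _sig(
                "crude RR(E->D) among selected = 2.0 (no internal bias: E "
                "independent of the selection origin C)",
                lambda s: abs(_crude_rr(s.analysis_cohort(), "E1", "D2") - 2.0)
                < 1e-9,
            ),
            _sig(
                "baseline risk among unexposed differs: selected vs. total",
                lambda s: risk(s.analysis_cohort(), "D2", {"E1": 0}).value
                > risk(expected_cohort(s.model), "D2", {"E1": 0}).value + 1e-9,
            ),
        ),
    )


def _fig2c(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "C0", "role": "covariate"},
            {"id": "U0", "role": "unknown_cause"},
            {"id": "E1", "role": "exposure"},
        ],
        edges=[["C0", "E1"], ["U0", "E1"]],
        probs={
            "C0": 0.5,
            "U0": 0.5,
            "E1": lambda v: _T1_P_EXPOSED[(v["C0"], v["U0"])],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig2c",
        description=(
            "Multifactorial selection in exposure: a known cause C and an "
            "unknown cause U independently select who becomes exposed, "
            "inducing an inverse C-U association within strata of E."
        ),
        model=model,
        expected_cells={"E1": "1.1.1"},
        labels={"E1": "multifactorial self-selection / healthy worker hire effect"},
        exposure="E1",
        outcome=None,
        bias_signature=(
            _sig_or_unity("C0", "U0"),
            _sig(
                "OR(C,U | E=1) < 1: induced inverse association among exposed",
                lambda s: odds_ratio(expected_cohort(s.model), "C0", "U0", {"E1": 1}).value
                < 1.0 - 1e-9,
            ),
        ),
    )


def _fig2d(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "U0", "role": "unknown_cause"},
            {"id": "E1", "role": "exposure"},
            {"id": "S1", "role": "selection", "conditioned": True},
            {"id": "D2", "role": "outcome"},
        ],
        # E and S share a time window: the index event is simultaneous
        # with exposure entry, so the selection acts at exposure entry.
        edges=[["E1", "S1"], ["U0", "S1"], ["U0", "D2"]],
        probs={
            "U0": 0.5,
            "E1": 0.4,
            # risk-additive so that conditioning on the collider induces a
            # genuine inverse E-U association
            "S1": lambda v: 0.1 + 0.3 * v["E1"] + 0.4 * v["U0"],
            "D2": lambda v: (0.1, 0.3)[v["U0"]],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig2d",
        description=(
            "Multifactorial selection in population composition at exposure "
            "entry: exposure E and an unknown factor U both cause entry "
            "into an index population (boxed S, e.g. incident disease); "
            "studying progression D among S=1 induces an inverse E-U "
            "association and a spurious protective E-D association "
            "(index event / collider stratification bias)."
        ),
        model=model,
        expected_cells={"S1": "1.2.1"},
        labels={"S1": "index event bias / collider stratification bias"},
        exposure="E1",
        outcome="D2",
        bias_signature=(
            _sig_or_unity("E1", "U0"),
            _sig_or_selected_lt1("E1", "U0"),
            _sig(
                "spurious protective RR(E->D) < 1 among S=1 despite E "
                "having no effect on D",
                lambda s: _crude_rr(s.analysis_cohort(), "E1", "D2") < 1.0 - 1e-9,
            ),
        ),
    )


def _fig3a(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "C0", "role": "covariate"},
            {"id": "E0", "role": "exposure"},
            {"id": "E1", "role": "exposure"},
            {"id": "D2", "role": "outcome"},
        ],
        edges=[["E0", "E1"], ["C0", "E1"], ["E1", "D2"], ["C0", "D2"]],
        probs={
            "C0": 0.5,
            "E0": 0.4,
            # continuation: common among initiators, with a C gradient;
            # initiation among non-initiators is rare
            "E1": lambda v: (0.8, 0.5)[v["C0"]] if v["E0"] else 0.05,
            "D2": lambda v: 0.1 * 2 ** v["E1"] * 2 ** v["C0"],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig3a",
        description=(
            "Selection in exposure during exposure: C does not influence "
            "exposure initiation (E0) but does influence continuation (E1) "
            "— the healthy worker survivor pattern."
        ),
        model=model,
        expected_cells={"E1": "1.1.2"},
        labels={"E1": "healthy worker survivor effect"},
        exposure="E1",
        outcome="D2",
        bias_signature=(
            _sig(
                "RR(E1->D) = 2.0 within each stratum of C",
                lambda s: all(
                    e.defined and abs(e.value - 2.0) < 1e-9
                    for e in risk_ratio(expected_cohort(s.model), "E1", "D2", ["C0"])
                ),
            ),
            _sig(
                "crude RR(E1->D) != 2.0: confounding of the continuation "
                "effect by C",
                lambda s: abs(_crude_rr(expected_cohort(s.model), "E1", "D2") - 2.0)
                > 1e-6,
            ),
            _sig(
                "C is unrelated to initiation: P(E0=1|C=1) = P(E0=1|C=0)",
                lambda s: abs(
                    prob(enumerate_joint(s.model), {"E0": 1}, {"C0": 1})
                    - prob(enumerate_joint(s.model), {"E0": 1}, {"C0": 0})
                )
                < 1e-12,
            ),
        ),
    )


def _fig3b(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "E0", "role": "exposure"},
            {"id": "A1", "role": "side_effect"},
            {"id": "E2", "role": "exposure"},
            {"id": "D3", "role": "outcome"},
        ],
        edges=[["E0", "A1"], ["A1", "E2"], ["E0", "E2"], ["E2", "D3"]],
        probs={
            "E0": 0.4,
            "A1": lambda v: (0.05, 0.4)[v["E0"]],
            "E2": lambda v: ((0.8, 0.3)[v["A1"]] if v["E0"] else 0.05),
            "D3": lambda v: 0.1 * 2 ** v["E2"],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig3b",
        description=(
            "Selection in exposure during exposure, mediated by a side "
            "effect: exposure causes an adverse event A (e.g. bad cough) "
            "that makes continuation less likely, so continuing exposed "
            "individuals have experienced A less than quitters."
        ),
        model=model,
        expected_cells={"E2": "1.1.2"},
        labels={"E2": "side effects causing exposure changes"},
        exposure="E2",
        outcome="D3",
        bias_signature=(
            _sig(
                "among initiators, continuers experienced the side effect "
                "less: P(A=1|E2=1,E0=1) < P(A=1|E2=0,E0=1)",
                lambda s: prob(
                    enumerate_joint(s.model), {"A1": 1}, {"E2": 1, "E0": 1}
                )
                < prob(enumerate_joint(s.model), {"A1": 1}, {"E2": 0, "E0": 1})
                - 1e-9,
            ),
        ),
    )


def _fig3c(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "E0", "role": "exposure"},
            {"id": "U0", "role": "unknown_cause"},
            {"id": "S1", "role": "selection", "conditioned": True},
            {"id": "D2", "role": "outcome"},
        ],
        edges=[["E0", "S1"], ["U0", "S1"], ["E0", "D2"], ["U0", "D2"]],
        probs={
            "E0": 0.5,
            "U0": 0.5,
            # S = remaining at risk (e.g. survival); E and U both raise
            # the competing event, additively on the risk scale
            "S1": lambda v: 0.9 - 0.3 * v["E0"] - 0.3 * v["U0"],
            "D2": lambda v: 0.1 * 2 ** v["E0"] * 3 ** v["U0"],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig3c",
        description=(
            "Selection in population composition during exposure: exposure "
            "and an unknown determinant both cause a competing event that "
            "precludes the outcome of interest; only those without the "
            "competing event (S=1) remain at risk."
        ),
        model=model,
        expected_cells={"S1": "1.2.2"},
        labels={"S1": "competing event"},
        exposure="E0",
        outcome="D2",
        bias_signature=(
            _sig_or_unity("E0", "U0"),
            _sig_or_selected_lt1("E0", "U0"),
            _sig(
                "crude RR(E->D) among survivors < U-conditional RR (=2.0): "
                "exposed survivors carry less U",
                lambda s: _crude_rr(s.analysis_cohort(), "E0", "D2") < 2.0 - 1e-9,
            ),
        ),
    )


def _fig3d(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "E0", "role": "exposure"},
            {"id": "U0", "role": "unknown_cause"},
            # boxed outcome: conditioning by nature on *not* having had the
            # early event (the population still at risk of D2)
            {
                "id": "D1",
                "variable": "D",
                "time": 1,
                "role": "outcome",
                "conditioned": True,
                "condition_value": 0,
            },
            {"id": "D2", "variable": "D", "time": 2, "role": "outcome"},
        ],
        edges=[["E0", "D1"], ["U0", "D1"], ["E0", "D2"], ["U0", "D2"]],
        probs={
            "E0": 0.5,
            "U0": 0.5,
            "D1": lambda v: 0.1 + 0.2 * v["E0"] + 0.4 * v["U0"],
            "D2": lambda v: 0.1 * 2 ** v["E0"] * 4 ** v["U0"],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig3d",
        description=(
            "Depletion of susceptibles: exposure and an unknown "
            "susceptibility factor cause early outcome events (boxed D1), "
            "which progressively remove susceptible individuals; the "
            "apparent later effect of exposure (on D2, among D1=0 "
            "survivors) is attenuated unless susceptibility is accounted "
            "for."
        ),
        model=model,
        expected_cells={"D1": "1.2.2"},
        labels={"D1": "depletion of susceptibles"},
        exposure="E0",
        outcome="D2",
        bias_signature=(
            _sig(
                "among D1=0 survivors, P(U=1|E=1) < P(U=1|E=0): exposed "
                "survivors are a more selected group",
                lambda s: prob(_sel_joint(s), {"U0": 1}, {"E0": 1})
                < prob(_sel_joint(s), {"U0": 1}, {"E0": 0}) - 1e-9,
            ),
            _sig(
                "RR(E->D2 | D1=0) < 2.0 crude, but = 2.0 within each "
                "stratum of U",
                lambda s: _crude_rr(s.analysis_cohort(), "E0", "D2") < 2.0 - 1e-9
                and all(
                    e.defined and abs(e.value - 2.0) < 1e-9
                    for e in risk_ratio(s.analysis_cohort(), "E0", "D2", ["U0"])
                ),
            ),
        ),
    )


def _fig4a(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "D0", "role": "outcome"},
            {"id": "E1", "role": "exposure"},
        ],
        edges=[["D0", "E1"]],
        probs={
            "D0": 0.3,
            "E1": lambda v: (0.2, 0.6)[v["D0"]],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig4a",
        description=(
            "Reversed causality: the outcome (or its subclinical phase) "
            "causes subsequent exposure change. The cross-lagged E1-D0 "
            "association mimics an exposure effect; no later outcome "
            "exists against which an RR bias could be measured."
        ),
        model=model,
        expected_cells={"E1": "1.1.3"},
        labels={"E1": "reversed causality / subclinical symptoms causing exposure changes"},
        exposure="E1",
        outcome=None,
        bias_signature=(
            _sig(
                "cross-lagged association OR(E1, D0) > 1 although E has no "
                "causal effect on D",
                lambda s: odds_ratio(expected_cohort(s.model), "E1", "D0").value
                > 1.0 + 1e-9,
            ),
        ),
    )


def _fig4b(N: float) -> Scenario:
    model = _model(
        nodes=[
            {"id": "E0", "role": "exposure"},
            {"id": "D0", "variable": "D", "time": 0, "role": "outcome"},
            {"id": "S1", "role": "selection", "conditioned": True},
        ],
        edges=[["E0", "S1"], ["D0", "S1"]],
        probs={
            "E0": 0.4,
            "D0": 0.2,
            "S1": lambda v: 0.1 + 0.3 * v["E0"] + 0.4 * v["D0"],
        },
        cohort_size=N,
    )
    return Scenario(
        name="fig4b",
        description=(
            "Berkson's fallacy: membership of the observed population "
            "(boxed S, e.g. hospital attendance) depends on both the "
            "disease outcome and the exposure, distorting their "
            "association in the selected population."
        ),
        model=model,
        expected_cells={"S1": "1.2.3"},
        labels={"S1": "Berkson's fallacy"},
        exposure="E0",
        outcome="D0",
        bias_signature=(
            _sig_or_unity("E0", "D0"),
            _sig(
                "OR(E,D | S=1) != OR(E,D): association distorted in the "
                "selected population",
                lambda s: abs(
                    odds_ratio(s.analysis_cohort(), "E0", "D0").value - 1.0
                )
                > 1e-9,
            ),
        ),
    )


def _table1(N: float = 4000) -> Scenario:
    model = table1_model(N)
    return Scenario(
        name="table1",
        description=(
            "The worked hypothetical cohort: multifactorial selection in "
            "exposure from a known cause C and an unknown cause U, with a "
            "C x U interaction on the outcome. The exposure effect is "
            "homogeneous (RR 2.0) but C-only adjustment is biased because "
            "exposed and unexposed with the same C differ in U."
        ),
        model=model,
        expected_cells={"E1": "1.1.1"},
        labels={"E1": "multifactorial self-selection"},
        exposure="E1",
        outcome="D2",
        bias_signature=(
            _sig(
                "RR(E->D) = 2.0 in all four C x U strata",
                lambda s: all(
                    e.defined and abs(e.value - 2.0) < 1e-9
                    for e in risk_ratio(
                        expected_cohort(s.model), "E1", "D2", ["C0", "U0"]
                    )
                ),
            ),
            _sig_or_unity("C0", "U0"),
            _sig(
                "OR(C,U | E=1) < 1: induced inverse association among exposed",
                lambda s: odds_ratio(
                    expected_cohort(s.model), "C0", "U0", {"E1": 1}
                ).value
                < 1.0 - 1e-9,
            ),
            _sig(
                "full standardization over {C,U} recovers 2.0; "
                "Mantel-Haenszel over C alone does not",
                lambda s: abs(
                    standardized_risk_ratio(
                        expected_cohort(s.model), "E1", "D2", ["C0", "U0"]
                    ).value
                    - 2.0
                )
                < 1e-10
                and abs(
                    mh_risk_ratio(expected_cohort(s.model), "E1", "D2", ["C0"]).value
                    - 2.0
                )
                > 1e-3,
            ),
        ),
    )


_BUILDERS: dict[str, Callable[[float], Scenario]] = {
    "fig2a": _fig2a,
    "fig2b": _fig2b,
    "fig2c": _fig2c,
    "fig2d": _fig2d,
    "fig3a": _fig3a,
    "fig3b": _fig3b,
    "fig3c": _fig3c,
    "fig3d": _fig3d,
    "fig4a": _fig4a,
    "fig4b": _fig4b,
    "table1": _table1,
}

#: canonical-phenomenon aliases into the figure registry
_ALIASES = {
    "healthy_worker_hire": "fig2a",
    "healthy_worker_survivor": "fig3a",
    "berkson": "fig4b",
    "index_event": "fig2d",
    "depletion": "fig3d",
}

_DEFAULT_N = 10000.0


def scenario_names(include_aliases: bool = True) -> tuple[str, ...]:
    names = list(_BUILDERS)
    if include_aliases:
        names += list(_ALIASES)
    return tuple(names)


def _parse_override_key(key: str) -> tuple[str, dict[str, int]]:
    """Parse "E1" or "E1|C0=1,U0=0" into (node, partial parent assignment)."""
    if "|" not in key:
        return key.strip(), {}
    node, _, rest = key.partition("|")
    assignment = {}
    for part in rest.split(","):
        if "=" not in part:
            raise SpecError(f"override condition {part!r} is not name=value", path=key)
        name, _, val = part.partition("=")
        assignment[name.strip()] = int(val)
    return node.strip(), assignment


def make_scenario(
    name: str, overrides: Mapping[str, float] | None = None
) -> Scenario:
    """Build a registry scenario, optionally overriding individual
    conditional probabilities.

    Override keys are ``"node"`` (roots, or all rows) or
    ``"node|parent=value,..."`` for a (possibly partial) parent
    configuration, e.g. ``{"E1|C0=1": 0.2}``.
    """
    canonical = _ALIASES.get(name, name)
    if canonical not in _BUILDERS:
        raise SpecError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        )
    scenario = _BUILDERS[canonical](4000 if canonical == "table1" else _DEFAULT_N)
    if name in _ALIASES:
        scenario = replace(scenario, name=name)
    model = scenario.model
    for key, value in (overrides or {}).items():
        node, assignment = _parse_override_key(key)
        model = model.with_probability(node, assignment, float(value))
    if model is not scenario.model:
        scenario = replace(scenario, model=model)
    return scenario


# ---------------------------------------------------------------------------
# label lookup for arbitrary graphs


def _structure_key(graph: CausalGraph) -> tuple:
    nodes = tuple(
        (n.variable, n.time, n.role, n.conditioned, n.condition_value)
        for n in graph.nodes
    )
    by_id = {n.id: (n.variable, n.time) for n in graph.nodes}
    edges = tuple(sorted((by_id[e.tail], by_id[e.head]) for e in graph.edges))
    return nodes, edges


@lru_cache(maxsize=1)
def _registry_structures() -> tuple[tuple[tuple, dict], ...]:
    out = []
    for name in _BUILDERS:
        scenario = _BUILDERS[name](1.0)
        out.append((_structure_key(scenario.model.graph), dict(scenario.labels)))
    return tuple(out)


def lookup_labels(graph: CausalGraph) -> dict[str, str]:
    """Canonical epidemiological labels for a graph that structurally
    matches a builtin scenario (study-specific flags ignored); empty for
    unrecognized graphs — labels are never invented."""
    key = _structure_key(graph)
    for skey, labels in _registry_structures():
        if skey == key:
            return dict(labels)
    return {}


# ---------------------------------------------------------------------------
# bias report


@dataclass(frozen=True)
class BiasReport:
    """Truth vs. naive analyses for one scenario, plus its qualitative
    signature verdicts."""

    scenario: str
    truth: float | None
    rows: tuple  # (label, EffectEstimate, abs_bias, rel_bias)
    signatures: tuple  # (description, holds)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for label, est, abs_bias, rel_bias in self.rows:
            recs.append(
                {
                    "analysis": label,
                    "method": est.method,
                    "value": est.value,
                    "abs_bias": abs_bias,
                    "rel_bias": rel_bias,
                    "status": "ok" if est.defined else "undefined",
                }
            )
        return pd.DataFrame(
            recs, columns=["analysis", "method", "value", "abs_bias", "rel_bias", "status"]
        )

    def all_signatures_hold(self) -> bool:
        return all(ok for _, ok in self.signatures)


def bias_report(scenario: Scenario) -> BiasReport:
    """Contrast the true exposure effect with naive analyses.

    Rows: the true standardized RR (all covariates, pre-selection
    cohort), the crude RR on the analysis cohort, the RR adjusted
    (Mantel-Haenszel) for observed covariates only, IPW over observed
    covariates, and IPW over the full covariate set including unknown
    causes. Scenarios without a downstream outcome report only their
    signature verdicts (the distortion there is an induced association,
    not an RR bias).
    """
    signatures = tuple(scenario.check_signatures())
    if scenario.exposure is None or scenario.outcome is None:
        return BiasReport(scenario.name, None, (), signatures)

    graph = scenario.model.graph
    e, d = scenario.exposure, scenario.outcome
    full_covariates = [
        n.id for n in graph.nodes if n.role in ("covariate", "unknown_cause")
    ]
    observed_covariates = [n.id for n in graph.nodes if n.role == "covariate"]

    full = expected_cohort(scenario.model)
    analysis = scenario.analysis_cohort()

    truth_est = standardized_risk_ratio(full, e, d, full_covariates)
    truth = truth_est.value

    def _entry(label: str, est: EffectEstimate):
        if est.defined and truth is not None:
            return (label, est, est.value - truth, est.value / truth)
        return (label, est, None, None)

    rows = (
        _entry("true standardized RR (all covariates, pre-selection)", truth_est),
        _entry("crude RR", risk_ratio(analysis, e, d)[0]),
        _entry(
            "RR adjusted for observed covariates (Mantel-Haenszel)",
            mh_risk_ratio(analysis, e, d, observed_covariates),
        ),
        _entry(
            "IPW RR, observed covariates",
            ipw_risk_ratio(analysis, e, d, observed_covariates),
        ),
        _entry(
            "IPW RR, full covariate set (incl. unknown causes)",
            ipw_risk_ratio(analysis, e, d, full_covariates),
        ),
    )
    return BiasReport(scenario.name, truth, rows, signatures)
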