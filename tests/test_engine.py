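"""Exact enumeration, conditioning by nature, cohorts and sampling."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selproc import (
    Cohort,
    ConditionalTable,
    EmptySelectionError,
    SpecError,
    StructuralModel,
    ZeroProbabilityError,
    apply_selection,
    build_graph,
    condition,
    enumerate_joint,
    expected_cohort,
    make_scenario,
    marginal,
    prob,
    sample_cohort,
    table1_model,
)

# Expected Table-1-style cohort: (U, C, E) -> (cases, non-cases)
T1_CELLS = {
    (0, 0, 1): (20, 80),
    (0, 0, 0): (90, 810),
    (0, 1, 1): (90, 210),
    (0, 1, 0): (105, 595),
    (1, 0, 1): (40, 160),
    (1, 0, 0): (80, 720),
    (1, 1, 1): (400, 100),
    (1, 1, 0): (200, 300),
}


def _chain_model(ps, cohort_size=1.0):
    """X0 -> X1 -> ... with P(X_i=1 | parent) from ps (test helper)."""
    k = len(ps)
    nodes = [{"id": f"X{i}", "variable": f"X{i}", "time": i} for i in range(k)]
    edges = [[f"X{i}", f"X{i+1}"] for i in range(k - 1)]
    graph = build_graph({"nodes": nodes, "edges": edges})
    tables = {}
    for i in range(k):
        if i == 0:
            tables["X0"] = ConditionalTable("X0", (), {(): ps[0]})
        else:
            p0, p1 = ps[i]
            tables[f"X{i}"] = ConditionalTable(
                f"X{i}", (f"X{i-1}",), {(0,): p0, (1,): p1}
            )
    return StructuralModel(graph, tables, cohort_size)


def test_joint_is_product_of_conditionals(t1_model):
    joint = enumerate_joint(t1_model)
    # hand product: P(C=1) P(U=1) P(E=1|1,1) P(D=1|1,1,1) = .5*.5*.5*.8
    assert prob(joint, {"C0": 1, "U0": 1, "E1": 1, "D2": 1}) == pytest.approx(
        0.10, abs=1e-15
    )
    assert joint.mass.sum() == pytest.approx(1.0, abs=1e-12)


def test_independent_nodes_give_uniform_mass():
    m = _chain_model([0.5, (0.5, 0.5), (0.5, 0.5)])
    joint = enumerate_joint(m)
    assert np.allclose(joint.mass, 0.125)


def test_degenerate_single_node():
    m = _chain_model([1.0])
    joint = enumerate_joint(m)
    assert prob(joint, {"X0": 1}) == 1.0
    assert prob(joint, {"X0": 0}) == 0.0


def test_enumeration_cap():
    k = 21
    nodes = [{"id": f"X{i}", "variable": f"X{i}", "time": i} for i in range(k)]
    graph = build_graph({"nodes": nodes, "edges": []})
    tables = {f"X{i}": ConditionalTable(f"X{i}", (), {(): 0.5}) for i in range(k)}
    with pytest.raises(SpecError, match="cap"):
        enumerate_joint(StructuralModel(graph, tables))


def test_probability_out_of_range_rejected():
    with pytest.raises(SpecError, match="outside"):
        ConditionalTable("X0", (), {(): 1.5})


def test_marginals_and_conditionals_of_worked_cohort(t1_model):
    joint = enumerate_joint(t1_model)
    assert prob(joint, {"E1": 1}) == pytest.approx(0.275, abs=1e-12)
    assert prob(joint, {"D2": 1}, given={"E1": 1, "C0": 1, "U0": 1}) == pytest.approx(
        0.8, abs=1e-12
    )
    full = marginal(joint, joint.variables)
    assert np.allclose(full.mass, joint.mass)


def test_conditioning_on_independent_node_leaves_margins():
    m = _chain_model([0.3, (0.5, 0.5)])  # X1 independent of X0
    joint = enumerate_joint(m)
    cond = condition(joint, {"X1": 1})
    assert prob(cond, {"X0": 1}) == pytest.approx(prob(joint, {"X0": 1}), abs=1e-12)


def test_zero_probability_conditioning_raises():
    m = _chain_model([1.0])
    with pytest.raises(ZeroProbabilityError):
        condition(enumerate_joint(m), {"X0": 0})


def test_collider_conditioning_induces_inverse_association():
    """Conditioning on the index event makes independent causes inversely
    associated (marginally their odds ratio is exactly 1)."""
    from selproc import expected_cohort, odds_ratio

    s = make_scenario("fig2d")
    joint = enumerate_joint(s.model)
    cohort = expected_cohort(s.model)
    assert odds_ratio(cohort, "E1", "U0").value == pytest.approx(1.0, abs=1e-12)
    cond = condition(joint, {"S1": 1})
    # OR from conditioned joint masses
    p = {
        (e, u): prob(cond, {"E1": e, "U0": u})
        for e, u in product((0, 1), repeat=2)
    }
    or_sel = (p[(1, 1)] * p[(0, 0)]) / (p[(1, 0)] * p[(0, 1)])
    assert or_sel < 1.0


@st.composite
def chain_models(draw):
    k = draw(st.integers(2, 4))
    unit = st.floats(0.05, 0.95)
    ps = [draw(unit)] + [(draw(unit), draw(unit)) for _ in range(k - 1)]
    return _chain_model(ps)


@given(chain_models())
@settings(max_examples=40, derandomize=True)
def test_condition_then_marginal_commutes(model):
    joint = enumerate_joint(model)
    keep = list(joint.variables[:-1])
    cond_then_marg = marginal(condition(joint, {joint.variables[-1]: 1}), keep)
    # brute-force oracle: renormalize masses summed by hand
    masses = joint.as_dict()
    last = len(joint.variables) - 1
    total = sum(m for cfg, m in masses.items() if cfg[last] == 1)
    for cfg, got in cond_then_marg.as_dict().items():
        want = (
            sum(
                m
                for full_cfg, m in masses.items()
                if full_cfg[:last] == cfg and full_cfg[last] == 1
            )
            / total
        )
        assert got == pytest.approx(want, abs=1e-12)


@given(chain_models())
@settings(max_examples=40, derandomize=True)
def test_mass_conservation(model):
    joint = enumerate_joint(model)
    assert joint.mass.sum() == pytest.approx(1.0, abs=1e-12)
    cohort = expected_cohort(model)
    assert cohort.total == pytest.approx(model.cohort_size, abs=1e-12)


def test_expected_cohort_reproduces_all_printed_counts(t1_cohort):
    """The worked 4000-person cohort: all 16 expected cell counts exact."""
    for (u, c, e), (cases, non_cases) in T1_CELLS.items():
        got_cases = t1_cohort.count({"U0": u, "C0": c, "E1": e, "D2": 1})
        got_non = t1_cohort.count({"U0": u, "C0": c, "E1": e, "D2": 0})
        assert got_cases == pytest.approx(cases, abs=1e-9)
        assert got_non == pytest.approx(non_cases, abs=1e-9)
    assert t1_cohort.total == pytest.approx(4000, abs=1e-9)


def test_zero_cohort_size_gives_zero_counts():
    cohort = expected_cohort(table1_model(0))
    assert cohort.total == 0


def test_sampling_is_deterministic_for_fixed_seed(t1_model):
    a = sample_cohort(t1_model, 5000, seed=7)
    b = sample_cohort(t1_model, 5000, seed=7)
    assert np.array_equal(a.counts, b.counts)
    assert a.mode == "sampled" and a.total == 5000


def test_sampling_degenerate_model_yields_single_configuration():
    m = _chain_model([1.0, (1.0, 1.0)])
    cohort = sample_cohort(m, 100, seed=1)
    assert cohort.count({"X0": 1, "X1": 1}) == 100


def test_sampled_frequencies_approach_enumerated_masses(t1_model):
    """Law of large numbers: each configuration within 4 binomial SE."""
    n = 100_000
    cohort = sample_cohort(t1_model, n, seed=42)
    joint = enumerate_joint(t1_model)
    for mass, count in zip(joint.mass, cohort.counts):
        se = np.sqrt(n * mass * (1 - mass))
        assert abs(count - n * mass) <= 4 * se + 1e-9


def test_apply_selection_removes_unselected_configurations():
    s = make_scenario("fig3c")
    cohort = apply_selection(expected_cohort(s.model))
    assert cohort.selected_only
    assert cohort.count({"S1": 0}) == 0
    assert cohort.excluded_counts is not None
    # pre/post contrast still available
    assert cohort.excluded_counts.sum() + cohort.total == pytest.approx(
        s.model.cohort_size
    )


def test_apply_selection_noop_without_conditioned_nodes(t1_cohort):
    assert apply_selection(t1_cohort) is t1_cohort


def test_depletion_selection_conditions_on_survivors():
    """Among early-event-free survivors the exposed carry less of the
    unknown susceptibility factor — the induced inverse association."""
    s = make_scenario("fig3d")
    cohort = apply_selection(expected_cohort(s.model))
    assert cohort.count({"D1": 1}) == 0  # condition_value = 0
    p_u_exposed = cohort.count({"U0": 1, "E0": 1}) / cohort.count({"E0": 1})
    p_u_unexposed = cohort.count({"U0": 1, "E0": 0}) / cohort.count({"E0": 0})
    assert p_u_exposed < p_u_unexposed


def test_selection_that_empties_cohort_raises():
    spec = {
        "nodes": [
            {"id": "S1", "role": "selection", "conditioned": True},
        ],
        "edges": [],
    }
    graph = build_graph(spec)
    tables = {"S1": ConditionalTable("S1", (), {(): 0.0})}
    cohort = expected_cohort(StructuralModel(graph, tables, 100))
    with pytest.raises(EmptySelectionError):
        apply_selection(cohort)
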