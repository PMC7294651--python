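"""Identification and three-dimensional classification of selection
processes, including the frozen golden cells for all builtin templates."""

import dataclasses
import json
from pathlib import Path

import pytest

from selproc import (
    CausalGraph,
    build_graph,
    classify,
    framework_report,
    identify_processes,
    make_scenario,
)

GOLDEN = json.loads(
    (Path(__file__).parent / "data" / "golden_cells.json").read_text()
)


def _graph(name: str) -> CausalGraph:
    return make_scenario(name).model.graph


def test_identify_single_process_with_origins():
    procs = identify_processes(_graph("fig2a"))
    assert len(procs) == 1
    assert procs[0].target == "E1"
    assert procs[0].origins == frozenset({"C0"})


def test_identify_empty_for_graph_without_targets():
    g = build_graph(
        {
            "nodes": [{"id": "E1", "role": "exposure"}, {"id": "D2", "role": "outcome"}],
            "edges": [["E1", "D2"]],
        }
    )
    assert identify_processes(g) == []


def test_side_effect_mediation_flag():
    procs = identify_processes(_graph("fig3b"))
    (proc,) = [p for p in procs if p.target == "E2"]
    assert proc.mediated_by_side_effect
    # no side-effect mediation in plain continuation selection
    (proc3a,) = identify_processes(_graph("fig3a"))
    assert not proc3a.mediated_by_side_effect


def test_classify_multifactorial_selection_in_exposure():
    g = _graph("fig2c")
    (proc,) = identify_processes(g)
    c = classify(proc, g)
    assert (c.level, c.mechanism, c.timing, c.factors) == (
        "population",
        "in_exposure",
        "at_exposure_entry",
        "multifactorial",
    )
    assert c.cell_code == "1.1.1"


def test_classify_reversed_causality_is_post_outcome():
    g = _graph("fig4a")
    (proc,) = identify_processes(g)
    c = classify(proc, g)
    assert c.cell_code == "1.1.3"
    assert c.factors == "unifactorial"


def test_classify_competing_event_during_exposure():
    g = _graph("fig3c")
    (proc,) = identify_processes(g)
    c = classify(proc, g)
    assert c.cell_code == "1.2.2"
    assert c.mechanism == "in_population_composition"


def test_golden_cells_for_all_builtin_templates():
    """Every figure template classifies to its framework cell."""
    for name, expected in GOLDEN.items():
        report = framework_report(_graph(name))
        got = dict(zip(report.target, report.cell_code))
        assert got == expected, f"{name}: {got} != {expected}"


def test_scenario_expected_cells_agree_with_golden_file():
    for name, expected in GOLDEN.items():
        assert make_scenario(name).expected_cells == expected


@pytest.mark.parametrize("name", sorted(GOLDEN))
def test_study_specific_toggle_changes_only_level_digit(name):
    g = _graph(name)
    report = framework_report(g)
    for target, cell in zip(report.target, report.cell_code):
        nodes = [
            dataclasses.replace(n, study_specific=True) if n.id == target else n
            for n in g.nodes
        ]
        toggled = framework_report(CausalGraph(nodes, g.edges))
        got = dict(zip(toggled.target, toggled.cell_code))[target]
        assert got == "2" + cell[1:]


@pytest.mark.parametrize("shift", [1, 3])
@pytest.mark.parametrize("name", sorted(GOLDEN))
def test_time_shift_invariance(name, shift):
    """Time indices are ordinal labels: shifting all of them changes nothing."""
    g = _graph(name)
    nodes = [dataclasses.replace(n, time=n.time + shift) for n in g.nodes]
    shifted = framework_report(CausalGraph(nodes, g.edges), labels={})
    base = framework_report(g, labels={})
    assert list(shifted.cell_code) == list(base.cell_code)
    assert list(shifted.factors) == list(base.factors)


def test_adding_an_origin_variable_never_changes_timing():
    g = _graph("fig2a")
    spec = g.to_spec()
    spec["nodes"].append({"id": "U0", "variable": "U", "time": 0, "role": "unknown_cause"})
    spec["edges"].append(["U0", "E1"])
    extended = build_graph(spec)
    base = classify(identify_processes(g)[0], g)
    ext = classify(identify_processes(extended)[0], extended)
    assert ext.timing == base.timing
    assert ext.factors == "multifactorial"


def test_classifier_is_pure():
    g = _graph("fig3d")
    r1 = framework_report(g)
    r2 = framework_report(g)
    assert r1.equals(r2)


def test_report_empty_for_edgeless_graph():
    g = build_graph({"nodes": [{"id": "E1", "role": "exposure"}], "edges": []})
    assert framework_report(g).empty


def test_no_exposure_graph_warns_and_defaults_timing():
    g = build_graph(
        {
            "nodes": [
                {"id": "C0"},
                {"id": "S1", "role": "selection", "conditioned": True},
            ],
            "edges": [["C0", "S1"]],
        }
    )
    (proc,) = identify_processes(g)
    with pytest.warns(UserWarning, match="no exposure node"):
        c = classify(proc, g)
    assert c.timing == "at_exposure_entry"


def test_canonical_labels_attached_from_registry():
    report = framework_report(_graph("fig4b"))
    assert report.label.iloc[0] == "Berkson's fallacy"
    # unrecognized structures get no label rather than an invented one
    g = build_graph(
        {
            "nodes": [{"id": "A0"}, {"id": "E1", "role": "exposure"}],
            "edges": [["A0", "E1"]],
        }
    )
    assert framework_report(g).label.iloc[0] == ""


def test_persistence_edges_do_not_count_toward_factors():
    g = _graph("fig3a")  # E1 <- {E0, C0}
    (proc,) = identify_processes(g)
    assert classify(proc, g).factors == "unifactorial"
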