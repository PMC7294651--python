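"""Three-dimensional classification of selection processes.

A *selection process* is any bundle of arrows producing a non-random
split of a population: arrows into an exposure node (selection in
exposure) or into a conditioned node (selection in population
composition). Each identified process is classified on three dimensions:

* **level** — population (1) vs. study-specific (2),
* **mechanism** — selection in exposure (1) vs. in population
  composition (2),
* **timing** — at exposure entry (1), during exposure/follow-up (2),
  post-outcome (3),

yielding a cell code ``L.M.T`` (e.g. ``1.2.3`` = Berkson's fallacy).
Uni- vs. multifactorial origin is reported as a derived attribute, not
a fourth axis. The classifier is a pure function of the graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import GraphError
from .graph import CausalGraph

__all__ = [
    "SelectionProcess",
    "Classification",
    "identify_processes",
    "classify",
    "framework_report",
]


@dataclass(frozen=True)
class SelectionProcess:
    """A classification target: a node receiving directed selection.

    ``target`` is an exposure node with at least one cause, or any
    conditioned ("boxed") node; ``origins`` are its parents.
    ``mediated_by_side_effect`` is true when some origin descends from an
    earlier exposure node (e.g. smoking -> cough -> quitting).
    """

    target: str
    origins: frozenset[str]
    mediated_by_side_effect: bool = False


@dataclass(frozen=True)
class Classification:
    """Where a selection process sits in the three-dimensional framework."""

    level: str  # population | study_specific
    mechanism: str  # in_exposure | in_population_composition
    timing: str  # at_exposure_entry | during_exposure | post_outcome
    factors: str  # unifactorial | multifactorial
    cell_code: str  # "L.M.T"
    label: str = ""  # canonical epidemiological synonym, may be empty

    def __post_init__(self) -> None:
        expected = "{}.{}.{}".format(
            {"population": 1, "study_specific": 2}[self.level],
            {"in_exposure": 1, "in_population_composition": 2}[self.mechanism],
            {"at_exposure_entry": 1, "during_exposure": 2, "post_outcome": 3}[
                self.timing
            ],
        )
        if self.cell_code != expected:
            raise ValueError(
                f"cell_code {self.cell_code!r} inconsistent with dimensions "
                f"(expected {expected!r})"
            )


def identify_processes(graph: CausalGraph) -> list[SelectionProcess]:
    """All selection processes in a graph, ordered by (target time, id).

    One process per exposure node with in-degree >= 1 and one per
    conditioned node. Graphs without such targets yield an empty list.
    """
    targets = []
    for n in graph.nodes:
        if n.role == "exposure" and graph.parents(n.id):
            targets.append(n)
        elif n.conditioned:
            targets.append(n)
    targets.sort(key=lambda n: (n.time, n.id))

    exposure_ids = {n.id for n in graph.nodes_with_role("exposure")}
    out = []
    for t in targets:
        origins = graph.parents(t.id)
        mediated = any(
            graph.node(o).role != "exposure"
            and any(
                e in graph.ancestors(o)
                and graph.node(e).time < t.time
                for e in exposure_ids
            )
            for o in origins
        )
        out.append(
            SelectionProcess(
                target=t.id,
                origins=frozenset(origins),
                mediated_by_side_effect=mediated,
            )
        )
    return out


_LEVEL_DIGIT = {"population": "1", "study_specific": "2"}
_MECH_DIGIT = {"in_exposure": "1", "in_population_composition": "2"}
_TIMING_DIGIT = {"at_exposure_entry": "1", "during_exposure": "2", "post_outcome": "3"}


def classify(
    process: SelectionProcess, graph: CausalGraph, label: str = ""
) -> Classification:
    """Classify one selection process on the three framework dimensions.

    Timing precedence is post_outcome > during_exposure >
    at_exposure_entry: a direct outcome parent at an earlier time marks
    post-outcome selection; otherwise any exposure node strictly earlier
    than the target means selection happened while exposure was ongoing;
    otherwise the process acts at exposure entry. Persistence arrows
    (same variable, earlier time) do not count toward the factor count,
    so exposure continuation is not spuriously "multifactorial".
    """
    target = graph.node(process.target)
    if process.origins != frozenset(graph.parents(target.id)):
        raise GraphError(
            f"process for {target.id!r} does not match the graph's parent set"
        )
    if target.role != "exposure" and not target.conditioned:
        raise GraphError(
            f"node {target.id!r} is neither an exposure nor conditioned; "
            f"not a selection-process target"
        )

    mechanism = (
        "in_exposure" if target.role == "exposure" else "in_population_composition"
    )
    level = "study_specific" if target.study_specific else "population"

    origin_nodes = [graph.node(o) for o in process.origins]
    if any(o.role == "outcome" and o.time < target.time for o in origin_nodes):
        timing = "post_outcome"
    else:
        exposures = graph.nodes_with_role("exposure")
        if not exposures and not target.role == "exposure":
            warnings.warn(
                f"graph has no exposure node; timing of {target.id!r} "
                f"defaults to at_exposure_entry",
                stacklevel=2,
            )
            timing = "at_exposure_entry"
        elif any(e.time < target.time for e in exposures):
            timing = "during_exposure"
        else:
            timing = "at_exposure_entry"

    external = {
        o.variable
        for o in origin_nodes
        if not (o.variable == target.variable and o.time < target.time)
    }
    factors = "multifactorial" if len(external) >= 2 else "unifactorial"

    cell = ".".join(
        (_LEVEL_DIGIT[level], _MECH_DIGIT[mechanism], _TIMING_DIGIT[timing])
    )
    return Classification(
        level=level,
        mechanism=mechanism,
        timing=timing,
        factors=factors,
        cell_code=cell,
        label=label,
    )


def framework_report(graph: CausalGraph, labels: dict[str, str] | None = None) -> pd.DataFrame:
    """Classify every selection process in ``graph``.

    Returns one row per process (stable order) with columns: target,
    origins, level, mechanism, timing, factors, cell_code, label,
    bias_prone. ``labels`` optionally maps target ids to canonical
    epidemiological names; by default the builtin scenario registry is
    consulted for a structural match.

    ``bias_prone`` flags the structures most associated with distorted
    internal validity — a conditioned collider, or a multifactorial
    exposure process with an unknown origin. Whether bias actually
    occurs must be judged case by case; the flag marks structure only.
    """
    if labels is None:
        from .scenarios import lookup_labels  # local import: avoid cycle

        labels = lookup_labels(graph)

    rows = []
    for proc in identify_processes(graph):
        c = classify(proc, graph, label=labels.get(proc.target, ""))
        origin_nodes = [graph.node(o) for o in proc.origins]
        bias_prone = (
            graph.node(proc.target).conditioned and len(proc.origins) >= 2
        ) or (
            c.mechanism == "in_exposure"
            and c.factors == "multifactorial"
            and any(o.role == "unknown_cause" for o in origin_nodes)
        )
        rows.append(
            {
                "target": proc.target,
                "origins": ",".join(sorted(proc.origins)),
                "mediated_by_side_effect": proc.mediated_by_side_effect,
                "level": c.level,
                "mechanism": c.mechanism,
                "timing": c.timing,
                "factors": c.factors,
                "cell_code": c.cell_code,
                "label": c.label,
                "bias_prone": bias_prone,
            }
        )
    columns = [
        "target",
        "origins",
        "mediated_by_side_effect",
        "level",
        "mechanism",
        "timing",
        "factors",
        "cell_code",
        "label",
        "bias_prone",
    ]
    return pd.DataFrame(rows, columns=columns)
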