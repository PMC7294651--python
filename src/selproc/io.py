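"""Model-spec JSON and cohort/report CSV serialization.

The model-spec dialect (one JSON document) has top-level keys:

``nodes``
    list of ``{id, variable?, time?, role?, conditioned?, study_specific?}``
    (variable/time are parsed from the id when omitted; role defaults to
    "covariate"; booleans default false),
``edges``
    list of ``[tail, head]`` pairs,
``tables``
    ``{node: {"parents": [...], "p1": {"C0=1,U0=0": prob, ...}}}``; root
    nodes may abbreviate ``p1`` to a bare number,
``cohort_size``
    positive number N.

CSV is the single tabular format: UTF-8, "." decimal separator, one row
per configuration in canonical binary order, unrounded numbers with
display-precision duplicates in separate columns, undefined estimates as
an empty value plus a status column — all so that diffs are bit-stable.
"""

from __future__ import annotations

import json
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import Cohort, ConditionalTable, StructuralModel
from .errors import SpecError
from .estimators import EffectEstimate
from .graph import CausalGraph, build_graph

__all__ = [
    "read_model_spec",
    "write_model_spec",
    "read_graph_spec",
    "write_cohort",
    "read_cohort",
    "write_report",
    "estimates_frame",
    "format_risk",
    "format_ratio",
]


def format_risk(value: float | None) -> str:
    """Display convention: risks as whole percent."""
    return "" if value is None else f"{round(value * 100):.0f}%"


def format_ratio(value: float | None) -> str:
    """Display convention: ratio measures to two decimals."""
    return "" if value is None else f"{value:.2f}"


# ---------------------------------------------------------------------------
# model specs


def read_graph_spec(source) -> CausalGraph:
    """Graph-only spec (``nodes`` + ``edges``) from a path, file object or
    already-parsed mapping."""
    data = _load(source)
    _require(data, "nodes", "$")
    return build_graph(data)


def _load(source) -> Mapping:
    if isinstance(source, Mapping):
        return source
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SpecError(f"not valid JSON: {exc}", path="$") from exc
    if not isinstance(data, Mapping):
        raise SpecError("top level must be a JSON object", path="$")
    return data


def _require(data: Mapping, key: str, path: str):
    if key not in data:
        raise SpecError(f"missing required key {key!r}", path=path)
    return data[key]


def _parse_assignment(key: str, graph: CausalGraph, path: str) -> dict[str, int]:
    out: dict[str, int] = {}
    if not key:
        return out
    for part in key.split(","):
        name, sep, value = part.partition("=")
        if not sep:
            raise SpecError(f"configuration key part {part!r} is not name=value", path=path)
        try:
            node_id = graph.resolve(name.strip())
        except Exception as exc:
            raise SpecError(str(exc), path=path) from exc
        if value.strip() not in ("0", "1"):
            raise SpecError(f"value for {name!r} must be 0 or 1", path=path)
        out[node_id] = int(value)
    return out


def read_model_spec(source) -> StructuralModel:
    """Read and fully validate a StructuralModel from the JSON dialect.

    Error messages carry a JSON-path-like locator of the offending field.
    """
    data = _load(source)
    graph = read_graph_spec(data)
    tables_spec = _require(data, "tables", "$")
    if not isinstance(tables_spec, Mapping):
        raise SpecError("must be an object keyed by node id", path="tables")

    tables: dict[str, ConditionalTable] = {}
    for n in graph.nodes:
        path = f"tables.{n.id}"
        if n.id not in tables_spec:
            raise SpecError("missing conditional table for this node", path=path)
        entry = tables_spec[n.id]
        parents = tuple(i for i in graph.node_ids if i in graph.parents(n.id))

        if isinstance(entry, (int, float)):
            if parents:
                raise SpecError(
                    f"bare probability given but node has parents {list(parents)}",
                    path=path,
                )
            tables[n.id] = ConditionalTable(n.id, (), {(): float(entry)})
            continue
        if not isinstance(entry, Mapping):
            raise SpecError("must be a number or an object", path=path)

        declared = tuple(entry.get("parents", parents))
        try:
            declared = tuple(graph.resolve(p) for p in declared)
        except Exception as exc:
            raise SpecError(str(exc), path=f"{path}.parents") from exc
        if set(declared) != set(parents):
            raise SpecError(
                f"declared parents {list(declared)} != graph parents {list(parents)}",
                path=f"{path}.parents",
            )

        p1 = entry.get("p1")
        if isinstance(p1, (int, float)) and not parents:
            tables[n.id] = ConditionalTable(n.id, (), {(): float(p1)})
            continue
        if not isinstance(p1, Mapping):
            raise SpecError("missing or malformed 'p1' map", path=f"{path}.p1")

        probs: dict[tuple[int, ...], float] = {}
        for key, value in p1.items():
            kpath = f"{path}.p1[{key!r}]"
            assignment = _parse_assignment(str(key), graph, kpath)
            if set(assignment) != set(parents):
                raise SpecError(
                    f"configuration must assign exactly the parents {list(parents)}",
                    path=kpath,
                )
            if not isinstance(value, (int, float)):
                raise SpecError("probability must be a number", path=kpath)
            cfg = tuple(assignment[p] for p in parents)
            if cfg in probs:
                raise SpecError("duplicate parent configuration", path=kpath)
            probs[cfg] = float(value)
        tables[n.id] = ConditionalTable(n.id, parents, probs)

    cohort_size = data.get("cohort_size", 1.0)
    if not isinstance(cohort_size, (int, float)) or cohort_size < 0:
        raise SpecError("must be a non-negative number", path="cohort_size")
    return StructuralModel(graph, tables, float(cohort_size))


def write_model_spec(model: StructuralModel, path=None) -> dict:
    """Serialize a model back to the JSON dialect (round-trips through
    :func:`read_model_spec` up to canonical ordering)."""
    spec = model.graph.to_spec()
    tables = {}
    for node_id in model.graph.node_ids:
        table = model.tables[node_id]
        p1 = {}
        for cfg in product((0, 1), repeat=len(table.parent_order)):
            key = ",".join(f"{p}={v}" for p, v in zip(table.parent_order, cfg))
            p1[key] = table.p1(cfg)
        tables[node_id] = {"parents": list(table.parent_order), "p1": p1}
    spec["tables"] = tables
    spec["cohort_size"] = model.cohort_size
    if path is not None:
        Path(path).write_text(
            json.dumps(spec, indent=2, sort_keys=False) + "\n", encoding="utf-8"
        )
    return spec


# ---------------------------------------------------------------------------
# cohorts


def write_cohort(cohort: Cohort, path) -> None:
    """CSV with one row per configuration in canonical binary order:
    variable columns, unrounded count, selected flag."""
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(source) -> Cohort:
    """Rebuild a Cohort from :func:`write_cohort` output; counts round-trip
    exactly. Conditioning metadata is not stored in CSV, so selection
    state is inferred from the ``selected`` column."""
    df = pd.read_csv(source)
    meta = {"count", "selected"}
    variables = tuple(c for c in df.columns if c not in meta)
    if not variables or "count" not in df.columns:
        raise SpecError("cohort CSV needs variable columns and a 'count' column", path="$")
    k = len(variables)
    counts = np.zeros(2**k)
    excluded = np.zeros(2**k)
    selected_col = df["selected"] if "selected" in df else pd.Series(True, index=df.index)
    has_excluded = bool((~selected_col.astype(bool)).any())
    for _, row in df.iterrows():
        idx = 0
        for v in variables:
            idx = (idx << 1) | int(row[v])
        if bool(selected_col.loc[row.name]):
            counts[idx] += float(row["count"])
        else:
            excluded[idx] += float(row["count"])
    return Cohort(
        variables=variables,
        counts=counts,
        mode="expected" if (counts % 1 != 0).any() else "sampled",
        selected_only=has_excluded,
        excluded_counts=excluded if has_excluded else None,
    )


# ---------------------------------------------------------------------------
# reports


def estimates_frame(estimates: Iterable[EffectEstimate]) -> pd.DataFrame:
    """Tabulate estimates: unrounded value, display duplicate, status."""
    rows = []
    for est in estimates:
        display = (
            format_risk(est.value) if est.measure == "risk" else format_ratio(est.value)
        )
        rows.append(
            {
                "measure": est.measure,
                "method": est.method,
                "stratum": ",".join(f"{k}={v}" for k, v in sorted(est.stratum.items())),
                "value": est.value if est.defined else "",
                "value_display": display,
                "status": "ok" if est.defined else "undefined",
            }
        )
    return pd.DataFrame(
        rows, columns=["measure", "method", "stratum", "value", "value_display", "status"]
    )


def write_report(report: pd.DataFrame, path) -> None:
    """Write any report frame as deterministic CSV (UTF-8, '.' decimals)."""
    df = report.copy()
    if "value" in df.columns and "value_display" not in df.columns:
        df["value_display"] = [
            format_ratio(v) if isinstance(v, (int, float)) and not pd.isna(v) else ""
            for v in df["value"]
        ]
    df.to_csv(path, index=False)
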