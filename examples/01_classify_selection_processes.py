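"""Classify every selection process in a causal diagram.

Builds a small time-indexed DAG by hand — a covariate C measured at t=0
that influences who becomes exposed at t=1, with a disease outcome at
t=2 — and prints the framework report: one row per selection process
with its level (population vs. study-specific), mechanism (in exposure
vs. in population composition), timing (at exposure entry / during
exposure / post-outcome) and cell code.
"""

from selproc import build_graph, framework_report

graph = build_graph(
    {
        "nodes": [
            {"id": "C0", "role": "covariate"},
            {"id": "E1", "role": "exposure"},
            {"id": "D2", "role": "outcome"},
        ],
        "edges": [["C0", "E1"], ["C0", "D2"], ["E1", "D2"]],
    }
)

report = framework_report(graph)
print(report.to_string(index=False))
print()
print(
    "One process: the arrow C0 -> E1 selects who becomes exposed "
    f"(cell {report.cell_code.iloc[0]} = population-level selection in "
    "exposure at exposure entry); because C also causes D it is flagged "
    "as the classic confounding structure."
)
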