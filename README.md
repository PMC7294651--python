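# selproc

Selection processes — non-random splits of a population with respect to
exposure, health status or membership — are ubiquitous in observational
research, and they are routinely conflated with their consequences
(confounding, collider stratification bias, loss of external validity).
`selproc` is a toolkit for epidemiologists and methods researchers who
want to make these processes explicit: draw them as time-indexed causal
diagrams, classify them systematically, simulate them exactly, and watch
how they distort standard effect estimators.

The package has four layers:

1. **Causal graphs** (`selproc.graph`) — binary variables at discrete
   time windows (`E1` = exposure in window 1), with roles (exposure,
   outcome, covariate, unknown cause, selection, side effect) and
   "boxed" nodes that mark conditioning by nature (survival, disease
   incidence) or by design.
2. **Taxonomy** (`selproc.taxonomy`) — every arrow into an exposure node
   and every conditioned node is a selection process, classified on
   three dimensions into a cell code `L.M.T`:
   * **L**evel: population (1) vs. study-specific (2),
   * **M**echanism: selection in exposure (1) vs. in population
     composition (2),
   * **T**iming: at exposure entry (1), during exposure (2),
     post-outcome (3),
   plus derived attributes (uni-/multifactorial origin, side-effect
   mediation). Cell 1.1.1 is the healthy worker hire effect; 1.2.3 is
   Berkson's fallacy.
3. **Engine** (`selproc.engine`) — a binary structural causal model per
   graph: exact joint enumeration P(x) = ∏ᵥ P(xᵥ | pa(v)) over all 2^k
   configurations, conditioning, marginalization, expected-count cohorts
   (counts = N·P) and seeded ancestral Monte-Carlo sampling.
4. **Estimators** (`selproc.estimators`) — risks, crude/stratified risk
   ratios, the Mantel–Haenszel summary RR_MH = Σᵢaᵢn₀ᵢ/Tᵢ ÷ Σᵢcᵢn₁ᵢ/Tᵢ,
   directly standardized RRs, cross-product odds ratios, and inverse
   probability weighting with saturated propensities
   wᵢ = 1/P(Eᵢ | covariates).

A registry (`selproc.scenarios`) ships ready-made models for the
canonical phenomena — healthy worker hire and survivor effects,
side-effect-mediated exposure change, competing events, depletion of
susceptibles, index event bias, reversed causality, Berkson's fallacy —
each with a machine-checked qualitative bias signature, plus the worked
4000-person cohort with multifactorial selection in exposure.

## Worked example

The worked cohort: exposure E is selected by a known cause C and an
unknown cause U (P(C)=P(U)=½; P(E=1|C,U) = 0.10/0.30/0.20/0.50), and the
disease risk is P(D=1|E,C,U) = 0.10 · 2^E · (1.5(1−U)+4U)^C — a
homogeneous exposure effect (RR 2.0 in every C×U stratum) with a C×U
interaction on the outcome.

```python
from selproc import expected_cohort, risk_ratio, table1_model

cohort = expected_cohort(table1_model())          # N = 4000, exact counts
print(cohort.count({"C0": 1, "U0": 1, "E1": 1, "D2": 1}))
print([e.value for e in risk_ratio(cohort, "E", "D", ["C0", "U0"])])
print({e.stratum["C0"]: round(e.value, 2)
       for e in risk_ratio(cohort, "E", "D", ["C0"])})
```

prints

```
400.0
[2.0, 2.0, 2.0, 2.0]
{0: 2.0, 1: 2.41}
```

400 is the expected number of exposed cases in the C=1, U=1 stratum; the
effect is exactly 2.0 in all four C×U strata; but collapsing over the
unmeasured U inflates the C=1 stratum estimate to 2.41 — adjustment for
the known selection origin alone does not remove the bias, and
stratifying on C suggests a spurious effect heterogeneity. Running
`python examples/04_ipw_correction.py` shows the full contrast: crude
3.05, Mantel–Haenszel over C 2.34, IPW over C 2.29, IPW over {C, U}
2.0000 (with saturated weights, IPW equals standardization to the total
population).

More narrative walk-throughs live in `examples/`:

* `01_classify_selection_processes.py` — framework report for a DAG,
* `02_worked_cohort.py` — the exact expected cohort and its estimates,
* `03_collider_bias.py` — index event bias via conditioning by nature,
* `04_ipw_correction.py` — adjustment vs. IPW and the covariate set.

There is also a thin CLI:

```bash
selproc classify examples/models/table1.json
selproc demo berkson
selproc simulate examples/models/table1.json --sample 100000 --seed 7 --out cohort.csv
selproc estimate cohort.csv --exposure E1 --outcome D2 --strata C0,U0
```

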