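# Methods

## The model

`selproc` works with binary structural causal models over time-indexed
DAGs. Each node is a Bernoulli variable observed in a discrete time
window; time indices are ordinal labels only (no durations), used solely
to order events. Every arrow is read two ways: as a direct causal effect
and as a directed selection process — `C0 → E1` makes C-positive
individuals over-represented among the exposed, splitting the population
non-randomly. Boxed (conditioned) nodes mark **conditioning by nature**:
once the population has been filtered on that node's retained level
(survival, incident disease, eligibility), all downstream causal action
happens in the selected subpopulation only.

The joint law factorizes over the DAG, P(x) = ∏ᵥ P(xᵥ | pa(v)), and is
enumerated exactly over all 2^k configurations. Everything downstream —
conditioning, marginalization, expected cohorts, estimator bias — is
therefore exact arithmetic, not approximate inference: when the package
says a collider induces OR = 0.4, that number has no Monte-Carlo error.
Enumeration is capped at k = 20 nodes (2^20 configurations, ~8 MB of
mass); every builtin scenario has k ≤ 6. Monte-Carlo cohorts exist for
finite-sample work and use ancestral sampling in a deterministic
topological order (sorted by time, then variable) from a single
`numpy.random.default_rng` (PCG64) generator per call, so a fixed seed
gives bit-identical cohorts across platforms.

## The classifier

A **selection process** is a target node together with its incoming
arrows: one per exposure node with in-degree ≥ 1 and one per conditioned
node. Classification is a pure function of graph structure:

* **mechanism** — in exposure if the target is an exposure node,
  otherwise in population composition (the target is conditioned);
* **timing** — post-outcome if some *direct* parent is an outcome node
  at an earlier time; otherwise during exposure if any exposure node
  exists strictly earlier than the target; otherwise at exposure entry.
  The precedence is post-outcome > during > at-entry. Post-outcome
  triggers only on a direct outcome parent, not on any outcome ancestor:
  both canonical post-outcome structures (reversed causality,
  Berkson-type participation) have the direct arrow, and an
  ancestor-based rule would misfile depletion-of-susceptibles chains.
* **level** — study-specific iff the target is flagged as created by the
  study; this flips only the first digit of the cell code.
* **factors** (derived attribute, not an axis) — multifactorial iff at
  least two distinct origin *variables* remain after discarding
  persistence arrows (same variable at an earlier time). Without that
  exclusion every exposure-continuation process would count its own past
  as a second factor.

An index-event structure (exposure and an unknown factor jointly causing
entry into the study-defining population) is modelled with the exposure
and the collider in the *same* time window: the selection happens at
exposure entry, not during an ongoing exposure, and the classifier's
timing rule reads exactly that off the time indices. Same-window arrows
are permitted generally but warned about, since they are easy to create
by accident.

Canonical labels ("Berkson's fallacy", "healthy worker survivor
effect", …) are attached only when a graph structurally matches a
registry scenario; the classifier never invents terminology for cells it
cannot name, and several framework cells legitimately carry no label.
The report flags *bias-prone* structures (a conditioned collider, or a
multifactorial exposure process with an unknown origin) but deliberately
does not declare bias: whether a selection process damages a given
analysis depends on the research question and the estimand, so the flag
marks structure only.

One representational extension was needed: conditioned nodes carry a
`condition_value` (default 1). Depletion of susceptibles conditions the
population at risk on the *absence* of the early outcome (survivors,
D1 = 0), which a fixed convention of "keep level 1" cannot express.

## Estimators

All estimators run on configuration counts — never on model parameters —
so the identical code path serves exact expected cohorts (counts = N·P,
real-valued, never rounded internally) and sampled integer cohorts.
Zero denominators and empty exposure arms yield *undefined* estimates
carried as values in reports, not exceptions, and no continuity
corrections are applied. Display rounding (risks to whole percent,
ratios to two decimals) happens only at serialization.

IPW uses saturated propensities — the empirical exposure frequency per
covariate pattern — rather than a parametric propensity model, which
would introduce an arbitrary specification choice the problem does not
need. Two identities anchor the implementation and are verified to
1e-10 in the tests: saturated IPW over a covariate set equals direct
standardization of the same cohort to its total population, and on an
unselected expected cohort the fitted propensities coincide with the
model's true ones. Model-based weights (`weight_source="true_model"`)
are available to demonstrate what an analyst who could measure the
unknown causes would obtain; they raise an error when the model assigns
an observed exposure level zero probability (a positivity violation).

## The worked cohort

The `table1` scenario encodes the reference hypothetical cohort:
P(C)=P(U)=½ independently, P(E=1|C,U) = 0.10/0.30/0.20/0.50 for
(C,U) = (0,0)/(1,0)/(0,1)/(1,1), and
P(D=1|E,C,U) = 0.10 · 2^E · (1.5(1−U)+4U)^C. The cohort size N = 4000 is
forced by the printed stratum counts (four C×U strata of 1000); with it
the expected cohort reproduces all sixteen cell counts exactly, the
stratum risk ratios are 2.0 throughout, and the C-stratified totals are
2.0 (C=0) and 2.41 (C=1).

One printed summary is deliberately not reproduced: the totals-row
exposure RR of 2.32. The crude RR of the printed counts is 3.05, the
Mantel–Haenszel RR over C is 2.34, and the totally standardized RR over
C is 2.29; no standard C-adjusted summary yields 2.32 and the adjustment
method behind it is unstated. The package reports all standard summaries
and leaves the 2.32 undocumented rather than reverse-engineering an
unnamed estimator.

## The scenario generator

The registry's role is to *emulate the mechanisms*, not any particular
dataset: each scenario is the minimal DAG exhibiting one phenomenon,
with constant default probabilities. Only `table1` uses published worked
numbers; all other defaults are this package's own choices, fixed once,
in [0.05, 0.95], and selected so the scenario's qualitative signature
holds under exact enumeration:

| scenario | mechanism emulated | key defaults |
|---|---|---|
| fig2a / healthy_worker_hire | confounded selection in exposure | P(E\|C)=0.2/0.6; P(D)=0.1·2^E·2^C |
| fig2b | composition change, exposure unaffected | P(S\|C)=0.3/0.8; P(E)=0.4 |
| fig2c | multifactorial selection in exposure | P(E\|C,U) as in table1 |
| fig2d / index_event | collider at exposure entry | P(S\|E,U)=0.1+0.3E+0.4U; P(D\|U)=0.1/0.3 |
| fig3a / healthy_worker_survivor | selection in continuation | P(E1\|E0=1,C)=0.8/0.5, else 0.05 |
| fig3b | side-effect-mediated quitting | P(A\|E0)=0.05/0.4; P(E2\|E0=1,A)=0.8/0.3 |
| fig3c | competing event | P(S\|E,U)=0.9−0.3E−0.3U; P(D\|E,U)=0.1·2^E·3^U |
| fig3d / depletion | depletion of susceptibles | P(D1\|E,U)=0.1+0.2E+0.4U; P(D2\|E,U)=0.1·2^E·4^U |
| fig4a | reversed causality | P(D0)=0.3; P(E\|D0)=0.2/0.6 |
| fig4b / berkson | post-outcome participation | P(S\|E,D)=0.1+0.3E+0.4D |

Two non-obvious numerical choices. First, every *selection/collider*
table is additive on the risk scale: a multiplicative P(S|causes)
factorizes into per-cause terms, and conditioning on a collider whose
table factorizes induces **no** association at all — additive tables are
the simplest parameterization in which collider bias actually exists.
Second, exposure-continuation scenarios carry explicit persistence
arrows (E0 → E1), and their effect contrast is continued exposure vs.
quit.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: continuous or multi-level variables,
time-to-event structure (the "during exposure" window is one discrete
step), measurement error, parametric propensity misspecification (all
fits are saturated), and sampling designs beyond simple random draws
from the population law. Scenario cohorts demonstrate mechanisms;
calibrating them to real registers is out of scope, and the real-world
anecdotes in scenario descriptions are documentation, not data.

## Bias reports

`bias_report` contrasts, for each scenario with a downstream outcome:
the true standardized RR (all covariates including unknown causes, on
the pre-selection cohort), the crude RR on the analysis (post-selection)
cohort, the Mantel–Haenszel RR adjusted for observed covariates only,
and IPW with the observed vs. the full covariate set — each with
absolute and relative bias against the truth. Reversed causality has no
later outcome to estimate against, so its report carries only the
qualitative signature (the cross-lagged exposure–outcome association):
reporting an "RR bias" there would manufacture an estimand the structure
does not define.

## Problem sizes and determinism

Exactness makes the default problem sizes small: enumeration over ≤ 2^6
configurations, expected cohorts of N = 4000 (table1) or 10000 (other
scenarios), and Monte-Carlo checks at n = 100,000 draws, where sampled
configuration frequencies are required to sit within 4 binomial standard
errors of the enumerated masses and sampled risk ratios within 4
standard errors on the log scale. All sampling in tests and scripts is
seeded; identical invocations produce byte-identical outputs, and the
CLI logs the model-spec hash and seed for every run.

## Known limitations

* Binary variables only; no do-calculus beyond the all-exposed vs.
  all-unexposed standardization contrast; no d-separation or
  adjustment-set identification — the classifier reads arrows, it does
  not solve identifiability.
* At most one exposure variable and one outcome variable per graph
  (multiple time indices of each are allowed).
* The taxonomy's "intentional vs. unintentional" distinction for
  study-specific selection has no structural signature in a DAG and is
  supported only as free-text annotation.
* Saturated propensities require every covariate pattern to contain both
  exposure arms; sparse sampled cohorts can make IPW undefined where the
  expected cohort is fine.
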