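"""Index event bias: conditioning by nature on a collider.

In the index-event scenario an exposure E and an unknown factor U both
cause entry into an index population S (say, incident disease), and
disease progression D is then studied among S=1 only. E and U are
exactly independent in the population, but conditioning on the collider
S induces an inverse association between them — and since U drives
progression, E acquires a spurious "protective" association with D.
"""

from selproc import expected_cohort, make_scenario, odds_ratio, risk_ratio

scenario = make_scenario("index_event")
population = expected_cohort(scenario.model)
selected = scenario.analysis_cohort()  # conditioned by nature on S=1

print("OR(E, U) in the whole population: ",
      f"{odds_ratio(population, 'E', 'U').value:.3f}")
print("OR(E, U) among the index population (S=1):",
      f"{odds_ratio(selected, 'E', 'U').value:.3f}")
print("RR(E -> progression D) among S=1:          ",
      f"{risk_ratio(selected, 'E', 'D')[0].value:.3f}")
print()
print("E has no causal effect on D (their OR is 1.0 before selection), "
      "yet among the selected the exposed look protected because they "
      "carry less of the unknown co-cause U — collider stratification "
      "bias, exactly as enumeration predicts.")
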