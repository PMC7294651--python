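"""Correcting selection in exposure: adjustment vs. inverse probability
weighting, and why the covariate set matters more than the method.

On the worked cohort the true exposure effect is RR 2.0. Adjusting for
the known selection origin C alone — by Mantel-Haenszel stratification
or by IPW — leaves residual bias because the unknown origin U is still
unbalanced within C-strata. Weighting (or standardizing) over the full
covariate set recovers the truth exactly.
"""

from selproc import bias_report, make_scenario

report = bias_report(make_scenario("table1"))

print(f"True (standardized) RR: {report.truth:.4f}")
print()
print(report.to_frame().to_string(index=False))
print()
print("Qualitative signatures under exact enumeration:")
for description, holds in report.signatures:
    print(f"  [{'pass' if holds else 'FAIL'}] {description}")
print()
print("Crude = 3.05, C-only summaries ~2.3 (still biased), full-covariate "
      "IPW = 2.0000: with saturated weights IPW equals standardization to "
      "the total population, and only the full covariate set closes the "
      "backdoor through U.")
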