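"""Effect estimators on configuration-count cohorts.

Risks, crude/stratified risk ratios, Mantel-Haenszel and directly
standardized summaries, induced-association odds ratios and inverse
probability weighting (IPW). All estimators work on counts — never on
model parameters — so the same code path serves exact expected cohorts
and sampled finite cohorts.

Undefined estimates (zero denominators, empty exposure arms) are carried
as values, not raised: ``EffectEstimate.value is None`` and
``EffectEstimate.defined`` is False. No continuity corrections are
applied. Display rounding (risks to whole percent, ratios to two
decimals) happens only at serialization time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

from .engine import Cohort, StructuralModel, enumerate_joint, prob
from .errors import EstimationError

__all__ = [
    "EffectEstimate",
    "risk",
    "risk_ratio",
    "mh_risk_ratio",
    "standardized_risk_ratio",
    "odds_ratio",
    "ipw_risk_ratio",
]


@dataclass(frozen=True)
class EffectEstimate:
    """One estimated effect measure with its provenance.

    ``numerator_detail``/``denominator_detail`` hold the raw counts that
    entered the computation, so any estimate can be audited (and a Wald
    interval computed) without re-touching the cohort.
    """

    measure: str  # risk | risk_ratio | odds_ratio
    value: float | None
    method: str  # crude | stratified | mantel_haenszel | standardized | ipw
    stratum: dict = field(default_factory=dict)
    numerator_detail: dict = field(default_factory=dict)
    denominator_detail: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.value is not None

    def wald_ci(self, alpha: float = 0.05) -> tuple[float, float] | None:
        """Optional log-scale Wald interval for ratio measures; None when
        counts are unavailable or the estimate is undefined."""
        if not self.defined or self.measure == "risk":
            return None
        num, den = self.numerator_detail, self.denominator_detail
        try:
            if self.measure == "risk_ratio":
                var = (
                    1 / num["cases"]
                    - 1 / num["total"]
                    + 1 / den["cases"]
                    - 1 / den["total"]
                )
            else:  # odds ratio
                var = sum(1 / num[k] for k in ("n11", "n00")) + sum(
                    1 / den[k] for k in ("n10", "n01")
                )
        except (KeyError, ZeroDivisionError):
            return None
        if var < 0:
            return None
        # normal quantile via the error function; alpha=0.05 -> 1.96
        from statistics import NormalDist

        z = NormalDist().inv_cdf(1 - alpha / 2)
        half = z * math.sqrt(var)
        return (self.value * math.exp(-half), self.value * math.exp(half))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def risk(
    cohort: Cohort, outcome: str, given: Mapping[str, int] | None = None
) -> EffectEstimate:
    """P(outcome = 1 | given) from counts; undefined on an empty
    restriction."""
    given = dict(given or {})
    outcome = cohort.resolve(outcome)
    denom = cohort.count(given)
    numer = cohort.count({**given, outcome: 1})
    return EffectEstimate(
        measure="risk",
        value=_ratio(numer, denom),
        method="crude",
        stratum=given,
        numerator_detail={"cases": numer},
        denominator_detail={"total": denom},
    )


def _rr_in(
    cohort: Cohort,
    exposure: str,
    outcome: str,
    stratum: Mapping[str, int],
    method: str,
) -> EffectEstimate:
    a = cohort.count({**stratum, exposure: 1, outcome: 1})
    n1 = cohort.count({**stratum, exposure: 1})
    c = cohort.count({**stratum, exposure: 0, outcome: 1})
    n0 = cohort.count({**stratum, exposure: 0})
    r1 = _ratio(a, n1)
    r0 = _ratio(c, n0)
    value = None if (r1 is None or r0 is None or r0 == 0) else r1 / r0
    return EffectEstimate(
        measure="risk_ratio",
        value=value,
        method=method,
        stratum=dict(stratum),
        numerator_detail={"cases": a, "total": n1},
        denominator_detail={"cases": c, "total": n0},
    )


def _strata_assignments(
    cohort: Cohort, strata: Sequence[str]
) -> list[dict[str, int]]:
    names = [cohort.resolve(s) for s in strata]
    out = []
    for values in product((0, 1), repeat=len(names)):
        assignment = dict(zip(names, values))
        if cohort.count(assignment) > 0:
            out.append(assignment)
    return out


def risk_ratio(
    cohort: Cohort,
    exposure: str,
    outcome: str,
    strata: Sequence[str] = (),
) -> list[EffectEstimate]:
    """Risk ratio of exposure on outcome, crude (empty ``strata``) or one
    estimate per observed stratum of the listed variables."""
    exposure = cohort.resolve(exposure)
    outcome = cohort.resolve(outcome)
    if not strata:
        return [_rr_in(cohort, exposure, outcome, {}, "crude")]
    return [
        _rr_in(cohort, exposure, outcome, s, "stratified")
        for s in _strata_assignments(cohort, strata)
    ]


def mh_risk_ratio(
    cohort: Cohort,
    exposure: str,
    outcome: str,
    strata: Sequence[str],
) -> EffectEstimate:
    """Mantel-Haenszel common risk ratio over strata:
    sum_i a_i n0_i / T_i  divided by  sum_i c_i n1_i / T_i."""
    exposure = cohort.resolve(exposure)
    outcome = cohort.resolve(outcome)
    assignments = _strata_assignments(cohort, strata) or [{}]
    num = den = 0.0
    for s in assignments:
        a = cohort.count({**s, exposure: 1, outcome: 1})
        n1 = cohort.count({**s, exposure: 1})
        c = cohort.count({**s, exposure: 0, outcome: 1})
        n0 = cohort.count({**s, exposure: 0})
        t = n1 + n0
        if t == 0:
            continue
        num += a * n0 / t
        den += c * n1 / t
    return EffectEstimate(
        measure="risk_ratio",
        value=_ratio(num, den),
        method="mantel_haenszel",
        numerator_detail={"weighted_cases": num},
        denominator_detail={"weighted_cases": den},
    )


def standardized_risk_ratio(
    cohort: Cohort,
    exposure: str,
    outcome: str,
    strata: Sequence[str],
    weight_source: str = "total",
) -> EffectEstimate:
    """Ratio of stratum-weighted average risks.

    ``weight_source`` chooses the standard population: the whole cohort
    ("total"), the exposed ("exposed") or the unexposed ("unexposed")
    stratum distribution. With total weights this is the marginal causal
    contrast "set everyone exposed vs. everyone unexposed" under the
    model where the strata close all backdoor paths.
    """
    if weight_source not in ("total", "exposed", "unexposed"):
        raise EstimationError(f"unknown weight_source {weight_source!r}")
    exposure = cohort.resolve(exposure)
    outcome = cohort.resolve(outcome)
    assignments = _strata_assignments(cohort, strata) or [{}]
    num = den = wsum = 0.0
    undefined = False
    for s in assignments:
        if weight_source == "total":
            w = cohort.count(s)
        elif weight_source == "exposed":
            w = cohort.count({**s, exposure: 1})
        else:
            w = cohort.count({**s, exposure: 0})
        if w == 0:
            continue
        r1 = _ratio(cohort.count({**s, exposure: 1, outcome: 1}),
                    cohort.count({**s, exposure: 1}))
        r0 = _ratio(cohort.count({**s, exposure: 0, outcome: 1}),
                    cohort.count({**s, exposure: 0}))
        if r1 is None or r0 is None:
            undefined = True
            break
        num += w * r1
        den += w * r0
        wsum += w
    value = None if (undefined or den == 0) else num / den
    return EffectEstimate(
        measure="risk_ratio",
        value=value,
        method="standardized",
        numerator_detail={"weighted_risk": num, "weight_total": wsum},
        denominator_detail={"weighted_risk": den, "weight_total": wsum},
    )


def odds_ratio(
    cohort: Cohort,
    a: str,
    b: str,
    given: Mapping[str, int] | None = None,
) -> EffectEstimate:
    """Cross-product odds ratio of two binary variables within an optional
    restriction; undefined on any zero cell (no continuity correction)."""
    given = dict(given or {})
    a = cohort.resolve(a)
    b = cohort.resolve(b)
    cells = {}
    if a == b:
        value = None
        cells = {"n11": 0.0, "n00": 0.0, "n10": 0.0, "n01": 0.0}
    else:
        for va, vb in product((0, 1), repeat=2):
            cells[f"n{va}{vb}"] = cohort.count({**given, a: va, b: vb})
        num = cells["n11"] * cells["n00"]
        den = cells["n10"] * cells["n01"]
        value = None if (den == 0 or num == 0) else num / den
    return EffectEstimate(
        measure="odds_ratio",
        value=value,
        method="crude",
        stratum=given,
        numerator_detail={k: cells[k] for k in ("n11", "n00")},
        denominator_detail={k: cells[k] for k in ("n10", "n01")},
    )


def ipw_risk_ratio(
    cohort: Cohort,
    exposure: str,
    outcome: str,
    covariates: Sequence[str],
    weight_source: str = "fitted",
    model: StructuralModel | None = None,
) -> EffectEstimate:
    """Risk ratio in the inverse-probability-weighted pseudo-population.

    Each individual is weighted by 1 / P(observed exposure level |
    covariate pattern). Propensities come from saturated empirical
    frequencies per covariate pattern (``weight_source="fitted"``; no
    parametric model) or from the exact structural model
    (``weight_source="true_model"``, which can include unmeasured causes
    the analyst could not fit). With the full, correctly specified
    propensity this equals direct standardization to the total
    population.
    """
    if weight_source not in ("fitted", "true_model"):
        raise EstimationError(f"unknown weight_source {weight_source!r}")
    if weight_source == "true_model" and model is None:
        raise EstimationError("weight_source='true_model' requires a model")
    exposure = cohort.resolve(exposure)
    outcome = cohort.resolve(outcome)
    names = [cohort.resolve(c) for c in covariates]

    joint = enumerate_joint(model) if weight_source == "true_model" else None

    num1 = den1 = num0 = den0 = 0.0
    for pattern_values in product((0, 1), repeat=len(names)):
        pattern = dict(zip(names, pattern_values))
        n_pattern = cohort.count(pattern)
        if n_pattern == 0:
            continue
        if weight_source == "fitted":
            e = cohort.count({**pattern, exposure: 1}) / n_pattern
        else:
            e = prob(joint, {exposure: 1}, given=pattern)
        for level, e_level in ((1, e), (0, 1.0 - e)):
            n_obs = cohort.count({**pattern, exposure: level})
            if n_obs == 0:
                continue
            if e_level == 0.0:
                raise EstimationError(
                    f"zero propensity for observed configuration "
                    f"{pattern} with {exposure}={level}"
                )
            w = 1.0 / e_level
            cases = cohort.count({**pattern, exposure: level, outcome: 1})
            if level == 1:
                num1 += w * cases
                den1 += w * n_obs
            else:
                num0 += w * cases
                den0 += w * n_obs
    r1 = _ratio(num1, den1)
    r0 = _ratio(num0, den0)
    value = None if (r1 is None or r0 is None or r0 == 0) else r1 / r0
    return EffectEstimate(
        measure="risk_ratio",
        value=value,
        method="ipw",
        numerator_detail={"weighted_cases": num1, "weighted_total": den1},
        denominator_detail={"weighted_cases": num0, "weighted_total": den0},
    )
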