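"""Effect estimators against an independent brute-force oracle and the
worked-cohort reference values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selproc import (
    EstimationError,
    ipw_risk_ratio,
    make_scenario,
    mh_risk_ratio,
    odds_ratio,
    risk,
    risk_ratio,
    standardized_risk_ratio,
)
from selproc.scenarios import Scenario

from conftest import (
    make_cohort,
    oracle_mh,
    oracle_or,
    oracle_risk,
    oracle_rr,
)

VARS = ("C", "E", "D")


@st.composite
def random_cohorts(draw):
    counts = {
        cfg: draw(st.integers(0, 30))
        for cfg in [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    }
    return make_cohort(VARS, counts), counts


@given(random_cohorts())
@settings(max_examples=60, derandomize=True)
def test_estimators_match_brute_force_oracle(data):
    cohort, counts = data
    assert risk(cohort, "D", {"E": 1}).value == oracle_risk(counts, VARS, "D", {"E": 1})

    crude = risk_ratio(cohort, "E", "D")[0].value
    assert crude == oracle_rr(counts, VARS, "E", "D", {})

    for est in risk_ratio(cohort, "E", "D", ["C"]):
        want = oracle_rr(counts, VARS, "E", "D", est.stratum)
        assert est.value == want

    assert mh_risk_ratio(cohort, "E", "D", ["C"]).value == oracle_mh(
        counts, VARS, "E", "D", ["C"]
    )
    assert odds_ratio(cohort, "E", "D").value == oracle_or(counts, VARS, "E", "D", {})


@given(random_cohorts(), st.floats(0.1, 100))
@settings(max_examples=30, derandomize=True)
def test_scaling_counts_leaves_estimates_unchanged(data, factor):
    cohort, _ = data
    scaled = cohort.scaled(factor)
    for c in (cohort,):
        base = risk_ratio(c, "E", "D")[0].value
        got = risk_ratio(scaled, "E", "D")[0].value
        if base is None:
            assert got is None
        else:
            assert got == pytest.approx(base, rel=1e-12)
    b = mh_risk_ratio(cohort, "E", "D", ["C"]).value
    g = mh_risk_ratio(scaled, "E", "D", ["C"]).value
    assert (b is None and g is None) or g == pytest.approx(b, rel=1e-12)


@given(random_cohorts())
@settings(max_examples=60, derandomize=True)
def test_mh_lies_between_stratum_extremes(data):
    cohort, counts = data
    stratum_rrs = [
        e.value for e in risk_ratio(cohort, "E", "D", ["C"]) if e.defined
    ]
    mh = mh_risk_ratio(cohort, "E", "D", ["C"])
    if mh.defined and len(stratum_rrs) == 2 and all(v > 0 for v in stratum_rrs):
        assert min(stratum_rrs) - 1e-9 <= mh.value <= max(stratum_rrs) + 1e-9


def test_zero_denominators_yield_undefined_not_exceptions():
    cohort = make_cohort(VARS, {(0, 0, 0): 10, (0, 0, 1): 5})  # nobody exposed
    assert not risk(cohort, "D", {"E": 1}).defined
    assert not risk_ratio(cohort, "E", "D")[0].defined
    assert not odds_ratio(cohort, "E", "D").defined


def test_risk_on_all_outcome_positive_cohort_is_one():
    cohort = make_cohort(VARS, {(0, 1, 1): 4, (1, 0, 1): 6})
    assert risk(cohort, "D").value == 1.0


def test_single_stratum_mh_and_standardized_collapse_to_crude():
    cohort = make_cohort(VARS, {(0, e, d): 10 * (1 + e + d) for e in (0, 1) for d in (0, 1)})
    crude = risk_ratio(cohort, "E", "D")[0].value
    assert mh_risk_ratio(cohort, "E", "D", []).value == pytest.approx(crude)
    assert standardized_risk_ratio(cohort, "E", "D", []).value == pytest.approx(crude)


def test_identical_variables_give_undefined_odds_ratio():
    cohort = make_cohort(VARS, {(0, 1, 1): 5, (1, 0, 0): 5})
    assert not odds_ratio(cohort, "E", "E").defined


# ---------------------------------------------------------------------------
# worked-cohort reference values


def test_worked_cohort_risks(t1_cohort):
    assert risk(t1_cohort, "D", {"E1": 1, "C0": 0, "U0": 0}).value == pytest.approx(0.20)
    assert risk(t1_cohort, "D", {"E1": 0}).value == pytest.approx(475 / 2900)
    assert risk(t1_cohort, "D", {"E1": 1}).value == pytest.approx(0.50)


def test_worked_cohort_stratum_rrs_all_two(t1_cohort):
    for est in risk_ratio(t1_cohort, "E", "D", ["C0", "U0"]):
        assert est.value == pytest.approx(2.0, abs=1e-12)


def test_worked_cohort_c_stratified_rrs(t1_cohort):
    by_stratum = {
        tuple(e.stratum.items()): e.value
        for e in risk_ratio(t1_cohort, "E", "D", ["C0"])
    }
    assert by_stratum[(("C0", 0),)] == pytest.approx(2.0, abs=1e-12)
    assert round(by_stratum[(("C0", 1),)], 2) == 2.41


def test_worked_cohort_c_adjustment_remains_biased(t1_cohort):
    """Adjusting for the known cause C alone does not remove the bias from
    the unknown cause U, whatever standard summary is used."""
    mh = mh_risk_ratio(t1_cohort, "E", "D", ["C0"]).value
    std = standardized_risk_ratio(t1_cohort, "E", "D", ["C0"]).value
    ipw = ipw_risk_ratio(t1_cohort, "E", "D", ["C0"]).value
    for value in (mh, std, ipw):
        assert value > 2.0 + 1e-6
    # hand Mantel-Haenszel on the four C-stratum margins
    # C=0: a=60, n1=300, c=170, n0=1700; C=1: a=490, n1=800, c=305, n0=1200
    want = (60 * 1700 / 2000 + 490 * 1200 / 2000) / (
        170 * 300 / 2000 + 305 * 800 / 2000
    )
    assert mh == pytest.approx(want, rel=1e-12)


def test_induced_inverse_association_among_exposed(t1_cohort):
    assert odds_ratio(t1_cohort, "C", "U").value == pytest.approx(1.0, abs=1e-12)
    or_e1 = odds_ratio(t1_cohort, "C", "U", {"E1": 1}).value
    assert or_e1 == pytest.approx((0.5 * 0.1) / (0.3 * 0.2), rel=1e-12)
    assert or_e1 < 1


def test_ipw_full_covariates_recovers_truth(t1_cohort, t1_model):
    fitted = ipw_risk_ratio(t1_cohort, "E", "D", ["C0", "U0"])
    true_w = ipw_risk_ratio(
        t1_cohort, "E", "D", ["C0", "U0"], weight_source="true_model", model=t1_model
    )
    assert fitted.value == pytest.approx(2.0, abs=1e-10)
    assert true_w.value == pytest.approx(2.0, abs=1e-10)


def test_ipw_equals_crude_under_marginal_randomization():
    s = make_scenario("fig2b")  # exposure has no parents
    from selproc import expected_cohort

    cohort = expected_cohort(s.model)
    crude = risk_ratio(cohort, "E1", "D2")[0].value
    ipw = ipw_risk_ratio(cohort, "E1", "D2", ["C0"]).value
    assert ipw == pytest.approx(crude, abs=1e-12)


@pytest.mark.parametrize(
    "name", ["fig2a", "fig2b", "fig2d", "fig3a", "fig3c", "fig3d", "table1"]
)
def test_ipw_equals_total_standardization(name):
    """Saturated IPW over a covariate set equals direct standardization to
    the total population of the same cohort, on every builtin scenario
    with a downstream outcome."""
    from selproc import expected_cohort

    s = make_scenario(name)
    covariates = [
        n.id
        for n in s.model.graph.nodes
        if n.role in ("covariate", "unknown_cause")
    ]
    for cohort in (expected_cohort(s.model), s.analysis_cohort()):
        ipw = ipw_risk_ratio(cohort, s.exposure, s.outcome, covariates).value
        std = standardized_risk_ratio(
            cohort, s.exposure, s.outcome, covariates, weight_source="total"
        ).value
        assert ipw == pytest.approx(std, abs=1e-10)


def test_true_model_weights_on_unselected_cohort_match_fitted(t1_model, t1_cohort):
    fitted = ipw_risk_ratio(t1_cohort, "E", "D", ["C0"]).value
    true_w = ipw_risk_ratio(
        t1_cohort, "E", "D", ["C0"], weight_source="true_model", model=t1_model
    ).value
    assert true_w == pytest.approx(fitted, abs=1e-12)


def test_zero_propensity_raises():
    """Model-based weights blow up when the model gives an observed
    exposure level zero probability. (Saturated fitted weights cannot:
    an observed arm always has positive empirical frequency.)"""
    model = make_scenario("fig2a", {"E1|C0=1": 1.0}).model
    cohort = make_cohort(
        ("C0", "E1", "D2"), {(1, 0, 0): 10, (1, 1, 1): 10, (0, 0, 0): 5}
    )
    with pytest.raises(EstimationError, match="zero propensity"):
        ipw_risk_ratio(
            cohort, "E1", "D2", ["C0"], weight_source="true_model", model=model
        )


def test_homogeneous_risks_equal_across_weight_sources():
    cohort = make_cohort(
        VARS,
        {(c, e, d): 50.0 * (0.3 if d else 0.7) * (1 + c + e) for c in (0, 1) for e in (0, 1) for d in (0, 1)},
    )
    values = {
        w: standardized_risk_ratio(cohort, "E", "D", ["C"], weight_source=w).value
        for w in ("total", "exposed", "unexposed")
    }
    assert values["total"] == pytest.approx(values["exposed"], rel=1e-12)
    assert values["total"] == pytest.approx(values["unexposed"], rel=1e-12)


def test_wald_interval_covers_point_estimate(t1_cohort):
    est = risk_ratio(t1_cohort, "E", "D")[0]
    lo, hi = est.wald_ci()
    assert lo < est.value < hi
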