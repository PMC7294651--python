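"""Shared fixtures and independent brute-force oracles.

The oracles work directly on {configuration: count} dictionaries with
plain Python loops — no shared code with the estimators or the engine —
so they can serve as an independent cross-check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from selproc import Cohort, expected_cohort, table1_model


@pytest.fixture(scope="session")
def t1_model():
    return table1_model()


@pytest.fixture(scope="session")
def t1_cohort(t1_model):
    return expected_cohort(t1_model)


def make_cohort(variables, counts_by_config) -> Cohort:
    """Build a Cohort from a {config tuple: count} dict (test helper)."""
    k = len(variables)
    counts = np.zeros(2**k)
    for cfg, c in counts_by_config.items():
        idx = 0
        for v in cfg:
            idx = (idx << 1) | int(v)
        counts[idx] = c
    return Cohort(variables=tuple(variables), counts=counts)


# ---------------------------------------------------------------------------
# brute-force oracles on {config: count} dicts


def oracle_count(table, variables, assignment):
    total = 0.0
    for cfg, n in table.items():
        named = dict(zip(variables, cfg))
        if all(named[k] == v for k, v in assignment.items()):
            total += n
    return total


def oracle_risk(table, variables, outcome, given):
    den = oracle_count(table, variables, given)
    if den == 0:
        return None
    num = oracle_count(table, variables, {**given, outcome: 1})
    return num / den


def oracle_rr(table, variables, exposure, outcome, stratum):
    r1 = oracle_risk(table, variables, outcome, {**stratum, exposure: 1})
    r0 = oracle_risk(table, variables, outcome, {**stratum, exposure: 0})
    if r1 is None or r0 is None or r0 == 0:
        return None
    return r1 / r0


def oracle_or(table, variables, a, b, given):
    n = {
        (va, vb): oracle_count(table, variables, {**given, a: va, b: vb})
        for va, vb in product((0, 1), repeat=2)
    }
    den = n[(1, 0)] * n[(0, 1)]
    num = n[(1, 1)] * n[(0, 0)]
    if den == 0 or num == 0:
        return None
    return num / den


def oracle_mh(table, variables, exposure, outcome, strata):
    num = den = 0.0
    for values in product((0, 1), repeat=len(strata)):
        s = dict(zip(strata, values))
        a = oracle_count(table, variables, {**s, exposure: 1, outcome: 1})
        n1 = oracle_count(table, variables, {**s, exposure: 1})
        c = oracle_count(table, variables, {**s, exposure: 0, outcome: 1})
        n0 = oracle_count(table, variables, {**s, exposure: 0})
        t = n1 + n0
        if t == 0:
            continue
        num += a * n0 / t
        den += c * n1 / t
    return None if den == 0 else num / den
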