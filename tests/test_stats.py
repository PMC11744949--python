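"""Unit and property tests for the disproportionality statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pvsignal.stats import (ContingencyTable, bonferroni,
                            classify_signal, ebgm_stat, ic_stat, metrics_frame,
                            mgps_ebgm, prr_stat, ror_stat)

cells = st.integers(min_value=1, max_value=500)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


# --- worked examples ------------------------------------------------------

def test_ror_worked_example():
    r = ror_stat(ContingencyTable(10, 90, 100, 9900))
    assert r.estimate == pytest.approx(11.0)
    se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
    assert r.lower == pytest.approx(11.0 * math.exp(-1.959963984540054 * se))
    assert r.lower < r.estimate < r.upper


def test_prr_worked_example():
    prr, chi2 = prr_stat(ContingencyTable(10, 90, 100, 9900))
    assert prr == pytest.approx(10.0)
    assert chi2 == pytest.approx(74.447174, rel=1e-6)


def test_ic_worked_example():
    ic, ic025 = ic_stat(ContingencyTable(10, 90, 100, 9900))
    assert ic == pytest.approx(math.log2(10 * 10100 / (110 * 100)))
    assert ic == pytest.approx(3.19878, abs=1e-4)
    assert ic025 < ic


def test_ebgm_equals_two_to_the_ic():
    t = ContingencyTable(10, 90, 100, 9900)
    assert ebgm_stat(t).estimate == pytest.approx(2 ** ic_stat(t)[0])
    assert ebgm_stat(t).estimate == pytest.approx(9.1818, abs=1e-3)


@pytest.mark.parametrize("table", [
    ContingencyTable(5, 95, 50, 950),
    ContingencyTable(2, 8, 20, 80),
    ContingencyTable(7, 7, 7, 7),
])
def test_independence_tables_are_null(table):
    """a/(a+b) == c/(c+d) forces ROR = PRR = EBGM = 1, IC = 0, chi2 = 0."""
    assert ror_stat(table).estimate == pytest.approx(1.0)
    prr, chi2 = prr_stat(table)
    assert prr == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    ic, _ = ic_stat(table)
    assert ic == pytest.approx(0.0, abs=1e-12)
    assert ebgm_stat(table).estimate == pytest.approx(1.0)


def test_zero_cells_are_undefined_not_zero():
    t = ContingencyTable(0, 10, 10, 100)
    assert not ror_stat(t).defined
    assert math.isnan(ic_stat(t)[0])
    assert math.isnan(ebgm_stat(t).estimate)
    prr, chi2 = prr_stat(ContingencyTable(3, 0, 1, 0))
    # c+d margin nonzero here but b+d = 0 collapses chi2; PRR itself defined
    t2 = ContingencyTable(3, 3, 0, 5)
    assert math.isnan(prr_stat(t2)[0])


def test_negative_or_empty_table_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 0, 0)


# --- brute-force oracle ---------------------------------------------------

def _oracle(a, b, c, d):
    """Exact-arithmetic evaluation of every printed formula."""
    n = a + b + c + d
    ror = Fraction(a * d, b * c)
    prr = Fraction(a * (c + d), c * (a + b))
    chi2 = Fraction((a * d - b * c) ** 2 * n,
                    (a + b) * (c + d) * (a + c) * (b + d))
    oe = Fraction(a * n, (a + c) * (a + b))
    return float(ror), float(prr), float(chi2), math.log2(oe), float(oe)


def test_oracle_equivalence_on_random_tables():
    """1,000 random tables agree with exact arithmetic to 12 digits."""
    rng = np.random.default_rng(42)
    A = rng.integers(1, 400, 1000)
    B = rng.integers(1, 400, 1000)
    C = rng.integers(1, 400, 1000)
    D = rng.integers(1, 400, 1000)
    m = metrics_frame(A, B, C, D)
    for i in range(1000):
        ror, prr, chi2, ic, ebgm = _oracle(int(A[i]), int(B[i]), int(C[i]), int(D[i]))
        assert m["ror"][i] == pytest.approx(ror, rel=1e-12)
        assert m["prr"][i] == pytest.approx(prr, rel=1e-12)
        assert m["chi2"][i] == pytest.approx(chi2, rel=1e-12, abs=1e-12)
        assert m["ic"][i] == pytest.approx(ic, rel=1e-12, abs=1e-12)
        assert m["ebgm"][i] == pytest.approx(ebgm, rel=1e-12)


def test_vectorised_matches_scalar_path():
    rng = np.random.default_rng(7)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(1, 200, 4))
        t = ContingencyTable(a, b, c, d)
        m = metrics_frame([a], [b], [c], [d])
        assert m["ror"][0] == pytest.approx(ror_stat(t).estimate, rel=1e-14)
        assert m["ror_lo"][0] == pytest.approx(ror_stat(t).lower, rel=1e-14)
        assert m["prr"][0] == pytest.approx(prr_stat(t)[0], rel=1e-14)
        assert m["chi2"][0] == pytest.approx(prr_stat(t)[1], rel=1e-14, abs=1e-14)
        assert m["ic025"][0] == pytest.approx(ic_stat(t)[1], rel=1e-12)
        assert m["ebgm05"][0] == pytest.approx(ebgm_stat(t).lower, rel=1e-14)


def test_chi2_matches_pearson_without_correction():
    obs = np.array([[17, 83], [120, 4780]])
    t = ContingencyTable(17, 83, 120, 4780)
    expected = sps.chi2_contingency(obs, correction=False)[0]
    assert prr_stat(t)[1] == pytest.approx(expected, rel=1e-12)


# --- properties -----------------------------------------------------------

@settings(max_examples=200, deadline=None)
@given(tables)
def test_ebgm_ic_identity_property(t):
    """The relative reporting ratio equals 2**IC for every table."""
    assert ebgm_stat(t).estimate == pytest.approx(2 ** ic_stat(t)[0], rel=1e-10)


@settings(max_examples=100, deadline=None)
@given(tables)
def test_interval_ordering(t):
    r = ror_stat(t)
    assert r.lower <= r.estimate <= r.upper
    e = ebgm_stat(t)
    assert e.lower <= e.estimate <= e.upper


def test_monotonicity_in_a():
    """Increasing a with b, c, d fixed strictly increases every statistic."""
    prev = None
    for a in (5, 10, 20, 40):
        t = ContingencyTable(a, 100, 50, 5000)
        cur = (ror_stat(t).estimate, prr_stat(t)[0], ic_stat(t)[0],
               ebgm_stat(t).estimate)
        if prev is not None:
            assert all(x > y for x, y in zip(cur, prev))
        prev = cur


def test_ic_scale_invariance():
    t1 = ContingencyTable(10, 90, 100, 9900)
    t2 = ContingencyTable(20, 180, 200, 19800)
    assert ic_stat(t1)[0] == pytest.approx(ic_stat(t2)[0], rel=1e-12)


# --- decision logic -------------------------------------------------------

def test_decision_thresholds_and_consensus():
    d = classify_signal(n=3, ror_lo=1.2, prr=2.5, chi2=5, ic025=0.1, ebgm05=2.1)
    assert d.consensus
    assert not classify_signal(n=3, ror_lo=1.2, prr=2.5, chi2=5, ic025=0.1,
                               ebgm05=1.9).consensus
    # N >= 3 gates both the ROR and PRR criteria
    d2 = classify_signal(n=2, ror_lo=50.0, prr=100.0, chi2=400.0, ic025=5.0,
                         ebgm05=50.0)
    assert not (d2.pass_ror or d2.pass_prr)
    assert not d2.consensus


def test_undefined_statistics_fail_their_criterion():
    d = classify_signal(n=5, ror_lo=math.nan, prr=3.0, chi2=10.0, ic025=0.5,
                        ebgm05=2.5)
    assert not d.pass_ror and d.pass_prr and not d.consensus


# --- bonferroni -----------------------------------------------------------

def test_bonferroni_examples():
    adj, thr = bonferroni([0.001] * 50, alpha=0.05)
    assert thr == pytest.approx(0.001)
    assert adj[0] == pytest.approx(0.05)
    adj2, _ = bonferroni([0.5] * 10)
    assert adj2[0] == 1.0  # capped
    with pytest.raises(ValueError):
        bonferroni([])


def test_bonferroni_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    p = [0.001, 0.02, 0.3, 0.7, 0.04]
    adj, _ = bonferroni(p)
    ref = multipletests(p, method="bonferroni")[1]
    assert np.allclose(adj, ref)


# --- shrinkage mode -------------------------------------------------------

def test_mgps_shrinks_small_counts_toward_background():
    """A lone 3/0.2 cell is pulled toward 1 by the gamma-Poisson prior while
    large-count cells stay close to their observed ratio."""
    rng = np.random.default_rng(0)
    e = rng.uniform(5, 50, 200)
    a = rng.poisson(e)  # null background
    a_sig = np.array([3, 400])
    e_sig = np.array([0.2, 40.0])
    ebgm, eb05 = mgps_ebgm(np.concatenate([a, a_sig]), np.concatenate([e, e_sig]))
    raw_small, raw_big = 3 / 0.2, 400 / 40.0
    assert ebgm[-2] < raw_small * 0.8          # visibly shrunk
    assert ebgm[-1] == pytest.approx(raw_big, rel=0.15)
    assert np.all(eb05 <= ebgm + 1e-12)
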