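"""Time-to-onset: date rules, Weibull fit, failure taxonomy, KM/log-rank."""

import numpy as np
import pandas as pd
import pytest

from pvsignal.cases import CaseReport
from pvsignal.errors import FitError
from pvsignal.tto import (WeibullTTO, classify_failure, compute_tto, km_compare,
                          long_term_tabulation, tto_by_level, tto_distribution)


def _case(start, event):
    return CaseReport(primaryid="1", caseid="1", fda_dt="20200601",
                      reactions=["X"], therapy_start=start, event_date=event)


# --- interval computation -------------------------------------------------

@pytest.mark.parametrize("start,event,days,reason", [
    ("20200101", "20200210", 40, None),          # calendar arithmetic
    ("20200101", "20200101", 0, None),           # day 0 retained
    ("202001", "20200210", None, "partial"),     # start lacks a day
    ("20200101", "2020", None, "partial"),       # event is year-only
    ("", "20200210", None, "missing"),
    ("20200101", None, None, "missing"),
    ("20200210", "20200101", None, "negative"),  # event precedes start
])
def test_compute_tto_rules(start, event, days, reason):
    out = compute_tto(_case(start, event))
    assert out.days == days and out.reason == reason


def test_compute_tto_never_negative():
    rng = np.random.default_rng(0)
    for _ in range(200):
        s = 20200101 + int(rng.integers(0, 27))
        e = 20200101 + int(rng.integers(0, 27))
        out = compute_tto(_case(str(s), str(e)))
        if out.included:
            assert out.days >= 0


# --- distribution ---------------------------------------------------------

def test_distribution_median_and_iqr():
    out = tto_distribution([10, 40, 163])
    assert out.attrs["median"] == 40
    assert out["count"].sum() == 3


def test_distribution_first_bin_all():
    out = tto_distribution([1, 5, 30, 0])
    assert out.loc[out["interval"] == "0-30", "proportion"].iloc[0] == 1.0


def test_distribution_proportions_sum_to_one():
    rng = np.random.default_rng(1)
    out = tto_distribution(rng.integers(0, 1000, 500))
    assert out["proportion"].sum() == pytest.approx(1.0)


def test_first_month_proportion_in_mc_envelope():
    """Weibull(90, 0.67), n=2000: share of onsets in the first month lies in
    the envelope pre-computed over 200 Monte-Carlo replicates."""
    rng = np.random.default_rng(12345)
    days = np.rint(90 * rng.weibull(0.67, 2000))
    out = tto_distribution(days)
    first = out.loc[out["interval"] == "0-30", "proportion"].iloc[0]
    assert 0.35 <= first <= 0.43


def test_empty_distribution_errors():
    with pytest.raises(ValueError):
        tto_distribution([])


# --- Weibull fit ----------------------------------------------------------

def test_weibull_parameter_recovery():
    """n = 5,000 draws at shape 0.67: recovered beta within +-0.05."""
    rng = np.random.default_rng(99)
    days = np.rint(69.1 * rng.weibull(0.67, 5000))
    fit = WeibullTTO(days).fit()
    assert fit.beta == pytest.approx(0.67, abs=0.05)
    assert fit.beta_lo < fit.beta < fit.beta_hi
    assert fit.failure_type == "early"


def test_weibull_recovery_across_shapes():
    """Median absolute error over 12 seeds stays inside the pre-computed
    envelope (0.05) for early, random and wear-out regimes."""
    for beta in (0.5, 1.0, 2.0):
        errs = []
        for seed in range(12):
            rng = np.random.default_rng(3000 + seed)
            days = np.rint(69.1 * rng.weibull(beta, 5000))
            errs.append(abs(WeibullTTO(days).fit().beta - beta))
        assert np.median(errs) < 0.05


def test_weibull_ci_coverage_at_beta_one():
    """Exponential data: the 95% CI for beta contains 1 in most replicates."""
    covered = 0
    n_rep = 40
    for seed in range(n_rep):
        rng = np.random.default_rng(500 + seed)
        days = np.rint(60 * rng.weibull(1.0, 800))
        fit = WeibullTTO(days).fit()
        covered += fit.beta_lo <= 1.0 <= fit.beta_hi
    assert covered / n_rep >= 0.85


def test_two_distinct_values_fit_without_crash():
    fit = WeibullTTO([3] * 6 + [200] * 6).fit()
    assert fit.beta_hi / fit.beta_lo > 1.0  # wide but finite


def test_degenerate_sample_raises():
    with pytest.raises(FitError):
        WeibullTTO([7] * 50).fit()


def test_day_zero_policy():
    days = [0] * 5 + list(range(1, 50))
    shifted = WeibullTTO(days, zeros="shift")
    dropped = WeibullTTO(days, zeros="drop")
    assert len(shifted.days) == len(days)
    assert len(dropped.days) == len(days) - 5
    assert shifted.days.min() == 0.5


# --- failure taxonomy -----------------------------------------------------

@pytest.mark.parametrize("beta,lo,hi,expected", [
    (0.67, 0.65, 0.69, "early"),       # beta < 1 and CI upper < 1
    (1.0, 0.9, 1.1, "random"),         # CI contains 1
    (1.5, 1.2, 1.8, "wear-out"),       # beta > 1 and CI lower > 1
    (0.95, 0.80, 1.05, "random"),
    (1.05, 0.98, 1.20, "random"),
])
def test_failure_classification_rules(beta, lo, hi, expected):
    assert classify_failure(beta, lo, hi) == expected


# --- Kaplan-Meier / log-rank ---------------------------------------------

def _records(days_by_group, group_col="sex"):
    rows = []
    for g, days in days_by_group.items():
        rows += [{"days": d, group_col: g, "pt": "X", "soc": "S"} for d in days]
    return pd.DataFrame(rows)


def test_identical_groups_logrank_zero():
    d = list(range(1, 101))
    km = km_compare(_records({"F": d, "M": list(d)}), "sex")
    assert km.statistic == pytest.approx(0.0, abs=1e-10)
    assert km.p_value == pytest.approx(1.0)


def test_shifted_group_strongly_significant():
    rng = np.random.default_rng(0)
    a = np.rint(60 * rng.weibull(1.2, 500))
    km = km_compare(_records({"F": a, "M": a + 100}), "sex")
    assert km.p_value < 0.001


def test_survival_curves_shape():
    rng = np.random.default_rng(2)
    rec = _records({"F": 1 + np.rint(50 * rng.weibull(1, 200)),
                    "M": 1 + np.rint(80 * rng.weibull(1, 200))})
    km = km_compare(rec, "sex")
    for g, curve in km.curves.items():
        s = curve["survival"].to_numpy()
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)       # non-increasing
        assert s[-1] == pytest.approx(0.0, abs=1e-12)  # all events observed


def test_unk_dropped_and_min_groups_enforced():
    rec = _records({"F": range(10), "UNK": range(10)})
    with pytest.raises(ValueError):
        km_compare(rec, "sex")


# --- grouped summaries ----------------------------------------------------

def test_by_level_hand_fixture():
    rec = _records({"F": [1], "M": [1]})
    rec["soc"] = ["SOC_A"] * 1 + ["SOC_B"] * 1
    rec = pd.DataFrame({
        "days": [10, 20, 30, 100, 200, 300],
        "soc": ["A"] * 3 + ["B"] * 3,
        "pt": ["p"] * 6, "sex": ["F"] * 6, "age_group": ["18-65"] * 6,
    })
    out = tto_by_level(rec, "soc")
    assert dict(zip(out["soc"], out["median"])) == {"A": 20, "B": 200}
    assert "p" in out.attrs


def test_by_level_min_n_and_single_group():
    rec = pd.DataFrame({"days": [5, 6, 7], "soc": ["A", "A", "B"],
                        "pt": ["p"] * 3, "sex": ["F"] * 3,
                        "age_group": ["18-65"] * 3})
    out = tto_by_level(rec, "soc", min_n=2)
    assert list(out["soc"]) == ["A"]
    assert "p" not in out.attrs  # single surviving group: no across-group test


def test_long_term_tabulation():
    rec = pd.DataFrame({
        "days": [100, 200, 400, 500, 700, 900, 360],
        "soc": ["A", "A", "A", "B", "B", "B", "A"],
        "pt": ["p1", "p2", "p3", "p3", "p3", "p4", "p5"],
        "sex": ["F"] * 7, "age_group": ["18-65"] * 7,
    })
    soc_tab, pt_tab = long_term_tabulation(rec, cutoff_days=360)
    assert soc_tab["count"].sum() == 4          # strictly > 360 only
    assert soc_tab["proportion"].sum() == pytest.approx(1.0)
    # brute-force check of the PT counts
    late = rec[rec["days"] > 360]
    assert dict(zip(pt_tab["pt"], pt_tab["count"])) == \
        late.groupby("pt").size().to_dict()


def test_long_term_empty():
    rec = pd.DataFrame({"days": [10, 20], "soc": ["A", "B"],
                        "pt": ["p", "q"], "sex": ["F", "M"],
                        "age_group": ["18-65"] * 2})
    soc_tab, pt_tab = long_term_tabulation(rec)
    assert soc_tab.empty and pt_tab.empty
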