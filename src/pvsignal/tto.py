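"""Time-to-onset (TTO) analysis: exclusion rules, Weibull fit, Kaplan-Meier.

TTO for one report is the number of whole days between therapy start
(START_DT) and event occurrence (EVENT_DT).  A record enters the analysis
only when both dates are complete (8-digit CCYYMMDD) and the interval is
nonnegative; otherwise a machine-readable exclusion reason is recorded
(``missing``, ``partial`` or ``negative``) — exclusions are data, not
errors.  One record is produced per (report, PT) pair.

The pooled onset distribution is modelled as Weibull(scale alpha, shape
beta); the shape parameter classifies the hazard over time:

* early failure - beta < 1 and the 95% CI upper bound < 1 (risk declines),
* random failure - the CI contains 1 (constant hazard),
* wear-out failure - beta > 1 and the CI lower bound > 1 (risk grows).

Cumulative incidence across subgroups uses the Kaplan-Meier product-limit
estimate (every record is an observed event; no censoring in this design)
compared with the log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, WeibullFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .cases import CaseReport
from .errors import FitError

__all__ = [
    "compute_tto", "TTOOutcome", "tto_records", "tto_distribution",
    "WeibullTTO", "WeibullTTOResults", "classify_failure",
    "km_compare", "KMResult", "tto_by_level", "long_term_tabulation",
]

_Z95 = 1.959963984540054
DEFAULT_BIN_EDGES = (0, 30, 60, 90, 120, 150, 180, 240, 300, 360)


@dataclass(frozen=True)
class TTOOutcome:
    """Either a nonnegative day count or an exclusion reason."""

    days: int | None
    reason: str | None = None  # None | "missing" | "partial" | "negative"

    @property
    def included(self) -> bool:
        return self.days is not None


def _parse_full_date(s: str | None) -> np.datetime64 | str:
    """A complete CCYYMMDD date, or the exclusion reason it triggers."""
    if s is None or str(s).strip() == "":
        return "missing"
    s = str(s).strip()
    if not s.isdigit() or len(s) != 8:
        return "partial" if s.isdigit() and len(s) in (4, 6) else "missing"
    try:
        return np.datetime64(f"{s[:4]}-{s[4:6]}-{s[6:]}", "D")
    except ValueError:
        return "missing"


def compute_tto(case: CaseReport, event_date: str | None = None) -> TTOOutcome:
    """Whole days from therapy start to event occurrence for one report.

    ``event_date`` overrides the report's own EVENT_DT.  Partial dates
    (CCYY or CCYYMM) and missing dates exclude the record; a negative
    interval (event before therapy start) excludes it as ``negative``.
    """
    ev = _parse_full_date(event_date if event_date is not None else case.event_date)
    st = _parse_full_date(case.therapy_start)
    for v in (st, ev):
        if isinstance(v, str):
            return TTOOutcome(None, v)
    days = int((ev - st) / np.timedelta64(1, "D"))
    if days < 0:
        return TTOOutcome(None, "negative")
    return TTOOutcome(days)


def tto_records(cases: Sequence[CaseReport],
                pt_soc_map: pd.DataFrame | None = None
                ) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per (report, PT) with stratification labels, plus exclusion
    counts keyed by reason."""
    rows = []
    excl = {"missing": 0, "partial": 0, "negative": 0}
    for c in cases:
        out = compute_tto(c)
        if not out.included:
            excl[out.reason] += len(set(c.reactions))
            continue
        for pt in dict.fromkeys(c.reactions):
            rows.append({"primaryid": c.primaryid, "days": out.days, "pt": pt,
                         "sex": c.sex, "age_group": c.age_group})
    rec = pd.DataFrame(rows, columns=["primaryid", "days", "pt", "sex", "age_group"])
    if pt_soc_map is not None and len(rec):
        rec = rec.merge(pt_soc_map[["pt", "soc_name"]].rename(
            columns={"soc_name": "soc"}), on="pt", how="left")
        rec["soc"] = rec["soc"].fillna("UNKNOWN")
    else:
        rec["soc"] = "UNKNOWN"
    return rec, excl


def tto_distribution(days: Iterable[int],
                     edges: Sequence[int] = DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Counts and proportions per onset interval, plus median and IQR.

    Bins are (edges[i], edges[i+1]] with the first bin including day 0 and a
    final open ``> edges[-1]`` bin.  Returns a frame with one row per bin and
    attaches ``median``, ``q1``, ``q3`` in ``.attrs``.
    """
    d = np.asarray(list(days), float)
    if d.size == 0:
        raise ValueError("no records")
    cuts = [-0.5] + list(edges[1:]) + [np.inf]
    labels = [f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])] + [f">{edges[-1]}"]
    binned = pd.cut(d, cuts, labels=labels)
    counts = binned.value_counts().reindex(labels)
    out = pd.DataFrame({"interval": labels, "count": counts.to_numpy()})
    out["proportion"] = out["count"] / d.size
    out.attrs["median"] = float(np.median(d))
    out.attrs["q1"] = float(np.percentile(d, 25))
    out.attrs["q3"] = float(np.percentile(d, 75))
    out.attrs["n"] = int(d.size)
    return out


def classify_failure(beta: float, lo: float, hi: float) -> str:
    """Hazard classification from the Weibull shape and its 95% CI."""
    if beta < 1 and hi < 1:
        return "early"
    if beta > 1 and lo > 1:
        return "wear-out"
    if lo <= 1 <= hi:
        return "random"
    return "indeterminate"


class WeibullTTO:
    """Weibull model for pooled onset times.

    Day-0 records break the log-likelihood; by default they are shifted to
    0.5 days (``zeros="shift"``); ``zeros="drop"`` excludes them instead.
    """

    def __init__(self, days: Iterable[int], zeros: str = "shift"):
        d = np.asarray(list(days), float)
        if zeros == "shift":
            d = np.where(d <= 0, 0.5, d)
        elif zeros == "drop":
            d = d[d > 0]
        else:
            raise ValueError(f"unknown zeros policy {zeros!r}")
        self.days = d

    def fit(self) -> "WeibullTTOResults":
        d = self.days
        if d.size < 2 or np.all(d == d[0]):
            raise FitError("degenerate sample: need >= 2 distinct onset times")
        wf = WeibullFitter()
        wf.fit(d, event_observed=np.ones_like(d))
        alpha = float(wf.lambda_)
        beta = float(wf.rho_)
        se_beta = float(wf.summary.loc["rho_", "se(coef)"])
        # normal approximation on log(beta): CI = beta * exp(+-1.96 se/beta)
        rel = _Z95 * se_beta / beta
        lo, hi = beta * math.exp(-rel), beta * math.exp(rel)
        se_alpha = float(wf.summary.loc["lambda_", "se(coef)"])
        rel_a = _Z95 * se_alpha / alpha
        return WeibullTTOResults(
            alpha=alpha, beta=beta, beta_lo=lo, beta_hi=hi,
            alpha_lo=alpha * math.exp(-rel_a), alpha_hi=alpha * math.exp(rel_a),
            n=int(d.size), fitter=wf)


@dataclass
class WeibullTTOResults:
    alpha: float
    beta: float
    beta_lo: float
    beta_hi: float
    alpha_lo: float
    alpha_hi: float
    n: int
    fitter: WeibullFitter | None = None

    @property
    def failure_type(self) -> str:
        return classify_failure(self.beta, self.beta_lo, self.beta_hi)

    def summary(self) -> str:
        return "\n".join([
            "Weibull time-to-onset fit",
            "=" * 40,
            f"n records:       {self.n}",
            f"scale alpha:     {self.alpha:.2f} d "
            f"(95% CI {self.alpha_lo:.2f}-{self.alpha_hi:.2f})",
            f"shape beta:      {self.beta:.2f} "
            f"(95% CI {self.beta_lo:.2f}-{self.beta_hi:.2f})",
            f"failure type:    {self.failure_type}",
        ])


@dataclass
class KMResult:
    """Per-group survival curves with the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    statistic: float
    p_value: float
    group_by: str

    def summary(self) -> str:
        sizes = {g: len(c) for g, c in self.curves.items()}
        return (f"Kaplan-Meier by {self.group_by}: groups {sizes}; "
                f"log-rank chi2 = {self.statistic:.3f}, p = {self.p_value:.3g}")


def km_compare(records: pd.DataFrame, group_by: str = "sex") -> KMResult:
    """Kaplan-Meier curves and log-rank test across subgroups.

    ``records`` needs columns ``days`` and the grouping column; UNK levels
    are dropped.  Every record is an observed event at its day.
    """
    if group_by not in records.columns:
        raise ValueError(f"no column {group_by!r} in records")
    sub = records[records[group_by] != "UNK"]
    groups = sorted(sub[group_by].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 nonempty groups after dropping UNK")
    curves = {}
    for g in groups:
        d = sub.loc[sub[group_by] == g, "days"].to_numpy(float)
        kmf = KaplanMeierFitter()
        kmf.fit(d, event_observed=np.ones_like(d))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
    lr = multivariate_logrank_test(sub["days"], sub[group_by],
                                   np.ones(len(sub)))
    return KMResult(curves=curves, statistic=float(lr.test_statistic),
                    p_value=float(lr.p_value), group_by=group_by)


def tto_by_level(records: pd.DataFrame, level: str = "soc",
                 min_n: int = 1, across_group_test: bool = True) -> pd.DataFrame:
    """Median/IQR onset summaries per SOC or PT with >= min_n records.

    When two or more groups remain and ``across_group_test`` is set, a
    Kruskal-Wallis p-value across groups is attached as ``.attrs['p']``.
    """
    if level not in records.columns:
        raise ValueError(f"no column {level!r} in records")
    g = records.groupby(level)["days"]
    out = g.agg(n="size", median="median",
                q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75),
                min="min", max="max").reset_index()
    out = out[out["n"] >= min_n].sort_values("median").reset_index(drop=True)
    if across_group_test and len(out) >= 2:
        samples = [records.loc[records[level] == grp, "days"].to_numpy(float)
                   for grp in out[level]]
        out.attrs["p"] = float(sps.kruskal(*samples)[1])
    return out


def long_term_tabulation(records: pd.DataFrame, cutoff_days: int = 360,
                         top_k: int = 15) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SOC and top-k PT frequency tables among records beyond the cutoff."""
    late = records[records["days"] > cutoff_days]
    def tab(col, k=None):
        counts = late.groupby(col).size().sort_values(ascending=False)
        if k:
            counts = counts.head(k)
        df = counts.rename("count").reset_index()
        df["proportion"] = df["count"] / len(late) if len(late) else np.nan
        return df
    return tab("soc"), tab("pt", top_k)
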