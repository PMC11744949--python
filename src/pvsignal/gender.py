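"""Sex-stratified signal analysis within the target drug's reports.

For each preferred term the female-vs-male 2x2 table is built *within*
target-drug reports with known sex::

                 target PT   other PTs
    female           a           b
    male             c           d

so ROR = ad/bc > 1 means female-skewed reporting.  This is a within-drug
contrast, not a drug-vs-background disproportionality; it quantifies which
events are reported disproportionately by one sex among treated patients.
:class:`GenderDisparity` fits every PT, attaches a two-sided p-value
(Fisher exact by default), Bonferroni-adjusts over the tested PTs, and
yields volcano-plot coordinates (log2 ROR vs -log10 adjusted p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cases import CaseReport
from .stats import bonferroni

__all__ = ["gender_table", "gender_ror", "GenderDisparity", "GenderResults",
           "monotherapy_filter"]

_Z95 = 1.959963984540054


def _sex_pt_counts(cases: Sequence[CaseReport]) -> tuple[pd.DataFrame, int, int]:
    """Per-PT report counts by sex over cases with known sex."""
    rows = []
    n_f = n_m = 0
    for c in cases:
        if c.sex == "F":
            n_f += 1
        elif c.sex == "M":
            n_m += 1
        else:
            continue
        for pt in set(c.reactions):
            rows.append((pt, c.sex))
    if not rows:
        return pd.DataFrame(columns=["n_female", "n_male"]), 0, 0
    df = pd.DataFrame(rows, columns=["pt", "sex"])
    tab = df.pivot_table(index="pt", columns="sex", aggfunc="size", fill_value=0)
    tab = tab.reindex(columns=["F", "M"], fill_value=0)
    tab.columns = ["n_female", "n_male"]
    return tab.sort_index(), n_f, n_m


def gender_table(cases: Sequence[CaseReport], pt: str) -> tuple[int, int, int, int]:
    """(a, b, c, d): female with/without the PT, male with/without the PT."""
    tab, n_f, n_m = _sex_pt_counts(cases)
    a = int(tab.loc[pt, "n_female"]) if pt in tab.index else 0
    c = int(tab.loc[pt, "n_male"]) if pt in tab.index else 0
    return a, n_f - a, c, n_m - c


def gender_ror(cases: Sequence[CaseReport], pt: str) -> tuple[float, float, float]:
    """Female-vs-male reporting odds ratio for one PT with lognormal 95% CI.

    Returns NaNs when any cell is zero (including the no-known-sex case).
    """
    a, b, c, d = gender_table(cases, pt)
    if min(a, b, c, d) <= 0:
        return (math.nan, math.nan, math.nan)
    ror = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-_Z95 * se), ror * math.exp(_Z95 * se)


def monotherapy_filter(cases: Sequence[CaseReport]) -> list[CaseReport]:
    """Reports whose drug list contains nothing but the target drug."""
    return [c for c in cases if c.is_monotherapy]


@dataclass(frozen=True)
class GenderOptions:
    alpha: float = 0.05
    min_n: int = 3            # minimum total cases (both sexes) per tested PT
    test: str = "fisher"      # "fisher" | "chi2"
    y_cap: float | None = None  # flag points with -log10(adj p) above this


class GenderDisparity:
    """Female-vs-male disproportionate reporting across all PTs.

    Reports with unknown sex are excluded (they cannot enter the table).
    """

    def __init__(self, cases: Sequence[CaseReport],
                 options: GenderOptions = GenderOptions()):
        self.cases = cases
        self.options = options

    def fit(self) -> "GenderResults":
        tab, n_f, n_m = _sex_pt_counts(self.cases)
        opt = self.options
        tab = tab[(tab["n_female"] + tab["n_male"]) >= opt.min_n]

        a = tab["n_female"].to_numpy(int)
        c = tab["n_male"].to_numpy(int)
        b = n_f - a
        d = n_m - c

        with np.errstate(divide="ignore", invalid="ignore"):
            pos = (a > 0) & (b > 0) & (c > 0) & (d > 0)
            ror = np.where(pos, a * d / (b * c.astype(float)), np.nan)
            se = np.where(pos, np.sqrt(1 / a + 1 / b + 1 / c + 1 / d.astype(float)),
                          np.nan)
            lo = ror * np.exp(-_Z95 * se)
            hi = ror * np.exp(_Z95 * se)

        pvals = np.ones(len(tab))
        for i in range(len(tab)):
            table = [[a[i], b[i]], [c[i], d[i]]]
            if opt.test == "fisher":
                pvals[i] = sps.fisher_exact(table, alternative="two-sided")[1]
            elif opt.test == "chi2":
                if min(a[i] + b[i], c[i] + d[i], a[i] + c[i], b[i] + d[i]) == 0:
                    pvals[i] = 1.0
                else:
                    pvals[i] = sps.chi2_contingency(table, correction=False)[1]
            else:
                raise ValueError(f"unknown test {opt.test!r}")

        if len(pvals):
            adj, _thr = bonferroni(pvals, opt.alpha)
        else:
            adj = pvals
        significant = (adj < opt.alpha) & ~np.isnan(ror)
        direction = np.where(np.isnan(ror), "",
                             np.where(ror > 1, "female", "male"))
        with np.errstate(divide="ignore"):
            neglogp = -np.log10(np.maximum(adj, np.finfo(float).tiny))
        frame = pd.DataFrame({
            "pt": tab.index,
            "n_female": a, "n_male": c,
            "ror": ror, "lo": lo, "hi": hi,
            "log2_ror": np.log2(ror),
            "p": pvals, "adj_p": adj,
            "neg_log10_adj_p": neglogp,
            "significant": significant,
            "direction": direction,
        }).reset_index(drop=True)
        if opt.y_cap is not None:
            frame["above_cap"] = frame["neg_log10_adj_p"] > opt.y_cap
        return GenderResults(self, frame, n_female=n_f, n_male=n_m)


class GenderResults:
    """Volcano table from a fitted :class:`GenderDisparity`."""

    def __init__(self, model: GenderDisparity, frame: pd.DataFrame,
                 n_female: int, n_male: int):
        self.model = model
        self.frame = frame
        self.n_female = n_female
        self.n_male = n_male

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def significant_pts(self, direction: str | None = None) -> set[str]:
        sig = self.significant
        if direction is not None:
            sig = sig[sig["direction"] == direction]
        return set(sig["pt"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g",
                          lineterminator="\n")

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Sex-stratified disproportionate reporting",
            "=" * 60,
            f"reports with known sex:  {self.n_female + self.n_male} "
            f"(F {self.n_female} / M {self.n_male})",
            f"PTs tested:              {len(self.frame)}",
            f"significant (adj p < {self.model.options.alpha}): {len(sig)} "
            f"(female {int((sig['direction'] == 'female').sum())}, "
            f"male {int((sig['direction'] == 'male').sum())})",
        ]
        if len(sig):
            cols = ["pt", "n_female", "n_male", "ror", "adj_p", "direction"]
            lines += ["", sig[cols].to_string(index=False,
                                              float_format=lambda v: f"{v:.3g}")]
        return "\n".join(lines)
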