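"""Drug-event disproportionality screening over a case universe.

:class:`DisproportionalityScreen` is the model object: it holds the case
universe (every deduplicated report, with target-drug reports flagged), the
positivity thresholds, and the screening options.  ``fit()`` builds the 2x2
table for every preferred term observed with the target drug, computes the
four statistics, applies the per-algorithm criteria and the four-way
consensus, removes indication terms, and flags consensus signals absent from
the product label as unexpected.  The result object carries the ranked
signal table and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .cases import CaseUniverse
from .stats import ContingencyTable, Thresholds, metrics_frame, mgps_ebgm

__all__ = ["build_contingency", "DisproportionalityScreen", "ScreenResults"]


def build_contingency(universe: CaseUniverse, pt: str) -> ContingencyTable:
    """The 2x2 report-count table for the target drug and one PT.

    The counting unit is the report: ``a`` counts target-drug reports
    mentioning the PT (a report with k distinct PTs contributes to k
    tables), and the margins complete over the whole universe.  A PT absent
    everywhere yields ``a = c = 0``.
    """
    if not pt:
        raise ValueError("pt must be nonempty")
    rx = universe.reactions
    with_pt = set(rx.loc[rx["pt"] == pt, "primaryid"])
    n_target = universe.n_target
    n_total = universe.n_reports
    a = sum(1 for pid in with_pt if universe.is_target_id(pid))
    c = len(with_pt) - a
    return ContingencyTable(a=a, b=n_target - a, c=c, d=n_total - n_target - c)


@dataclass(frozen=True)
class ScreenOptions:
    ic_variance: str = "bate"          # "bate" | "approx"
    ebgm_mode: str = "ratio"           # "ratio" (observed/expected) | "shrinkage"
    haldane: bool = False              # +0.5 continuity correction for exploration


class DisproportionalityScreen:
    """Four-algorithm signal screen for one target drug.

    Parameters
    ----------
    universe : CaseUniverse
        Full deduplicated report universe; comparator margins use every
        report, target-drug reports are those flagged ``is_target``.
    indication_exclusions : iterable of str
        PTs that are plausible indications; removed before decisions.
    label_pts : iterable of str
        PTs on the product label; consensus signals outside this list are
        flagged unexpected.
    thresholds : Thresholds
        Per-algorithm positivity criteria.
    pt_soc_map : DataFrame, optional
        Columns ``pt`` and ``soc_name`` (and optionally ``soc_code``) to
        annotate output rows with their system organ class.
    """

    def __init__(self, universe: CaseUniverse,
                 indication_exclusions: Iterable[str] = (),
                 label_pts: Iterable[str] = (),
                 thresholds: Thresholds = Thresholds(),
                 pt_soc_map: pd.DataFrame | None = None,
                 options: ScreenOptions = ScreenOptions()):
        self.universe = universe
        self.indication_exclusions = set(indication_exclusions)
        self.label_pts = set(label_pts)
        self.thresholds = thresholds
        self.pt_soc_map = pt_soc_map
        self.options = options

    def fit(self) -> "ScreenResults":
        tab = self.universe.pt_counts()
        tab = tab[tab["a"] > 0]                      # PTs observed with the drug
        tab = tab[~tab.index.isin(self.indication_exclusions)]

        n_target = self.universe.n_target
        n_total = self.universe.n_reports
        a = tab["a"].to_numpy(float)
        c = (tab["n_pt"] - tab["a"]).to_numpy(float)
        b = n_target - a
        d = (n_total - n_target) - c
        if self.options.haldane:
            a, b, c, d = (x + 0.5 for x in (a, b, c, d))

        m = metrics_frame(a, b, c, d, ic_variance=self.options.ic_variance)
        if self.options.ebgm_mode == "shrinkage":
            e = (a + c) * (a + b) / (a + b + c + d)
            ebgm, eb05 = mgps_ebgm(a, e)
            m["ebgm"], m["ebgm05"] = ebgm, eb05
        elif self.options.ebgm_mode != "ratio":
            raise ValueError(f"unknown ebgm mode {self.options.ebgm_mode!r}")

        t = self.thresholds
        n = tab["a"].to_numpy(int)
        pass_ror = _defined(m["ror_lo"]) & (m["ror_lo"] > t.ror_ci_low) & (n >= t.min_n)
        pass_prr = (_defined(m["prr"]) & _defined(m["chi2"])
                    & (m["prr"] >= t.prr_min) & (m["chi2"] >= t.chi2_min)
                    & (n >= t.min_n))
        pass_bcpnn = _defined(m["ic025"]) & (m["ic025"] > t.ic025_min)
        pass_mgps = _defined(m["ebgm05"]) & (m["ebgm05"] > t.ebgm05_min)
        consensus = pass_ror & pass_prr & pass_bcpnn & pass_mgps

        frame = pd.DataFrame({
            "pt": tab.index,
            "n": n,
            **{k: m[k] for k in ("ror", "ror_lo", "ror_hi", "prr", "chi2",
                                 "ic", "ic025", "ebgm", "ebgm05")},
            "pass_ror": pass_ror, "pass_prr": pass_prr,
            "pass_bcpnn": pass_bcpnn, "pass_mgps": pass_mgps,
            "consensus": consensus,
        })
        frame["unexpected"] = frame["consensus"] & ~frame["pt"].isin(self.label_pts)
        if self.pt_soc_map is not None:
            cols = [c for c in ("pt", "soc_name", "soc_code")
                    if c in self.pt_soc_map.columns]
            frame = frame.merge(self.pt_soc_map[cols], on="pt", how="left")
        # rank by EBGM descending; ties by descending n, then lexical PT
        frame = frame.sort_values(["ebgm", "n", "pt"],
                                  ascending=[False, False, True],
                                  kind="mergesort", na_position="last")
        frame = frame.reset_index(drop=True)
        return ScreenResults(self, frame)


def _defined(x: np.ndarray) -> np.ndarray:
    return ~np.isnan(x)


class ScreenResults:
    """Ranked signal table from a fitted :class:`DisproportionalityScreen`."""

    def __init__(self, model: DisproportionalityScreen, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def consensus_pts(self) -> set[str]:
        return set(self.frame.loc[self.frame["consensus"], "pt"])

    @property
    def unexpected_pts(self) -> set[str]:
        return set(self.frame.loc[self.frame["unexpected"], "pt"])

    def positive(self, algorithm: str) -> set[str]:
        """Positive PTs under one algorithm: ror | prr | bcpnn | mgps."""
        return set(self.frame.loc[self.frame[f"pass_{algorithm}"], "pt"])

    def top(self, k: int = 50) -> pd.DataFrame:
        return self.frame.head(k)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g",
                          lineterminator="\n")

    def summary(self, k: int = 10) -> str:
        u = self.model.universe
        lines = [
            "Disproportionality screen",
            "=" * 60,
            f"universe reports:        {u.n_reports}",
            f"target-drug reports:     {u.n_target}",
            f"PTs screened:            {len(self.frame)}",
            f"consensus signals:       {int(self.frame['consensus'].sum())}",
            f"unexpected signals:      {int(self.frame['unexpected'].sum())}",
            "",
            f"top {k} by EBGM:",
        ]
        cols = ["pt", "n", "ror", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05",
                "consensus"]
        lines.append(self.frame[cols].head(k).to_string(
            index=False, float_format=lambda v: f"{v:.2f}"))
        return "\n".join(lines)
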