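"""Analysis-ready safety-report containers shared by the FAERS and JADER readers.

A :class:`CaseReport` is one deduplicated spontaneous report; downstream
stages (screening, sex-stratified analysis, time-to-onset) consume lists of
these regardless of source database.  :class:`CaseUniverse` wraps the full
deduplicated report universe — target-drug cases plus the background of all
other reports — as the pair of tables the 2x2 margins are computed from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SEXES = ("F", "M", "UNK")
ROLES = ("PS", "SS", "C", "I")
AGE_GROUPS = ("<18", "18-65", ">65", "UNK")
WEIGHT_BANDS = ("<50", "50-100", ">100", "UNK")


def age_group(age_years: float | None) -> str:
    if age_years is None or pd.isna(age_years):
        return "UNK"
    if age_years < 18:
        return "<18"
    if age_years <= 65:
        return "18-65"
    return ">65"


def weight_band(weight_kg: float | None) -> str:
    if weight_kg is None or pd.isna(weight_kg):
        return "UNK"
    if weight_kg < 50:
        return "<50"
    if weight_kg <= 100:
        return "50-100"
    return ">100"


@dataclass
class DrugEntry:
    name: str
    active_ingredient: str = ""
    role: str = "PS"
    start_date: str | None = None
    is_target: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass
class CaseReport:
    """One deduplicated safety report (one canonical record per CASEID)."""

    primaryid: str
    caseid: str
    fda_dt: str
    sex: str = "UNK"
    age_years: float | None = None
    weight_kg: float | None = None
    country: str = ""
    reporter: str = "unknown"  # health-professional / consumer / unknown
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    therapy_start: str | None = None
    event_date: str | None = None

    @property
    def age_group(self) -> str:
        return age_group(self.age_years)

    @property
    def weight_band(self) -> str:
        return weight_band(self.weight_kg)

    @property
    def is_monotherapy(self) -> bool:
        """True when no drug other than the target appears on the report."""
        return len(self.drugs) > 0 and all(d.is_target for d in self.drugs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseReport":
        d = dict(d)
        d["drugs"] = [DrugEntry(**e) for e in d.get("drugs", [])]
        return cls(**d)


def write_cases(cases: Iterable[CaseReport], path: str | Path) -> None:
    """Serialise cases to JSON-lines (text, round-trips every field)."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in cases:
            fh.write(json.dumps(c.to_dict(), ensure_ascii=False, sort_keys=True) + "\n")


def read_cases(path: str | Path) -> list[CaseReport]:
    with open(path, encoding="utf-8") as fh:
        return [CaseReport.from_dict(json.loads(line)) for line in fh if line.strip()]


class CaseUniverse:
    """The full deduplicated report universe underlying every 2x2 table.

    Parameters
    ----------
    reports : DataFrame
        One row per deduplicated report with at least columns
        ``primaryid`` and boolean ``is_target`` (target drug present with an
        accepted role).
    reactions : DataFrame
        Unique ``(primaryid, pt)`` pairs over the whole universe.
    """

    def __init__(self, reports: pd.DataFrame, reactions: pd.DataFrame):
        if "primaryid" not in reports or "is_target" not in reports:
            raise ValueError("reports needs 'primaryid' and 'is_target' columns")
        if not {"primaryid", "pt"} <= set(reactions.columns):
            raise ValueError("reactions needs 'primaryid' and 'pt' columns")
        self.reports = reports.reset_index(drop=True)
        self.reactions = reactions.drop_duplicates(["primaryid", "pt"]).reset_index(drop=True)
        self._target_ids = set(reports.loc[reports["is_target"], "primaryid"])

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def n_target(self) -> int:
        return len(self._target_ids)

    def is_target_id(self, primaryid) -> bool:
        return primaryid in self._target_ids

    def pt_counts(self) -> pd.DataFrame:
        """Per-PT report counts split by target-drug membership.

        Returns a frame indexed by ``pt`` with columns ``a`` (target-drug
        reports mentioning the PT) and ``n_pt`` (all reports mentioning it).
        """
        rx = self.reactions
        on_target = rx["primaryid"].isin(self._target_ids)
        tab = pd.DataFrame({
            "n_pt": rx.groupby("pt", sort=True).size(),
            "a": rx[on_target].groupby("pt", sort=True).size(),
        })
        tab["a"] = tab["a"].fillna(0).astype(int)
        tab["n_pt"] = tab["n_pt"].astype(int)
        return tab

    @classmethod
    def from_case_reports(cls, cases: Sequence[CaseReport],
                          background: pd.DataFrame | None = None) -> "CaseUniverse":
        """Build a universe directly from assembled target cases plus an
        optional background reactions table (``primaryid``, ``pt``)."""
        rows = []
        rx = []
        for c in cases:
            rows.append({"primaryid": c.primaryid, "is_target": True})
            rx.extend({"primaryid": c.primaryid, "pt": p} for p in c.reactions)
        reports = pd.DataFrame(rows, columns=["primaryid", "is_target"])
        reactions = pd.DataFrame(rx, columns=["primaryid", "pt"])
        if background is not None and len(background):
            bg_ids = pd.DataFrame({
                "primaryid": background["primaryid"].unique(), "is_target": False})
            reports = pd.concat([reports, bg_ids], ignore_index=True)
            reactions = pd.concat([reactions, background[["primaryid", "pt"]]],
                                  ignore_index=True)
        return cls(reports, reactions)
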