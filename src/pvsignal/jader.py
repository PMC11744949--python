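"""JADER-style ingestion: DEMO/DRUG/REAC/HIST linkage and case assembly.

JADER distributes comma-separated tables keyed by a case identifier.  The
DRUG table carries the standardized generic name and an influence category
(PS - primary suspect, C - concomitant, I - interaction); the REAC table
carries the adverse-event name, outcome, and date of occurrence.  Real files
are Shift-JIS encoded; the reader takes an ``encoding`` argument and the
bundled synthetic fixtures are UTF-8.

Assembled cases expose the same :class:`~pvsignal.cases.CaseReport` fields
as FAERS ones, so every downstream stage is source-agnostic.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .cases import CaseReport, CaseUniverse, DrugEntry
from .errors import EncodingError, SchemaError

logger = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "HIST")

REQUIRED_COLUMNS = {
    "DEMO": ("case_id", "sex"),
    "DRUG": ("case_id", "influence", "generic_name"),
    "REAC": ("case_id", "reaction"),
    "HIST": ("case_id",),
}


class JaderTables:
    """The four JADER tables as string-typed DataFrames."""

    def __init__(self, demo, drug, reac, hist):
        self.demo, self.drug, self.reac, self.hist = demo, drug, reac, hist

    def __getitem__(self, name: str) -> pd.DataFrame:
        return getattr(self, name.lower())


def _find_file(directory: Path, table: str) -> Path | None:
    cands = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.name.lower().startswith(table.lower())
                   and p.suffix.lower() == ".csv")
    return cands[0] if cands else None


def read_jader(path: str | Path, encoding: str = "utf-8") -> JaderTables:
    """Read the four CSV tables from a directory.

    Raises :class:`EncodingError` (naming file and byte offset) when the
    bytes cannot be decoded, and :class:`SchemaError` when a table or a
    required column is missing.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise SchemaError(f"{directory} is not a directory")
    frames = {}
    for table in TABLE_NAMES:
        f = _find_file(directory, table)
        if f is None:
            raise SchemaError(f"{directory}: no {table} csv found")
        try:
            df = pd.read_csv(f, dtype=str, keep_default_na=False, encoding=encoding)
        except UnicodeDecodeError as e:
            raise EncodingError(
                f"{f}: cannot decode byte at offset {e.start} as {encoding}"
            ) from e
        missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
        if missing:
            raise SchemaError(f"{f}: missing required column(s) {missing}")
        frames[table.lower()] = df
    return JaderTables(**frames)


def dedup_exact_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Drop byte-identical duplicate rows (JADER table-level dedup rule)."""
    return df.drop_duplicates().reset_index(drop=True)


def assemble_jader_cases(raw: JaderTables, target_name: str,
                         role_filter: Iterable[str] = ("PS",)) -> list[CaseReport]:
    """CaseReports for cases naming ``target_name`` with an accepted influence.

    Exact-duplicate rows within DRUG and REAC are dropped first; DEMO is then
    linked on the case identifier.  Matching on the generic name is exact
    (JADER names are standardized).  Cases lacking a DEMO row are excluded
    and logged.
    """
    roles = set(role_filter)
    drug = dedup_exact_rows(raw.drug)
    reac = dedup_exact_rows(raw.reac)
    demo = raw.demo.drop_duplicates("case_id")

    tmask = (drug["generic_name"] == target_name) & drug["influence"].isin(roles)
    wanted = set(drug.loc[tmask, "case_id"])
    demo_ids = set(demo["case_id"])
    orphans = wanted - demo_ids
    for cid in sorted(orphans):
        logger.warning("JADER case %s has no DEMO row; excluded", cid)
    wanted &= demo_ids

    drugs_by_case: dict[str, list[DrugEntry]] = {}
    start_by_case: dict[str, str] = {}
    for row in drug[drug["case_id"].isin(wanted)].itertuples(index=False):
        is_target = row.generic_name == target_name
        role = row.influence if row.influence in ("PS", "C", "I") else "C"
        drugs_by_case.setdefault(row.case_id, []).append(DrugEntry(
            name=row.generic_name, active_ingredient=row.generic_name,
            role=role, start_date=getattr(row, "start_date", "") or None,
            is_target=is_target))
        if is_target and row.influence in roles and row.case_id not in start_by_case:
            start_by_case[row.case_id] = getattr(row, "start_date", "") or None

    reac_by_case: dict[str, list[tuple[str, str]]] = {}
    for row in reac[reac["case_id"].isin(wanted)].itertuples(index=False):
        reac_by_case.setdefault(row.case_id, []).append(
            (row.reaction, getattr(row, "event_date", "") or None))

    cases: list[CaseReport] = []
    for row in demo[demo["case_id"].isin(wanted)].itertuples(index=False):
        cid = row.case_id
        rx = reac_by_case.get(cid, [])
        if not rx:
            logger.debug("JADER case %s has no reactions; skipped", cid)
            continue
        seen: list[str] = []
        for pt, _ in rx:
            if pt not in seen:
                seen.append(pt)
        # single onset date per case: first nonmissing occurrence date
        event = next((e for _, e in rx if e), None)
        age = getattr(row, "age", "")
        try:
            age_years = float(age) if age not in ("", None) else None
        except ValueError:
            age_years = None
        wt = getattr(row, "weight", "")
        try:
            weight = float(wt) if wt not in ("", None) else None
        except ValueError:
            weight = None
        cases.append(CaseReport(
            primaryid=cid, caseid=cid, fda_dt="",
            sex=row.sex if row.sex in ("F", "M") else "UNK",
            age_years=age_years, weight_kg=weight, country="JP",
            reporter="unknown",
            drugs=drugs_by_case.get(cid, []),
            reactions=seen,
            indications=[], outcomes=[],
            therapy_start=start_by_case.get(cid),
            event_date=event,
        ))
    return cases


def build_universe(raw: JaderTables, target_name: str,
                   role_filter: Iterable[str] = ("PS",)) -> CaseUniverse:
    """Full deduplicated JADER universe with a target-case flag."""
    roles = set(role_filter)
    drug = dedup_exact_rows(raw.drug)
    reac = dedup_exact_rows(raw.reac)
    demo = raw.demo.drop_duplicates("case_id")
    tmask = (drug["generic_name"] == target_name) & drug["influence"].isin(roles)
    target_ids = set(drug.loc[tmask, "case_id"])
    reports = pd.DataFrame({"primaryid": demo["case_id"],
                            "caseid": demo["case_id"]})
    reports["is_target"] = reports["primaryid"].isin(target_ids)
    reactions = reac.rename(columns={"case_id": "primaryid", "reaction": "pt"})
    reactions = reactions[reactions["primaryid"].isin(set(demo["case_id"]))]
    return CaseUniverse(reports, reactions[["primaryid", "pt"]])
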