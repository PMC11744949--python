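"""FAERS quarterly-extract ingestion: parsing, deduplication, case assembly.

The FAERS ASCII dialect is a set of "$"-delimited tables (DEMO, DRUG, REAC,
THER, INDI, OUTC) keyed by PRIMARYID, one directory per quarter.  Ingestion
concatenates quarters, deduplicates cases by the regulatory rule (keep the
most recent FDA_DT per CASEID, then the higher PRIMARYID), selects reports
naming the target drug with an accepted role code (primary suspect by
default), and assembles :class:`~pvsignal.cases.CaseReport` objects.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cases import CaseReport, CaseUniverse, DrugEntry
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC")

REQUIRED_COLUMNS = {
    "DEMO": ("PRIMARYID", "CASEID", "FDA_DT"),
    "DRUG": ("PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"),
    "REAC": ("PRIMARYID", "PT"),
    "THER": ("PRIMARYID", "DSG_DRUG_SEQ", "START_DT"),
    "INDI": ("PRIMARYID", "INDI_PT"),
    "OUTC": ("PRIMARYID", "OUTC_COD"),
}

# legacy / current column-spelling aliases, applied on read
COLUMN_ALIASES = {
    "ISR": "PRIMARYID",
    "CASE": "CASEID",
    "GNDR_COD": "SEX",
    "INDI_DRUG_SEQ": "DSG_DRUG_SEQ",
    "OUTC_COD ": "OUTC_COD",
}


@dataclass
class RawTables:
    """The six FAERS tables as string-typed DataFrames."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame

    def __getitem__(self, name: str) -> pd.DataFrame:
        return getattr(self, name.lower())

    def restrict(self, primaryids: Iterable[str]) -> "RawTables":
        """Keep only rows whose PRIMARYID is in the given set."""
        keep = set(primaryids)
        return RawTables(*(
            getattr(self, t.lower())[
                getattr(self, t.lower())["PRIMARYID"].isin(keep)
            ].reset_index(drop=True)
            for t in TABLE_NAMES
        ))


def _find_table_file(directory: Path, table: str) -> Path | None:
    cands = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.name.upper().startswith(table)
    )
    return cands[0] if cands else None


def _read_table(path: Path, table: str, bad_line_tolerance: float) -> pd.DataFrame:
    bad: list[int] = []

    def on_bad(fields):
        bad.append(1)
        return None

    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                     engine="python", on_bad_lines=on_bad)
    df.columns = [COLUMN_ALIASES.get(c.strip().upper(), c.strip().upper())
                  for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for {table}")
    if bad:
        frac = len(bad) / max(len(df) + len(bad), 1)
        logger.warning("%s: %d malformed row(s) skipped (%.2f%%)",
                       path, len(bad), 100 * frac)
        if frac > bad_line_tolerance:
            raise SchemaError(
                f"{path}: {len(bad)} malformed rows exceed tolerance "
                f"{bad_line_tolerance:.2%}")
    return df


def read_faers_quarters(paths: Sequence[str | Path],
                        bad_line_tolerance: float = 0.01) -> RawTables:
    """Read and concatenate one or more quarterly directories.

    Each directory must contain the six table files (identified by filename
    prefix, case-insensitive).  Malformed rows are counted and logged; the
    read fails only when their fraction exceeds ``bad_line_tolerance``.
    """
    if not paths:
        raise SchemaError("no quarterly directories given")
    parts: dict[str, list[pd.DataFrame]] = {t: [] for t in TABLE_NAMES}
    for p in paths:
        directory = Path(p)
        if not directory.is_dir():
            raise SchemaError(f"{directory} is not a directory")
        for table in TABLE_NAMES:
            f = _find_table_file(directory, table)
            if f is None:
                raise SchemaError(f"{directory}: no {table} table file found")
            parts[table].append(_read_table(f, table, bad_line_tolerance))
    merged = {t: pd.concat(parts[t], ignore_index=True) for t in TABLE_NAMES}
    return RawTables(**{t.lower(): merged[t] for t in TABLE_NAMES})


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One canonical row per CASEID.

    Retains, within each CASEID, the row with the most recent FDA_DT; among
    rows sharing that FDA_DT, the one with the higher PRIMARYID.  The result
    is independent of input row order and idempotent.
    """
    for col in ("CASEID", "FDA_DT", "PRIMARYID"):
        if col not in demo.columns:
            raise SchemaError(f"deduplicate: DEMO lacks column {col}")
    if demo.empty:
        return demo.copy()
    key = demo.assign(
        _fda=pd.to_numeric(demo["FDA_DT"], errors="coerce").fillna(-1),
        _pid=pd.to_numeric(demo["PRIMARYID"], errors="coerce").fillna(-1),
    )
    key = key.sort_values(["CASEID", "_fda", "_pid"], kind="mergesort")
    out = key.groupby("CASEID", sort=True).tail(1)
    return out.drop(columns=["_fda", "_pid"]).reset_index(drop=True)


def apply_dedup(raw: RawTables) -> RawTables:
    """Deduplicate DEMO and drop non-retained PRIMARYIDs from every table."""
    demo = deduplicate(raw.demo)
    out = raw.restrict(demo["PRIMARYID"])
    out.demo = demo.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# target-drug matching


_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Uppercase, strip punctuation, collapse internal whitespace."""
    s = _PUNCT_RE.sub(" ", str(name).upper())
    return _WS_RE.sub(" ", s).strip()


def match_target_drug(drug: pd.DataFrame, synonyms: Sequence[str],
                      exact: bool = False,
                      role_filter: Iterable[str] | None = None) -> set[str]:
    """PRIMARYIDs whose DRUGNAME or PROD_AI matches any synonym.

    Matching is substring containment on normalized names by default
    (``exact=True`` requires full equality).  ``role_filter`` optionally
    restricts to rows whose ROLE_COD is in the given set.
    """
    if not synonyms:
        raise ValidationError("synonym list must be nonempty")
    norm_syn = [normalize_drug_name(s) for s in synonyms]
    names = drug["DRUGNAME"].map(normalize_drug_name)
    if "PROD_AI" in drug.columns:
        ais = drug["PROD_AI"].map(normalize_drug_name)
    else:
        ais = pd.Series("", index=drug.index)

    if exact:
        mask = names.isin(norm_syn) | ais.isin(norm_syn)
    else:
        mask = pd.Series(False, index=drug.index)
        for s in norm_syn:
            mask |= names.str.contains(s, regex=False) | ais.str.contains(s, regex=False)
    if role_filter is not None:
        mask &= drug["ROLE_COD"].isin(set(role_filter))
    return set(drug.loc[mask, "PRIMARYID"])


def target_drug_mask(drug: pd.DataFrame, synonyms: Sequence[str],
                     exact: bool = False) -> pd.Series:
    """Boolean row mask over the DRUG table for the target drug."""
    if not synonyms:
        raise ValidationError("synonym list must be nonempty")
    norm_syn = [normalize_drug_name(s) for s in synonyms]
    names = drug["DRUGNAME"].map(normalize_drug_name)
    ais = (drug["PROD_AI"].map(normalize_drug_name)
           if "PROD_AI" in drug.columns else pd.Series("", index=drug.index))
    if exact:
        return names.isin(norm_syn) | ais.isin(norm_syn)
    mask = pd.Series(False, index=drug.index)
    for s in norm_syn:
        mask |= names.str.contains(s, regex=False) | ais.str.contains(s, regex=False)
    return mask


# ---------------------------------------------------------------------------
# age / reporter harmonisation


_AGE_FACTORS = {"YR": 1.0, "YEAR": 1.0, "DEC": 10.0, "MON": 1 / 12.0,
                "WK": 1 / 52.0, "DY": 1 / 365.25, "HR": 1 / 8766.0}


def age_to_years(age: str, age_cod: str) -> float | None:
    try:
        v = float(age)
    except (TypeError, ValueError):
        return None
    factor = _AGE_FACTORS.get(str(age_cod).strip().upper() or "YR")
    if factor is None or v < 0:
        return None
    return v * factor


def _to_float(v) -> float | None:
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


_HP_CODES = {"MD", "PH", "OT", "HP", "RN"}


def reporter_type(occp_cod: str) -> str:
    code = str(occp_cod).strip().upper()
    if code in _HP_CODES:
        return "health-professional"
    if code == "CN":
        return "consumer"
    return "unknown"


# ---------------------------------------------------------------------------
# case assembly


def assemble_cases(raw: RawTables, synonyms: Sequence[str],
                   role_filter: Iterable[str] = ("PS",),
                   exact: bool = False) -> list[CaseReport]:
    """One CaseReport per deduplicated report naming the target drug with an
    accepted role.  ``raw`` must already be deduplicated (see
    :func:`apply_dedup`); therapy start is taken from the THER row matching
    the target drug's sequence number.
    """
    roles = set(role_filter)
    tmask = target_drug_mask(raw.drug, synonyms, exact=exact)
    target_rows = raw.drug[tmask & raw.drug["ROLE_COD"].isin(roles)]
    wanted = set(target_rows["PRIMARYID"])
    if not wanted:
        return []

    demo = raw.demo[raw.demo["PRIMARYID"].isin(wanted)]
    drug = raw.drug[raw.drug["PRIMARYID"].isin(wanted)]
    drug_target = tmask.reindex(drug.index, fill_value=False)
    reac = raw.reac[raw.reac["PRIMARYID"].isin(wanted)]
    ther = raw.ther[raw.ther["PRIMARYID"].isin(wanted)]
    indi = raw.indi[raw.indi["PRIMARYID"].isin(wanted)]
    outc = raw.outc[raw.outc["PRIMARYID"].isin(wanted)]

    drugs_by_pid: dict[str, list[DrugEntry]] = {}
    target_seq: dict[str, str] = {}
    for row, is_t in zip(drug.itertuples(index=False), drug_target):
        entry = DrugEntry(
            name=row.DRUGNAME,
            active_ingredient=getattr(row, "PROD_AI", ""),
            role=row.ROLE_COD if row.ROLE_COD in ("PS", "SS", "C", "I") else "C",
            is_target=bool(is_t),
        )
        drugs_by_pid.setdefault(row.PRIMARYID, []).append(entry)
        if is_t and row.ROLE_COD in roles and row.PRIMARYID not in target_seq:
            target_seq[row.PRIMARYID] = str(row.DRUG_SEQ)

    reac_by_pid: dict[str, list[str]] = {}
    for row in reac.itertuples(index=False):
        lst = reac_by_pid.setdefault(row.PRIMARYID, [])
        if row.PT not in lst:
            lst.append(row.PT)
    indi_by_pid: dict[str, list[str]] = {}
    for row in indi.itertuples(index=False):
        indi_by_pid.setdefault(row.PRIMARYID, []).append(row.INDI_PT)
    outc_by_pid: dict[str, list[str]] = {}
    for row in outc.itertuples(index=False):
        outc_by_pid.setdefault(row.PRIMARYID, []).append(row.OUTC_COD)
    ther_by_pid_seq: dict[tuple[str, str], str] = {}
    for row in ther.itertuples(index=False):
        ther_by_pid_seq.setdefault((row.PRIMARYID, str(row.DSG_DRUG_SEQ)),
                                   row.START_DT)

    cases: list[CaseReport] = []
    for row in demo.itertuples(index=False):
        pid = row.PRIMARYID
        reactions = reac_by_pid.get(pid, [])
        if not reactions:
            logger.debug("report %s has no reactions; skipped", pid)
            continue
        seq = target_seq.get(pid)
        start = ther_by_pid_seq.get((pid, seq)) if seq is not None else None
        entries = drugs_by_pid.get(pid, [])
        for e in entries:
            if e.is_target and e.role in roles:
                e.start_date = start or None
        cases.append(CaseReport(
            primaryid=pid,
            caseid=row.CASEID,
            fda_dt=row.FDA_DT,
            sex=(getattr(row, "SEX", "") or "UNK")
                if getattr(row, "SEX", "UNK") in ("F", "M") else "UNK",
            age_years=age_to_years(getattr(row, "AGE", ""), getattr(row, "AGE_COD", "YR")),
            weight_kg=_to_float(getattr(row, "WT", "")),
            country=getattr(row, "OCCR_COUNTRY", ""),
            reporter=reporter_type(getattr(row, "OCCP_COD", "")),
            drugs=entries,
            reactions=reactions,
            indications=indi_by_pid.get(pid, []),
            outcomes=outc_by_pid.get(pid, []),
            therapy_start=start or None,
            event_date=(getattr(row, "EVENT_DT", "") or None),
        ))
    return cases


def build_universe(raw: RawTables, synonyms: Sequence[str],
                   role_filter: Iterable[str] = ("PS",),
                   exact: bool = False) -> CaseUniverse:
    """Deduplicated full-database universe with a target-report flag.

    Comparator margins (cells b, c, d) are computed over every deduplicated
    report regardless of drug or role; the target flag marks reports naming
    the target drug with a role in ``role_filter``.
    """
    target_ids = {
        pid for pid in match_target_drug(raw.drug, synonyms, exact=exact,
                                         role_filter=set(role_filter))
    }
    reports = pd.DataFrame({
        "primaryid": raw.demo["PRIMARYID"],
        "caseid": raw.demo["CASEID"],
    })
    reports["is_target"] = reports["primaryid"].isin(target_ids)
    reactions = raw.reac.rename(columns={"PRIMARYID": "primaryid", "PT": "pt"})
    return CaseUniverse(reports, reactions[["primaryid", "pt"]])
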