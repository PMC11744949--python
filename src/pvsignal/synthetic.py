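"""Synthetic spontaneous-report generator with known ground truth.

Emits FAERS-dialect ("$"-delimited DEMO/DRUG/REAC/THER/INDI/OUTC) and
JADER-dialect (comma-separated DEMO/DRUG/REAC/HIST) raw files that exercise
every downstream stage: duplicate case submissions, drug role codes, partial
dates, negative onset intervals, planted drug-event association strengths and
Weibull-distributed onset times.

The generative model is deliberately simple.  Each report has one primary
suspect drug drawn uniformly from ``n_drugs``; event terms are independent
Bernoulli draws whose rate for a planted (drug, PT) pair is the background
rate multiplied by the planted relative risk, so the marginal
P(PT | focal drug) / P(PT | other drug) converges to the planted RR and the
downstream reporting odds ratio estimates it.  Time to onset is a rounded
Weibull(scale, shape) draw added to the therapy start date.  All randomness
derives from a single seeded generator, so identical configurations produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "GroundTruth", "generate_faers", "generate_jader",
           "simulate_faers", "simulate_jader", "simulate_universe", "write_pt_soc_map", "CATCHALL_PT",
           "FOCAL_SYNONYMS", "JADER_FOCAL_NAME"]

# Focal-drug spellings planted in FAERS DRUGNAME (with case/spacing noise).
FOCAL_SYNONYMS = (
    "INVEGA SUSTENNA",
    "Invega Sustenna 156 MG",
    "PALIPERIDONE PALMITATE",
    "INVEGA  TRINZA",
)
FOCAL_PROD_AI = "PALIPERIDONE PALMITATE"
# Standardised generic name used in the JADER dialect.
JADER_FOCAL_NAME = "パリペリドンパルミチン酸エステル"

_BASE_DATE = np.datetime64("2015-01-01")

_OUTCOME_CODES = np.array(["HO", "OT", "DE", "LT", "DS", "CA", "RI"])
_OUTCOME_P = np.array([0.45, 0.39, 0.10, 0.03, 0.02, 0.005, 0.005])
_COUNTRIES = np.array(["US", "FR", "JP", "GB", "CO", "DE"])
_COUNTRY_P = np.array([0.75, 0.05, 0.05, 0.04, 0.03, 0.08])
_OCCP = np.array(["MD", "PH", "OT", "CN", ""])
_OCCP_P = np.array([0.40, 0.20, 0.18, 0.21, 0.01])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic database.

    Defaults mirror the demographic mix of real paliperidone-palmitate
    reporting (≈24% unknown sex, ≈41% female among known, mostly missing age
    and weight) and an onset distribution Weibull(scale 69.1 d, shape 0.67),
    whose median is 40 days.
    """

    n_reports: int = 20_000
    n_drugs: int = 20
    n_pts: int = 50
    pt_soc_map_size: int = 10
    planted_signals: tuple[tuple[int, int, float], ...] = ()
    background_report_rate: float = 0.01
    duplicate_rate: float = 0.15
    partial_date_rate: float = 0.20
    negative_tto_rate: float = 0.02
    event_date_missing_rate: float = 0.30
    tto_weibull: tuple[float, float] = (69.1, 0.67)
    sex_ratio: float = 0.41
    sex_unknown_rate: float = 0.237
    age_missing_rate: float = 0.63
    weight_missing_rate: float = 0.84
    concomitant_rate: float = 0.50
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        for name in ("n_reports", "n_drugs", "n_pts", "pt_soc_map_size"):
            if getattr(self, name) <= 0:
                bad.append(name)
        for name in ("background_report_rate", "duplicate_rate", "partial_date_rate",
                     "negative_tto_rate", "event_date_missing_rate", "sex_ratio",
                     "sex_unknown_rate", "age_missing_rate", "weight_missing_rate",
                     "concomitant_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(name)
        if self.tto_weibull[0] <= 0 or self.tto_weibull[1] <= 0:
            bad.append("tto_weibull")
        for d, j, rr in self.planted_signals:
            if not (0 <= d < self.n_drugs and 0 <= j < self.n_pts and rr >= 0):
                bad.append(f"planted_signals({d},{j},{rr})")
        if bad:
            raise ValueError("invalid SyntheticConfig fields: " + ", ".join(bad))


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    planted: list[tuple[str, float]]          # (pt name, relative risk) on the focal drug
    planted_pairs: list[tuple[int, str, float]]  # (drug id, pt name, rr)
    tto_alpha: float
    tto_beta: float
    canonical: dict[str, str]                 # CASEID -> surviving PRIMARYID
    n_cases: int
    n_target_ps_cases: int                    # canonical cases with focal drug as PS
    n_target_monotherapy: int
    comention: dict[tuple[int, str], int]     # (drug id, pt) -> canonical report count
    pt_names: list[str] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)


CATCHALL_PT = "UNSPECIFIED ADVERSE EVENT"


def _pt_name(j: int) -> str:
    return f"PT_{j:03d}"


def _pt_label(j: int, n_pts: int) -> str:
    return CATCHALL_PT if j >= n_pts else _pt_name(j)


def _soc_of(j: int, n_socs: int) -> tuple[str, int]:
    s = j % n_socs
    return f"SOC_{s:02d}", 10000000 + s


def write_pt_soc_map(n_pts: int, n_socs: int, path: str | Path,
                     include_catchall: bool = True) -> pd.DataFrame:
    """Write the TSV PT->SOC mapping (columns pt, soc_name, soc_code)."""
    rows = []
    for j in range(n_pts):
        name, code = _soc_of(j, n_socs)
        rows.append({"pt": _pt_name(j), "soc_name": name, "soc_code": code})
    if include_catchall:
        name, code = _soc_of(0, n_socs)
        rows.append({"pt": CATCHALL_PT, "soc_name": name, "soc_code": code})
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return df


def _dates_to_str(days: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    """CCYYMMDD strings for integer day offsets from the base date."""
    dt = _BASE_DATE + days.astype("timedelta64[D]")
    s = np.datetime_as_string(dt, unit="D")
    out = np.char.replace(s, "-", "")
    if missing is not None:
        out = np.where(missing, "", out)
    return out


def _truncate_partial(dates: np.ndarray, mask: np.ndarray, halves: np.ndarray) -> np.ndarray:
    """Truncate masked CCYYMMDD strings to CCYYMM (halves) or CCYY."""
    out = dates.astype(object)
    mm = mask & (dates != "") & halves
    ym = mask & (dates != "") & ~halves
    for idx in np.nonzero(mm)[0]:
        out[idx] = out[idx][:6]
    for idx in np.nonzero(ym)[0]:
        out[idx] = out[idx][:4]
    return out.astype(str)


def _rate_matrix(cfg: SyntheticConfig) -> np.ndarray:
    rates = np.full((cfg.n_drugs, cfg.n_pts), cfg.background_report_rate)
    for d, j, rr in cfg.planted_signals:
        rates[d, j] = min(cfg.background_report_rate * rr, 0.95)
    return rates


def _core_draw(cfg: SyntheticConfig, rng: np.random.Generator):
    """Per-case draws shared by the FAERS and JADER emitters."""
    n = cfg.n_reports
    suspect = rng.integers(0, cfg.n_drugs, size=n)
    # Reaction indicator matrix; planted pairs inflate the Bernoulli rate.
    # Reports with no sampled term get the catch-all column (index n_pts),
    # which keeps every per-PT marginal rate — and hence each planted
    # relative risk — exactly as configured while guaranteeing >= 1 reaction.
    rates = _rate_matrix(cfg)[suspect]              # (n, n_pts)
    hits = np.zeros((n, cfg.n_pts + 1), dtype=bool)
    hits[:, : cfg.n_pts] = rng.random((n, cfg.n_pts)) < rates
    hits[~hits.any(axis=1), cfg.n_pts] = True

    sex_u = rng.random(n)
    sex_f = rng.random(n)
    sex = np.where(sex_u < cfg.sex_unknown_rate, "UNK",
                   np.where(sex_f < cfg.sex_ratio, "F", "M"))

    age_missing = rng.random(n) < cfg.age_missing_rate
    age = np.clip(rng.normal(40.0, 15.0, size=n), 10, 90).round(0)
    wt_missing = rng.random(n) < cfg.weight_missing_rate
    wt = np.clip(rng.normal(75.0, 18.0, size=n), 35, 140).round(1)

    start_day = rng.integers(0, 3285, size=n)       # therapy start, 2015-2023
    alpha, beta = cfg.tto_weibull
    onset = np.rint(alpha * rng.weibull(beta, size=n)).astype(int)
    negative = rng.random(n) < cfg.negative_tto_rate
    neg_lag = rng.integers(1, 101, size=n)
    event_day = np.where(negative, start_day - neg_lag, start_day + onset)
    event_missing = rng.random(n) < cfg.event_date_missing_rate
    report_delay = rng.integers(1, 121, size=n)
    fda_day = np.maximum(start_day, event_day) + report_delay

    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    occp = rng.choice(_OCCP, size=n, p=_OCCP_P)
    outc_none = rng.random(n) >= 0.45
    outc = rng.choice(_OUTCOME_CODES, size=n, p=_OUTCOME_P)

    # concomitant drugs (never the suspect itself; may include the focal drug)
    has_con = rng.random(n) < cfg.concomitant_rate
    n_con = 1 + rng.poisson(0.7, size=n)
    con_draw = rng.integers(0, cfg.n_drugs - 1, size=(n, 4))
    con_role = rng.choice(np.array(["SS", "C", "I"]), size=(n, 4))

    dup = rng.random(n) < cfg.duplicate_rate
    dup_lag = rng.integers(1, 301, size=n)

    part_start = rng.random(n) < cfg.partial_date_rate
    part_event = rng.random(n) < cfg.partial_date_rate
    part_half_s = rng.random(n) < 0.5
    part_half_e = rng.random(n) < 0.5

    return dict(locals())


def _drug_rows_for_case(cfg, cv, i):
    """(drug id, role) pairs for case i: suspect is PS, then concomitants."""
    rows = [(int(cv["suspect"][i]), "PS")]
    if cv["has_con"][i]:
        k = min(int(cv["n_con"][i]), 4)
        seen = {rows[0][0]}
        for slot in range(k):
            d = int(cv["con_draw"][i, slot])
            if d >= rows[0][0]:
                d += 1  # skip the suspect -> uniform over the others
            if d in seen:
                continue
            seen.add(d)
            rows.append((d, str(cv["con_role"][i, slot])))
    return rows


def simulate_faers(config: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Build the six FAERS tables in memory plus the ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cv = _core_draw(config, rng)
    n = config.n_reports

    caseid = np.array([f"{90000000 + i}" for i in range(n)])
    pid1 = np.array([f"{90000000 + i}1" for i in range(n)])
    pid2 = np.array([f"{90000000 + i}2" for i in range(n)])

    focal_variant = rng.integers(0, len(FOCAL_SYNONYMS), size=n)

    start_str = _dates_to_str(cv["start_day"])
    event_str = _dates_to_str(cv["event_day"], missing=cv["event_missing"])
    start_str = _truncate_partial(start_str, cv["part_start"], cv["part_half_s"])
    event_str = _truncate_partial(event_str, cv["part_event"], cv["part_half_e"])
    fda1 = _dates_to_str(cv["fda_day"])
    fda2 = _dates_to_str(cv["fda_day"] + cv["dup_lag"])

    age_str = np.where(cv["age_missing"], "", cv["age"].astype(int).astype(str))
    age_cod = np.where(cv["age_missing"], "", "YR")
    wt_str = np.where(cv["wt_missing"], "", cv["wt"].astype(str))

    demo_rows: list[dict] = []
    drug_rows: list[dict] = []
    reac_rows: list[dict] = []
    ther_rows: list[dict] = []
    indi_rows: list[dict] = []
    outc_rows: list[dict] = []

    indi_pool = [_pt_name(j) for j in range(max(config.n_pts - 3, 0), config.n_pts)]
    indi_pick = rng.integers(0, max(len(indi_pool), 1), size=n)

    comention: dict[tuple[int, str], int] = {
        (d, _pt_name(j)): 0 for d, j, _ in config.planted_signals}
    n_target_ps = 0
    n_target_mono = 0
    canonical: dict[str, str] = {}

    for i in range(n):
        versions = [(pid1[i], fda1[i])]
        if cv["dup"][i]:
            versions.append((pid2[i], fda2[i]))
        canonical[caseid[i]] = versions[-1][0]

        drugs = _drug_rows_for_case(config, cv, i)
        if int(cv["suspect"][i]) == 0:
            n_target_ps += 1
            if len(drugs) == 1:
                n_target_mono += 1
        pts = [_pt_label(j, config.n_pts) for j in np.nonzero(cv["hits"][i])[0]]
        for p in pts:
            key = (int(cv["suspect"][i]), p)
            if key in comention:
                comention[key] += 1

        for pid, fda in versions:
            demo_rows.append({
                "PRIMARYID": pid, "CASEID": caseid[i], "FDA_DT": fda,
                "EVENT_DT": event_str[i], "SEX": cv["sex"][i],
                "AGE": age_str[i], "AGE_COD": age_cod[i], "WT": wt_str[i],
                "OCCR_COUNTRY": cv["country"][i], "OCCP_COD": cv["occp"][i],
            })
            for seq, (d, role) in enumerate(drugs, start=1):
                if d == 0:
                    name = FOCAL_SYNONYMS[focal_variant[i]]
                    ai = FOCAL_PROD_AI
                else:
                    name = f"DRUG {d:03d}"
                    ai = f"INGREDIENT {d:03d}"
                drug_rows.append({"PRIMARYID": pid, "DRUG_SEQ": seq,
                                  "ROLE_COD": role, "DRUGNAME": name, "PROD_AI": ai})
            ther_rows.append({"PRIMARYID": pid, "DSG_DRUG_SEQ": 1,
                              "START_DT": start_str[i]})
            for p in pts:
                reac_rows.append({"PRIMARYID": pid, "PT": p})
            if indi_pool:
                indi_rows.append({"PRIMARYID": pid,
                                  "INDI_PT": indi_pool[indi_pick[i]]})
            if not cv["outc_none"][i]:
                outc_rows.append({"PRIMARYID": pid, "OUTC_COD": cv["outc"][i]})

    frames = {
        "DEMO": pd.DataFrame(demo_rows),
        "DRUG": pd.DataFrame(drug_rows),
        "REAC": pd.DataFrame(reac_rows),
        "THER": pd.DataFrame(ther_rows),
        "INDI": pd.DataFrame(indi_rows, columns=["PRIMARYID", "INDI_PT"]),
        "OUTC": pd.DataFrame(outc_rows, columns=["PRIMARYID", "OUTC_COD"]),
    }
    gt = GroundTruth(
        planted=[(_pt_name(j), rr) for d, j, rr in config.planted_signals if d == 0],
        planted_pairs=[(d, _pt_name(j), rr) for d, j, rr in config.planted_signals],
        tto_alpha=config.tto_weibull[0], tto_beta=config.tto_weibull[1],
        canonical=canonical, n_cases=n,
        n_target_ps_cases=n_target_ps, n_target_monotherapy=n_target_mono,
        comention=comention, pt_names=[_pt_name(j) for j in range(config.n_pts)],
    )
    return frames, gt


def generate_faers(config: SyntheticConfig, outdir: str | Path) -> GroundTruth:
    """Write a synthetic FAERS quarter ("$"-delimited ASCII) to ``outdir``.

    Also writes ``pt_soc_map.tsv`` and ``synonyms.txt`` next to the tables so
    a whole downstream run can start from the directory alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, gt = simulate_faers(config)
    for name, df in frames.items():
        path = outdir / f"{name}.txt"
        df.to_csv(path, sep="$", index=False, lineterminator="\n")
        gt.files[name] = str(path)
    write_pt_soc_map(config.n_pts, config.pt_soc_map_size, outdir / "pt_soc_map.tsv")
    (outdir / "synonyms.txt").write_text(
        "\n".join(["INVEGA SUSTENNA", "PALIPERIDONE PALMITATE", "INVEGA TRINZA"]) + "\n",
        encoding="utf-8")
    gt.files["pt_soc_map"] = str(outdir / "pt_soc_map.tsv")
    gt.files["synonyms"] = str(outdir / "synonyms.txt")
    return gt


def simulate_universe(config: SyntheticConfig):
    """Vectorised shortcut: the post-deduplication case universe in memory.

    Returns ``(reports, reactions, gt_like)`` where ``reports`` has one row
    per case (primaryid, caseid, suspect drug id, is_target, sex, age_group
    columns) and ``reactions`` holds unique (primaryid, pt) pairs.  This is
    exactly what assembling the emitted files and deduplicating them yields,
    without the per-row file plumbing — used for simulation studies where
    many replicates are screened.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cv = _core_draw(config, rng)
    n = config.n_reports
    primaryid = np.array([f"{90000000 + i}1" for i in range(n)])

    reports = pd.DataFrame({
        "primaryid": primaryid,
        "caseid": [f"{90000000 + i}" for i in range(n)],
        "suspect_drug": cv["suspect"],
        "is_target": cv["suspect"] == 0,
        "sex": cv["sex"],
    })
    ii, jj = np.nonzero(cv["hits"])
    reactions = pd.DataFrame({
        "primaryid": primaryid[ii],
        "pt": [_pt_label(j, config.n_pts) for j in jj],
    })
    return reports, reactions


# ---------------------------------------------------------------------------
# JADER dialect


def simulate_jader(config: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Build the four JADER tables (DEMO/DRUG/REAC/HIST) in memory.

    The JADER dialect is comma-separated, keyed by a case identifier, with
    drug influence categories PS/C/I.  Duplicates are exact re-emitted rows
    within DRUG and REAC (the table-level duplication its dedup rule removes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 7_000_003)
    cv = _core_draw(config, rng)
    n = config.n_reports
    case_id = np.array([f"J{70000000 + i}" for i in range(n)])

    start_str = _dates_to_str(cv["start_day"])
    event_str = _dates_to_str(cv["event_day"], missing=cv["event_missing"])
    start_str = _truncate_partial(start_str, cv["part_start"], cv["part_half_s"])
    event_str = _truncate_partial(event_str, cv["part_event"], cv["part_half_e"])
    age_str = np.where(cv["age_missing"], "", cv["age"].astype(int).astype(str))
    wt_str = np.where(cv["wt_missing"], "", cv["wt"].astype(str))
    outcomes = np.array(["recovered", "not recovered", "unknown"])
    outc_pick = rng.integers(0, 3, size=n)
    hist_pool = np.array(["hypertension", "diabetes mellitus", "none reported"])
    hist_pick = rng.integers(0, 3, size=n)

    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    comention: dict[tuple[int, str], int] = {
        (d, _pt_name(j)): 0 for d, j, _ in config.planted_signals}
    n_target_ps = 0
    n_target_mono = 0

    for i in range(n):
        drugs = _drug_rows_for_case(config, cv, i)
        if int(cv["suspect"][i]) == 0:
            n_target_ps += 1
            if len(drugs) == 1:
                n_target_mono += 1
        pts = [_pt_label(j, config.n_pts) for j in np.nonzero(cv["hits"][i])[0]]
        for p in pts:
            key = (int(cv["suspect"][i]), p)
            if key in comention:
                comention[key] += 1

        demo_rows.append({"case_id": case_id[i], "sex": cv["sex"][i],
                          "age": age_str[i], "weight": wt_str[i]})
        for seq, (d, role) in enumerate(drugs, start=1):
            influence = "PS" if role == "PS" else ("I" if role == "I" else "C")
            name = JADER_FOCAL_NAME if d == 0 else f"医薬品{d:03d}"
            row = {"case_id": case_id[i], "drug_seq": seq, "influence": influence,
                   "generic_name": name, "start_date": start_str[i]}
            drug_rows.append(row)
            if cv["dup"][i] and seq == 1:
                drug_rows.append(dict(row))
        for p in pts:
            row = {"case_id": case_id[i], "reaction": p,
                   "outcome": outcomes[outc_pick[i]], "event_date": event_str[i]}
            reac_rows.append(row)
            if cv["dup"][i]:
                reac_rows.append(dict(row))
        hist_rows.append({"case_id": case_id[i], "condition": hist_pool[hist_pick[i]]})

    frames = {
        "DEMO": pd.DataFrame(demo_rows),
        "DRUG": pd.DataFrame(drug_rows),
        "REAC": pd.DataFrame(reac_rows),
        "HIST": pd.DataFrame(hist_rows),
    }
    gt = GroundTruth(
        planted=[(_pt_name(j), rr) for d, j, rr in config.planted_signals if d == 0],
        planted_pairs=[(d, _pt_name(j), rr) for d, j, rr in config.planted_signals],
        tto_alpha=config.tto_weibull[0], tto_beta=config.tto_weibull[1],
        canonical={c: c for c in case_id}, n_cases=n,
        n_target_ps_cases=n_target_ps, n_target_monotherapy=n_target_mono,
        comention=comention, pt_names=[_pt_name(j) for j in range(config.n_pts)],
    )
    return frames, gt


def generate_jader(config: SyntheticConfig, outdir: str | Path,
                   encoding: str = "utf-8") -> GroundTruth:
    """Write synthetic JADER CSV files to ``outdir`` (UTF-8 by default)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, gt = simulate_jader(config)
    for name, df in frames.items():
        path = outdir / f"{name.lower()}.csv"
        df.to_csv(path, index=False, lineterminator="\n", encoding=encoding)
        gt.files[name] = str(path)
    write_pt_soc_map(config.n_pts, config.pt_soc_map_size, outdir / "pt_soc_map.tsv")
    gt.files["pt_soc_map"] = str(outdir / "pt_soc_map.tsv")
    return gt
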