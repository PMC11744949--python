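"""End-to-end study pipeline: ingest, deduplicate, screen, stratify, time.

``run_all`` executes the whole replication on a pair of FAERS/JADER-style
inputs: ingestion and deduplication, cohort description, four-algorithm
screening with consensus calling, sex-stratified volcano analysis, the
monotherapy sensitivity screen, time-to-onset modelling, and cross-database
overlap of consensus-positive terms.  Every stage output is a TSV under the
run directory plus a JSON manifest (seed, config, input hashes, attrition
counts); re-running on identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cases import CaseReport, CaseUniverse
from .errors import ValidationError
from .faers import apply_dedup, assemble_cases, build_universe, read_faers_quarters
from .gender import GenderDisparity, GenderOptions, monotherapy_filter
from .jader import assemble_jader_cases, build_universe as jader_universe, read_jader
from .screen import DisproportionalityScreen, ScreenResults
from .stats import Thresholds
from .tto import WeibullTTO, km_compare, long_term_tabulation, tto_by_level, tto_records

__all__ = ["RunConfig", "describe_cohort", "cross_validate", "run_all"]


@dataclass
class RunConfig:
    faers_quarters: list[str]
    synonyms_file: str
    pt_soc_map_file: str
    outdir: str
    jader_dir: str | None = None
    jader_target_name: str = "パリペリドンパルミチン酸エステル"
    jader_encoding: str = "utf-8"
    indication_exclusions_file: str | None = None
    label_pts_file: str | None = None
    roles: tuple[str, ...] = ("PS",)
    alpha: float = 0.05
    gender_min_n: int = 3
    tto_pt_min_n: int = 40
    tto_cutoff_days: int = 360
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = Thresholds(**thr)
        return cfg

    def validate(self) -> None:
        missing = []
        for p in [*self.faers_quarters, self.synonyms_file, self.pt_soc_map_file,
                  self.indication_exclusions_file, self.label_pts_file,
                  self.jader_dir]:
            if p is not None and not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise ValidationError("missing input path(s): " + ", ".join(missing))


def _read_lines(path: str | None) -> list[str]:
    if path is None:
        return []
    return [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip()]


def describe_cohort(cases: Sequence[CaseReport]) -> pd.DataFrame:
    """Demographic table: counts and percent by sex, age group, weight band,
    top-5 countries, reporter type, outcome category, top-5 indications and
    report year.  Proportions are percentages of all cases."""
    n = len(cases)
    rows: list[dict] = []

    def add(characteristic: str, counts: dict[str, int]) -> None:
        for cat, cnt in counts.items():
            rows.append({"characteristic": characteristic, "category": cat,
                         "n": cnt, "proportion_pct": 100.0 * cnt / n if n else 0.0})

    def counted(values, order=None, top=None):
        s = pd.Series(list(values)).value_counts()
        if order is not None:
            s = s.reindex(order, fill_value=0)
        if top is not None:
            s = s.head(top)
        return s.to_dict()

    add("sex", counted((c.sex for c in cases), order=["F", "M", "UNK"]))
    add("age_group", counted((c.age_group for c in cases),
                             order=["<18", "18-65", ">65", "UNK"]))
    add("weight_band", counted((c.weight_band for c in cases),
                               order=["<50", "50-100", ">100", "UNK"]))
    add("country", counted((c.country for c in cases if c.country), top=5))
    add("reporter", counted((c.reporter for c in cases)))

    outcome_names = {"HO": "Hospitalization-initial or prolonged",
                     "LT": "Life-threatening", "DS": "Disability",
                     "CA": "Congenital anomaly", "DE": "Death",
                     "OT": "Other serious outcome", "RI": "Required intervention"}
    oc: dict[str, int] = {v: 0 for v in outcome_names.values()}
    oc["Unknown"] = 0
    for c in cases:
        cats = {outcome_names.get(o, o) for o in c.outcomes}
        if not cats:
            oc["Unknown"] += 1
        for cat in cats:
            oc[cat] = oc.get(cat, 0) + 1
    add("outcome", oc)

    add("indication", counted((i for c in cases for i in set(c.indications)), top=5))
    add("report_year", dict(sorted(counted(
        (c.fda_dt[:4] for c in cases if len(c.fda_dt) >= 4)).items())))
    return pd.DataFrame(rows)


def cross_validate(faers_pts: set[str], jader_pts: set[str]) -> dict:
    """Overlap of consensus-positive PT sets between the two databases."""
    inter = faers_pts & jader_pts
    return {
        "n_faers": len(faers_pts),
        "n_jader": len(jader_pts),
        "n_overlap": len(inter),
        "overlap": sorted(inter),
        "faers_only": sorted(faers_pts - jader_pts),
        "jader_only": sorted(jader_pts - faers_pts),
    }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _monotherapy_universe(universe: CaseUniverse, mono_ids: set[str]) -> CaseUniverse:
    """Universe whose target flag keeps only monotherapy target reports
    (other target reports leave the target margin but stay in the
    comparator background)."""
    reports = universe.reports.copy()
    reports["is_target"] = reports["is_target"] & reports["primaryid"].isin(mono_ids)
    return CaseUniverse(reports, universe.reactions)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``config.outdir``.

    Returns a dict with the in-memory results keyed by stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    synonyms = _read_lines(config.synonyms_file)
    pt_soc_map = pd.read_csv(config.pt_soc_map_file, sep="\t", dtype={"pt": str})
    indication_excl = _read_lines(config.indication_exclusions_file)
    label_pts = _read_lines(config.label_pts_file)

    attrition: dict[str, int] = {}

    # --- FAERS ingest / dedup / assembly
    raw = read_faers_quarters(config.faers_quarters)
    attrition["faers_rows_demo"] = len(raw.demo)
    deduped = apply_dedup(raw)
    attrition["faers_duplicates_removed"] = len(raw.demo) - len(deduped.demo)
    universe = build_universe(deduped, synonyms, role_filter=config.roles)
    cases = assemble_cases(deduped, synonyms, role_filter=config.roles)
    attrition["faers_cases"] = len(deduped.demo)
    attrition["faers_target_cases"] = len(cases)

    cohort = describe_cohort(cases)
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False,
                  float_format="%.6g", lineterminator="\n")

    # --- main screen
    screen = DisproportionalityScreen(
        universe, indication_exclusions=indication_excl, label_pts=label_pts,
        thresholds=config.thresholds, pt_soc_map=pt_soc_map).fit()
    screen.to_tsv(outdir / "signals_faers.tsv")

    # --- sex-stratified volcano
    gender = GenderDisparity(cases, GenderOptions(
        alpha=config.alpha, min_n=config.gender_min_n)).fit()
    gender.to_tsv(outdir / "gender_volcano.tsv")
    attrition["gender_known_sex"] = gender.n_female + gender.n_male

    # --- monotherapy sensitivity screen
    mono = monotherapy_filter(cases)
    attrition["monotherapy_cases"] = len(mono)
    sens = DisproportionalityScreen(
        _monotherapy_universe(universe, {c.primaryid for c in mono}),
        indication_exclusions=indication_excl, label_pts=label_pts,
        thresholds=config.thresholds, pt_soc_map=pt_soc_map).fit()
    sens.to_tsv(outdir / "sensitivity_signals.tsv")

    # --- time to onset
    records, excl = tto_records(cases, pt_soc_map)
    for k, v in excl.items():
        attrition[f"tto_excluded_{k}"] = v
    records.to_csv(outdir / "tto_records.tsv", sep="\t", index=False,
                   lineterminator="\n")
    fit_rows = []
    km_frames = []
    tto_res = {}
    if len(records) >= 10:
        overall = WeibullTTO(records["days"]).fit()
        fit_rows.append({"level": "overall", "group": "all", "n": overall.n,
                         "alpha": overall.alpha, "beta": overall.beta,
                         "beta_lo": overall.beta_lo, "beta_hi": overall.beta_hi,
                         "failure_type": overall.failure_type})
        tto_res["overall_fit"] = overall
        by_pt = tto_by_level(records, "pt", min_n=config.tto_pt_min_n)
        for pt in by_pt["pt"]:
            d = records.loc[records["pt"] == pt, "days"]
            try:
                f = WeibullTTO(d).fit()
            except Exception:
                continue
            fit_rows.append({"level": "pt", "group": pt, "n": f.n,
                             "alpha": f.alpha, "beta": f.beta,
                             "beta_lo": f.beta_lo, "beta_hi": f.beta_hi,
                             "failure_type": f.failure_type})
        tto_res["by_pt"] = by_pt
        tto_res["by_soc"] = tto_by_level(records, "soc", min_n=1)
        for grouping in ("sex", "age_group"):
            try:
                km = km_compare(records, grouping)
            except ValueError:
                continue
            tto_res[f"km_{grouping}"] = km
            for g, curve in km.curves.items():
                cf = curve.copy()
                cf.insert(0, "group", g)
                cf.insert(0, "group_by", grouping)
                cf["logrank_p"] = km.p_value
                km_frames.append(cf)
        soc_tab, pt_tab = long_term_tabulation(records, config.tto_cutoff_days)
        tto_res["long_term"] = (soc_tab, pt_tab)
    pd.DataFrame(fit_rows).to_csv(outdir / "tto_fits.tsv", sep="\t", index=False,
                                  float_format="%.6g", lineterminator="\n")
    (pd.concat(km_frames, ignore_index=True) if km_frames else pd.DataFrame(
        columns=["group_by", "group", "time", "survival", "logrank_p"])
     ).to_csv(outdir / "km.tsv", sep="\t", index=False, float_format="%.6g",
              lineterminator="\n")

    # --- JADER external validation
    jader_screen: ScreenResults | None = None
    overlap = None
    if config.jader_dir is not None:
        jraw = read_jader(config.jader_dir, encoding=config.jader_encoding)
        juni = jader_universe(jraw, config.jader_target_name,
                              role_filter=("PS",))
        jcases = assemble_jader_cases(jraw, config.jader_target_name)
        attrition["jader_target_cases"] = len(jcases)
        jader_screen = DisproportionalityScreen(
            juni, indication_exclusions=indication_excl, label_pts=label_pts,
            thresholds=config.thresholds, pt_soc_map=pt_soc_map).fit()
        jader_screen.to_tsv(outdir / "signals_jader.tsv")
        overlap = cross_validate(screen.consensus_pts, jader_screen.consensus_pts)
        pd.DataFrame({
            "pt": overlap["overlap"] + overlap["faers_only"] + overlap["jader_only"],
            "in_faers": [True] * (overlap["n_overlap"] + len(overlap["faers_only"]))
                        + [False] * len(overlap["jader_only"]),
            "in_jader": [True] * overlap["n_overlap"]
                        + [False] * len(overlap["faers_only"])
                        + [True] * len(overlap["jader_only"]),
        }).to_csv(outdir / "overlap.tsv", sep="\t", index=False,
                  lineterminator="\n")

    # --- manifest
    inputs = {}
    for p in [*config.faers_quarters]:
        for f in sorted(Path(p).iterdir()):
            if f.is_file():
                inputs[str(f)] = _sha256(f)
    for p in (config.synonyms_file, config.pt_soc_map_file,
              config.indication_exclusions_file, config.label_pts_file):
        if p:
            inputs[str(p)] = _sha256(p)
    if config.jader_dir:
        for f in sorted(Path(config.jader_dir).iterdir()):
            if f.is_file():
                inputs[str(f)] = _sha256(f)
    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "config": {**{k: v for k, v in dataclasses.asdict(config).items()
                      if k != "thresholds"},
                   "thresholds": dataclasses.asdict(config.thresholds)},
        "input_hashes": inputs,
        "attrition": attrition,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8")

    return {
        "cases": cases,
        "universe": universe,
        "cohort": cohort,
        "screen": screen,
        "gender": gender,
        "sensitivity": sens,
        "tto_records": records,
        "tto": tto_res,
        "jader_screen": jader_screen,
        "overlap": overlap,
        "attrition": attrition,
        "manifest": manifest,
    }
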