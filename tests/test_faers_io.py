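"""FAERS ingestion: parsing, deduplication rule, matching, assembly."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.errors import SchemaError, ValidationError
from pvsignal.faers import (age_to_years, apply_dedup, assemble_cases,
                            deduplicate, match_target_drug,
                            normalize_drug_name, read_faers_quarters)
from pvsignal.synthetic import SyntheticConfig, generate_faers
from tests.conftest import SYNONYMS


# --- reading --------------------------------------------------------------

def test_round_trip_row_counts(faers_study, faers_raw):
    outdir, _ = faers_study
    for name in ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC"):
        on_disk = sum(1 for _ in open(outdir / f"{name}.txt")) - 1
        assert len(faers_raw[name]) == on_disk


def test_empty_directory_is_schema_error(tmp_path):
    with pytest.raises(SchemaError):
        read_faers_quarters([tmp_path])
    with pytest.raises(SchemaError):
        read_faers_quarters([])


def test_missing_column_names_file_and_column(tmp_path):
    gen = tmp_path / "q"
    generate_faers(SyntheticConfig(n_reports=50, seed=1), gen)
    demo = pd.read_csv(gen / "DEMO.txt", sep="$", dtype=str)
    demo.drop(columns=["FDA_DT"]).to_csv(gen / "DEMO.txt", sep="$", index=False)
    with pytest.raises(SchemaError, match="FDA_DT"):
        read_faers_quarters([gen])


def test_two_quarters_concatenate(tmp_path):
    d1, d2 = tmp_path / "q1", tmp_path / "q2"
    generate_faers(SyntheticConfig(n_reports=100, seed=1), d1)
    generate_faers(SyntheticConfig(n_reports=150, seed=2), d2)
    one = read_faers_quarters([d1])
    two = read_faers_quarters([d1, d2])
    other = read_faers_quarters([d2])
    assert len(two.demo) == len(one.demo) + len(other.demo)
    assert len(two.reac) == len(one.reac) + len(other.reac)


# --- deduplication --------------------------------------------------------

def _demo(rows):
    return pd.DataFrame(rows, columns=["CASEID", "FDA_DT", "PRIMARYID"])


def test_dedup_keeps_most_recent_fda_dt():
    demo = _demo([("1", "20200101", "10"), ("1", "20200301", "9")])
    out = deduplicate(demo)
    assert list(out["PRIMARYID"]) == ["9"]


def test_dedup_ties_keep_higher_primaryid():
    demo = _demo([("1", "20200101", "10"), ("1", "20200101", "11")])
    out = deduplicate(demo)
    assert list(out["PRIMARYID"]) == ["11"]


def test_dedup_single_row_unchanged():
    demo = _demo([("7", "20200101", "42")])
    assert deduplicate(demo).equals(demo)


def test_dedup_idempotent_and_empty_ok():
    demo = _demo([("1", "20200101", "10"), ("1", "20200301", "9"),
                  ("2", "20190101", "5")])
    once = deduplicate(demo)
    twice = deduplicate(once)
    assert once.reset_index(drop=True).equals(twice.reset_index(drop=True))
    assert deduplicate(_demo([])).empty


@settings(max_examples=50, deadline=None)
@given(st.permutations(list(range(6))))
def test_dedup_order_independent(perm):
    rows = [("1", "20200101", "10"), ("1", "20200301", "9"),
            ("2", "20200101", "20"), ("2", "20200101", "21"),
            ("3", "20190101", "5"), ("1", "20200201", "30")]
    demo = _demo([rows[i] for i in perm])
    kept = set(deduplicate(demo)["PRIMARYID"])
    assert kept == {"9", "21", "5"}


def test_apply_dedup_removes_nonretained_everywhere(faers_raw, faers_study):
    _, gt = faers_study
    deduped = apply_dedup(faers_raw)
    retained = set(deduped.demo["PRIMARYID"])
    assert retained == set(gt.canonical.values())
    for t in ("drug", "reac", "ther", "indi", "outc"):
        assert set(getattr(deduped, t)["PRIMARYID"]) <= retained


# --- drug matching --------------------------------------------------------

@pytest.mark.parametrize("name,expected", [
    ("Invega Sustenna 156 mg", True),
    ("INVEGA SUSTENNA", True),
    ("invega  sustenna.", True),
    ("PALIPERIDONE PALMITATE ER", True),
    ("INVEGA-TRINZA", True),
    ("RISPERIDONE", False),
    ("PALIPERIDONE", False),   # plain metabolite name is not a synonym
    ("", False),
])
def test_name_matching_normalisation(name, expected):
    drug = pd.DataFrame({"PRIMARYID": ["1"], "DRUG_SEQ": ["1"],
                         "ROLE_COD": ["PS"], "DRUGNAME": [name],
                         "PROD_AI": [""]})
    got = match_target_drug(drug, SYNONYMS)
    assert (got == {"1"}) is expected


def test_prod_ai_matches_too():
    drug = pd.DataFrame({"PRIMARYID": ["1"], "DRUG_SEQ": ["1"],
                         "ROLE_COD": ["PS"], "DRUGNAME": ["UNKNOWN BRAND"],
                         "PROD_AI": ["PALIPERIDONE PALMITATE"]})
    assert match_target_drug(drug, SYNONYMS) == {"1"}


def test_empty_synonyms_rejected():
    drug = pd.DataFrame({"PRIMARYID": [], "DRUGNAME": [], "ROLE_COD": []})
    with pytest.raises(ValidationError):
        match_target_drug(drug, [])


def test_normalize_drug_name():
    assert normalize_drug_name(" Invega-Sustenna  156 MG.") == "INVEGA SUSTENNA 156 MG"


# --- assembly -------------------------------------------------------------

def test_assembled_count_matches_ground_truth(cases, faers_study):
    _, gt = faers_study
    assert len(cases) == gt.n_target_ps_cases


def test_monotherapy_bookkeeping(cases, faers_study):
    _, gt = faers_study
    assert sum(c.is_monotherapy for c in cases) == gt.n_target_monotherapy


def test_role_filter_excludes_concomitant_only():
    demo = pd.DataFrame({"PRIMARYID": ["1"], "CASEID": ["1"],
                         "FDA_DT": ["20200101"], "SEX": ["F"]})
    drug = pd.DataFrame({
        "PRIMARYID": ["1", "1"], "DRUG_SEQ": ["1", "2"],
        "ROLE_COD": ["PS", "C"],
        "DRUGNAME": ["SOMETHING ELSE", "INVEGA SUSTENNA"],
        "PROD_AI": ["", ""]})
    reac = pd.DataFrame({"PRIMARYID": ["1"], "PT": ["Headache"]})
    empty = pd.DataFrame(columns=["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"])
    from pvsignal.faers import RawTables
    raw = RawTables(demo, drug, reac, empty,
                    pd.DataFrame(columns=["PRIMARYID", "INDI_PT"]),
                    pd.DataFrame(columns=["PRIMARYID", "OUTC_COD"]))
    assert assemble_cases(raw, SYNONYMS, role_filter=("PS",)) == []
    got = assemble_cases(raw, SYNONYMS, role_filter=("PS", "C"))
    assert len(got) == 1 and got[0].reactions == ["Headache"]


def test_reactions_collapse_duplicate_pts_within_report(faers_deduped):
    cases = assemble_cases(faers_deduped, SYNONYMS)
    for c in cases[:50]:
        assert len(c.reactions) == len(set(c.reactions))


def test_assembled_ids_subset_of_dedup_demo(universe, faers_deduped, cases):
    demo_ids = set(faers_deduped.demo["PRIMARYID"])
    assert {c.primaryid for c in cases} <= demo_ids
    assert universe.n_target == len(cases)


def test_age_harmonisation():
    assert age_to_years("40", "YR") == 40
    assert age_to_years("4", "DEC") == 40
    assert age_to_years("24", "MON") == pytest.approx(2.0)
    assert age_to_years("", "YR") is None
    assert age_to_years("abc", "YR") is None


def test_case_cache_round_trips_all_fields(tmp_path, cases):
    from pvsignal.cases import read_cases, write_cases
    path = tmp_path / "cases.jsonl"
    write_cases(cases, path)
    back = read_cases(path)
    assert back == cases
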