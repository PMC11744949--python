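import pandas as pd
import pytest

from pvsignal.faers import apply_dedup, assemble_cases, build_universe, read_faers_quarters
from pvsignal.synthetic import SyntheticConfig, generate_faers

SYNONYMS = ["INVEGA SUSTENNA", "PALIPERIDONE PALMITATE", "INVEGA TRINZA"]

# shared mid-size synthetic study: two planted signals on the focal drug
STUDY_CONFIG = SyntheticConfig(
    n_reports=8000, seed=11,
    planted_signals=((0, 0, 10.0), (0, 1, 6.0)),
)


@pytest.fixture(scope="session")
def faers_study(tmp_path_factory):
    """(directory, ground truth) for the shared synthetic FAERS quarter."""
    outdir = tmp_path_factory.mktemp("faers_q")
    gt = generate_faers(STUDY_CONFIG, outdir)
    return outdir, gt


@pytest.fixture(scope="session")
def faers_raw(faers_study):
    outdir, _ = faers_study
    return read_faers_quarters([outdir])


@pytest.fixture(scope="session")
def faers_deduped(faers_raw):
    return apply_dedup(faers_raw)


@pytest.fixture(scope="session")
def universe(faers_deduped):
    return build_universe(faers_deduped, SYNONYMS)


@pytest.fixture(scope="session")
def cases(faers_deduped):
    return assemble_cases(faers_deduped, SYNONYMS)


@pytest.fixture(scope="session")
def pt_soc_map(faers_study):
    outdir, _ = faers_study
    return pd.read_csv(outdir / "pt_soc_map.tsv", sep="\t", dtype={"pt": str})
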