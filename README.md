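# pvsignal

Pharmacovigilance signal detection for spontaneous adverse-event report
databases (FAERS- and JADER-style extracts), built for drug-safety analysts
who want a tested, reproducible version of the standard disproportionality
workflow: report deduplication, four-algorithm screening with consensus
calling, sex-stratified risk signals, and time-to-onset modelling.

## The problem and the methods

Spontaneous reporting systems such as the FDA Adverse Event Reporting System
(FAERS) and the Japanese Adverse Drug Event Report database (JADER) collect
millions of unsolicited drug-event reports.  Because there is no denominator
of exposed patients, association between a drug and an adverse event
(a MedDRA preferred term, PT) is screened by *disproportionality*: for each
drug-event pair a 2×2 table is built over the whole report universe,

|                | target ADE | other ADEs |
|----------------|-----------|------------|
| target drug    | a         | b          |
| other drugs    | c         | d          |

with N = a+b+c+d, and four families of statistics are computed:

* **ROR** = ad/bc, with 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
  positive when the CI lower bound exceeds 1 and a ≥ 3.
* **PRR** = a(c+d)/(c(a+b)) with the uncorrected Pearson
  χ² = (ad−bc)²·N/((a+b)(c+d)(a+c)(b+d)); positive when PRR ≥ 2, χ² ≥ 4
  and a ≥ 3.
* **BCPNN information component** IC = log₂(a·N/((a+c)(a+b))), with the
  Bayesian posterior-variance credibility bound IC025 = IC − 2√V(IC);
  positive when IC025 > 0.
* **EBGM** = a·N/((a+c)(a+b)) (the relative reporting ratio, equal to 2^IC)
  with a lognormal interval; positive when EBGM05 > 2.  An optional
  empirical-Bayes gamma-Poisson shrinkage mode is provided.

A PT is a **consensus signal** only when all four criteria hold
simultaneously; consensus signals absent from the product label are flagged
**unexpected**.  Sex differences are screened with a within-drug
female-vs-male ROR per PT (Fisher exact p, Bonferroni-adjusted).  Onset
timing is modelled per (report, PT) as days from therapy start to event,
fitted with a Weibull(α, β) distribution whose shape β classifies the hazard
(early / random / wear-out failure), and compared across subgroups with
Kaplan-Meier curves and the log-rank test.

Because real FAERS/JADER extracts are multi-gigabyte downloads, the package
ships a synthetic report generator (`pvsignal.synthetic`) that emits
raw files in both dialects with planted drug-event association strengths,
duplicate submissions, partial dates and Weibull onset times — so the whole
pipeline is testable with known ground truth.

## Worked example

```python
import tempfile
from pathlib import Path
import pandas as pd
from pvsignal import SyntheticConfig, generate_faers, DisproportionalityScreen, WeibullTTO
from pvsignal.faers import read_faers_quarters, apply_dedup, build_universe, assemble_cases
from pvsignal.tto import tto_records

with tempfile.TemporaryDirectory() as d:
    # 20,000 reports; drug 0 and event PT_000 associated with relative risk 10
    cfg = SyntheticConfig(n_reports=20_000, seed=42, planted_signals=((0, 0, 10.0),))
    generate_faers(cfg, d)

    raw = read_faers_quarters([d])
    deduped = apply_dedup(raw)
    synonyms = ["INVEGA SUSTENNA", "PALIPERIDONE PALMITATE", "INVEGA TRINZA"]
    universe = build_universe(deduped, synonyms)
    print(DisproportionalityScreen(universe).fit().summary(k=3))

    cases = assemble_cases(deduped, synonyms)
    soc = pd.read_csv(Path(d) / "pt_soc_map.tsv", sep="\t")
    records, excluded = tto_records(cases, soc)
    print(WeibullTTO(records["days"]).fit().summary())
```

prints

```
Disproportionality screen
============================================================
universe reports:        20000
target-drug reports:     1040
PTs screened:            51
consensus signals:       1
unexpected signals:      1

top 3 by EBGM:
    pt   n   ror   prr   chi2   ic  ic025  ebgm  ebgm05  consensus
PT_000 119 13.33 11.92 730.82 2.93   2.60  7.60    5.98       True
PT_027  26  2.25  2.21  15.64 1.06   0.47  2.08    1.38      False
PT_035  20  1.95  1.93   8.18 0.88   0.21  1.84    1.16      False

Weibull time-to-onset fit
========================================
n records:       521
scale alpha:     74.34 d (95% CI 65.13-84.86)
shape beta:      0.68 (95% CI 0.64-0.73)
failure type:    early
```

The planted pair is the only consensus signal (ROR ≈ its planted strength;
background PTs stay below the thresholds), and the Weibull fit recovers the
generator's shape 0.67 — β < 1 with CI below 1, i.e. an early-failure
hazard whose risk declines over time.

The same analyses are available from the shell via the `pvsignal` command
(`simulate`, `ingest-faers`, `ingest-jader`, `screen`, `gender`, `tto`,
`run`); `pvsignal run --config run.yaml` executes the full pipeline and
writes every stage table plus a reproducibility manifest.

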