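#!/usr/bin/env python
"""Spontaneous-report analysis: dedup, ROR signal scan, onset times, models.

Reads results/data/icsr_cohort.csv (run 01_simulate_cohorts.py first),
deduplicates on the seven key fields, scans every study drug and both
classes for TMA-spectrum disproportionality, summarises time to onset by
class, and fits univariate + multivariate logistic models of TMA occurrence
on gender, age band, and drug class.

Writes signal_table.csv, signal_table_by_cancer.csv, tto_summaries.csv,
tto_curves.csv, odds_ratio_table.csv under results/signal_scan/.
"""

from pathlib import Path

import pandas as pd

from pharmvig_tma import covariates, onset
from pharmvig_tma.disproportionality import scan_signals
from pharmvig_tma.icsr import DrugDictionary, EventSet, deduplicate
from pharmvig_tma.pipeline import build_model_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "signal_scan"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dictionary = DrugDictionary.bundled()
    tma = EventSet.bundled_tma()

    reports = pd.read_csv(ROOT / "data" / "icsr_cohort.csv",
                          parse_dates=["event_date", "therapy_start",
                                       "event_onset"])
    n0 = len(reports)
    reports = deduplicate(reports)
    print(f"deduplication: {n0} -> {len(reports)} reports")

    exposures = ["All", "VEGFi", "VEGFRi"] + sorted(dictionary.generics)
    table = scan_signals(reports, exposures, tma, dictionary)
    table.to_csv(OUT / "signal_table.csv", index=False)
    flagged = table[table["is_signal"]]
    print(f"signals: {len(flagged)} of {len(table)} exposures flagged")
    print(flagged[["exposure", "a", "ror", "ci_low", "ci_high"]]
          .head(10).to_string(index=False))

    by_cancer = scan_signals(reports, ["All"], tma, dictionary,
                             strata="cancer_type")
    by_cancer.to_csv(OUT / "signal_table_by_cancer.csv", index=False)
    print(f"per-cancer strata: {len(by_cancer)}, "
          f"{int(by_cancer['excluded'].sum())} excluded (<3 cases)")

    tma_reports = reports[tma.match_mask(reports["events"])]
    samples = onset.extract_tto(tma_reports, "drug_class", dictionary)
    rows, curves = [], []
    for name, sample in samples.items():
        med, q1, q3, n = onset.summarize(sample)
        rows.append({"group": name, "median": med, "q1": q1, "q3": q3,
                     "n": n})
        curves.append(onset.cumulative_curve(sample))
        print(f"TTO {name}: median {med:.1f} d [IQR {q1:.1f}-{q3:.1f}], "
              f"n={n}")
    u, p = onset.mann_whitney(samples["VEGFi"].onset_days,
                              samples["VEGFRi"].onset_days)
    print(f"Mann-Whitney VEGFi vs VEGFRi onset: U={u:.0f}, p={p:.2e}")
    pd.DataFrame(rows).to_csv(OUT / "tto_summaries.csv", index=False)
    pd.concat(curves).to_csv(OUT / "tto_curves.csv", index=False)

    model_df = build_model_frame(reports, dictionary, tma)
    design = model_df[["gender", "age_band", "drug_class"]]
    ulr = covariates.fit_logistic(model_df["outcome"], design,
                                  mode="univariate")
    mlr = covariates.fit_logistic(model_df["outcome"], design,
                                  mode="multivariate")
    or_table = pd.concat([covariates.odds_ratio_table(f)
                          for f in [*ulr.values(), mlr] if f.converged],
                         ignore_index=True)
    or_table.to_csv(OUT / "odds_ratio_table.csv", index=False)
    cls = or_table[(or_table["factor"] == "drug_class")]
    print(cls.to_string(index=False))


if __name__ == "__main__":
    main()
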