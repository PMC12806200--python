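#!/usr/bin/env python
"""Generate the three synthetic study datasets used by the downstream steps.

Writes, under results/data/:
  icsr_cohort.csv + icsr_truth.json        spontaneous-report universe
  biochem_panels.csv + biochem_truth.json  1698-patient pre/post marker panels
  expression.csv / groups.csv / gene_sets.gmt + expression_truth.json
  pathway_scores.csv / cancer_ror.csv + pathway_truth.json

All generators are seeded; rerunning reproduces the files byte for byte.
"""

from pathlib import Path

import pandas as pd

from pharmvig_tma import enrichment, synthetic

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    icsr_cfg = synthetic.IcsrSimConfig(seed=SEED)
    reports, truth = synthetic.generate_icsr_cohort(icsr_cfg)
    reports.to_csv(OUT / "icsr_cohort.csv", index=False)
    synthetic.write_truth(truth, OUT / "icsr_truth.json")
    print(f"ICSR cohort: {len(reports)} reports, "
          f"{truth['n_tma_reports']} TMA-spectrum, "
          f"{len(truth['duplicate_report_ids'])} injected duplicates")

    bio_cfg = synthetic.BiochemSimConfig(seed=SEED + 1)
    panels, truth = synthetic.generate_biochem_cohort(bio_cfg)
    panels.to_csv(OUT / "biochem_panels.csv", index=False)
    synthetic.write_truth(truth, OUT / "biochem_truth.json")
    print(f"Biochemistry: {bio_cfg.n_patients} patients x 2 timepoints, "
          f"{len(truth['ttp_forced_pre'])} -> {len(truth['ttp_forced_post'])} "
          "planted TTP flags")

    expr_cfg = synthetic.ExpressionSimConfig(
        planted_sets={"vegf_signaling": -1.5}, seed=SEED + 2)
    expr, labels, sets, truth = synthetic.generate_expression_experiment(expr_cfg)
    expr.to_csv(OUT / "expression.csv")
    pd.Series(labels, index=expr.columns, name="group"
              ).to_csv(OUT / "groups.csv")
    enrichment.write_gmt(sets, OUT / "gene_sets.gmt")
    synthetic.write_truth(truth, OUT / "expression_truth.json")
    print(f"Expression: {expr.shape[0]} genes x {expr.shape[1]} samples, "
          f"planted sets {truth['planted_sets']}")

    scores, ror, truth = synthetic.generate_pathway_ror_dataset(
        n_cancers=13, planted_rho=0.8, seed=SEED + 3)
    scores.to_csv(OUT / "pathway_scores.csv")
    ror.to_frame().to_csv(OUT / "cancer_ror.csv")
    synthetic.write_truth(truth, OUT / "pathway_truth.json")
    print(f"Pathway-vs-ROR: {len(scores)} cancers, planted Spearman "
          f"{truth['planted_rho']} on {truth['target_pathway']}")


if __name__ == "__main__":
    main()
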