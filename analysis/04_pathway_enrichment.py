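#!/usr/bin/env python
"""Pathway enrichment: two-group GSEA on the animal-model-style expression
experiment and Spearman correlation of per-cancer pathway scores with RORs.

Reads the expression matrix, gene sets, and per-cancer score/ROR tables from
results/data/, runs permutation GSEA for the treated-vs-control contrast,
and correlates each pathway's per-cancer score with the per-cancer ROR
vector.

Writes gsea_results.csv and pathway_ror_correlation.csv under
results/pathway/.
"""

from pathlib import Path

import pandas as pd

from pharmvig_tma import enrichment as E

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "pathway"
SEED = 20240904


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data = ROOT / "data"

    expr = pd.read_csv(data / "expression.csv", index_col=0)
    labels = pd.read_csv(data / "groups.csv", index_col=0)["group"]
    sets = E.read_gmt(data / "gene_sets.gmt")
    res = E.results_frame(E.gsea_two_group(
        expr, labels.to_numpy(), sets, n_perm=1000, seed=SEED,
        positive_label="treated"))
    res = res.sort_values("p_adj").reset_index(drop=True)
    res.to_csv(OUT / "gsea_results.csv", index=False)
    print("GSEA treated vs control (top rows):")
    print(res.head(5).to_string(index=False))
    sig = res[res["p_adj"] < 0.05]
    for _, row in sig.iterrows():
        direction = "down" if row["es"] < 0 else "up"
        print(f"  {row['set']}: ES={row['es']:.3f} ({direction}-regulated), "
              f"adjusted p={row['p_adj']:.3g}")

    scores = pd.read_csv(data / "pathway_scores.csv", index_col=0)
    ror = pd.read_csv(data / "cancer_ror.csv", index_col=0)["ror"]
    rho = E.correlate_ror_pathways(scores, ror)
    rho.to_csv(OUT / "pathway_ror_correlation.csv", index=False)
    print("\nper-cancer pathway score vs ROR:")
    print(rho.sort_values("p").to_string(index=False))


if __name__ == "__main__":
    main()
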