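#!/usr/bin/env python
"""Biochemical risk assessment of the treated patient cohort.

Reads results/data/biochem_panels.csv, compares the five TMA markers before
and after treatment, builds the composite Z-score risk score with
baseline-quartile tiers, applies the TTP rule, and tests the tier and
TTP-flag shifts (G-test / Fisher).

Writes marker_tests.csv, risk_assessments.csv, tier_transitions.csv,
ttp_transitions.csv under results/biomarker/.
"""

from pathlib import Path

import pandas as pd

from pharmvig_tma import biomarker as B

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "biomarker"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panels = pd.read_csv(ROOT / "data" / "biochem_panels.csv")
    pre = panels[panels.timepoint == "pre"].reset_index(drop=True)
    post = panels[panels.timepoint == "post"].reset_index(drop=True)
    print(f"{pre.patient_id.nunique()} patients with paired panels")

    tests = B.paired_marker_tests(pre, post)
    tests.to_csv(OUT / "marker_tests.csv", index=False)
    for _, row in tests.iterrows():
        pre_m = pre[row["marker"]].mean()
        post_m = post[row["marker"]].mean()
        print(f"{row['marker']:>18}: {pre_m:8.2f} -> {post_m:8.2f}  "
              f"(Mann-Whitney p = {row['p']:.3g})")

    baseline = B.BaselineStats.from_panels(pre)
    score_pre = B.composite_score(B.zscore_panel(pre, baseline))
    score_post = B.composite_score(B.zscore_panel(post, baseline))
    cuts = B.tier_cutpoints(score_pre)
    tiers_pre = B.assign_tier(score_pre, cuts)
    tiers_post = B.assign_tier(score_post, cuts)
    tiers_pre.index = pre["patient_id"]
    tiers_post.index = post["patient_id"]

    trans, g = B.tier_shift_analysis(tiers_pre, tiers_post)
    trans.to_csv(OUT / "tier_transitions.csv")
    print("\ntier counts pre :", tiers_pre.value_counts().to_dict())
    print("tier counts post:", tiers_post.value_counts().to_dict())
    print(f"G-test on marginal tier distributions: G={g['marginal'][0]:.1f}, "
          f"df={g['marginal'][1]}, p={g['marginal'][2]:.3g}")

    ttp_pre = B.ttp_rule(pre)
    ttp_post = B.ttp_rule(post)
    ttp_pre.index = pre["patient_id"]
    ttp_post.index = post["patient_id"]
    ttp_trans, fisher_p = B.ttp_shift_analysis(ttp_pre, ttp_post)
    ttp_trans.to_csv(OUT / "ttp_transitions.csv")
    n = len(ttp_pre)
    print(f"\nTTP at risk: {int(ttp_pre.sum())} ({100*ttp_pre.mean():.2f}%) "
          f"-> {int(ttp_post.sum())} ({100*ttp_post.mean():.2f}%) of {n}; "
          f"Fisher p = {fisher_p:.3g}")

    assessment = pd.DataFrame({
        "patient_id": pre["patient_id"],
        "score_pre": score_pre.to_numpy(),
        "score_post": score_post.to_numpy(),
        "tier_pre": tiers_pre.to_numpy(),
        "tier_post": tiers_post.to_numpy(),
        "ttp_pre": ttp_pre.to_numpy(),
        "ttp_post": ttp_post.to_numpy(),
    })
    assessment.to_csv(OUT / "risk_assessments.csv", index=False)


if __name__ == "__main__":
    main()
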