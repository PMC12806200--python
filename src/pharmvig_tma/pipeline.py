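"""End-to-end analysis orchestration.

Three stages, each runnable from one YAML config with explicit seeds and a
JSON manifest recording the counts at every step so any artifact can be
reproduced:

* signal scan  — ingest -> dedup -> normalize -> cohort -> ROR scan -> TTO
  summaries -> univariate/multivariate logistic models -> cumulative curves
* biomarker assessment — Z-scores, composite risk, tiers, TTP rule,
  pre/post marker tests, tier and TTP transition analyses
* pathway correlation — ssGSEA-style per-cancer pathway summaries against
  per-cancer RORs
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import biomarker, covariates, disproportionality, onset, synthetic
from .icsr import (DrugDictionary, EventSet, deduplicate, normalize_drugs,
                   select_cohort)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _jsonable(obj):
    """Deep-convert to JSON-encodable form (tuple dict keys become strings)."""
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else "|".join(map(str, k))
                 if isinstance(k, tuple) else str(k)): _jsonable(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(config), sort_keys=True,
                   default=str).encode()).hexdigest()[:12]


def _write_manifest(outdir: Path, stage: str, config: dict, counts: dict,
                    artifacts: list[str]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(config),
        "seed": config.get("seed"),
        "counts": counts,
        "artifacts": artifacts,
        "config": _jsonable(config),
    }
    with open(outdir / f"{stage}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_signal_scan(config: dict, outdir) -> dict:
    """Figure-2-style chain: signal table, TTO summaries and curves,
    ULR/MLR odds-ratio table.  Returns the manifest counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    dictionary = DrugDictionary.bundled()
    tma = EventSet.bundled_tma()

    if "cohort_csv" in config:
        raw = pd.read_csv(config["cohort_csv"])
        from .icsr import ingest_reports
        reports, quarantine = ingest_reports(raw)
        quarantine.to_csv(outdir / "quarantine.csv", index=False)
    else:
        sim = synthetic.IcsrSimConfig(
            **{**config.get("icsr_sim", {}), "seed": seed})
        reports, truth = synthetic.generate_icsr_cohort(sim)
        synthetic.write_truth(truth, outdir / "icsr_truth.json")
    n_raw = len(reports)

    reports = deduplicate(reports)
    n_dedup = len(reports)
    reports = normalize_drugs(reports, dictionary)
    reports = select_cohort(reports, config.get("cohort_filters"), dictionary)
    n_cohort = len(reports)

    exposures = config.get(
        "exposures",
        ["All", "VEGFi", "VEGFRi"] + sorted(dictionary.generics))
    signals = disproportionality.scan_signals(
        reports, exposures, tma, dictionary,
        strata=config.get("strata"), alpha=config.get("alpha", 0.05))
    signals.to_csv(outdir / "signal_table.csv", index=False)

    tma_reports = reports[tma.match_mask(reports["events"])]
    samples = onset.extract_tto(tma_reports, "drug_class", dictionary)
    summaries, curves = [], []
    for name, sample in samples.items():
        if len(sample.onset_days) == 0:
            continue
        med, q1, q3, n = onset.summarize(sample)
        summaries.append({"group": name, "median": med, "q1": q1, "q3": q3,
                          "n": n, "n_excluded": sample.n_excluded})
        curves.append(onset.cumulative_curve(sample))
    tto_mw = None
    if {"VEGFi", "VEGFRi"} <= samples.keys() \
            and min(len(samples[c].onset_days) for c in ("VEGFi", "VEGFRi")):
        u, p = onset.mann_whitney(samples["VEGFi"].onset_days,
                                  samples["VEGFRi"].onset_days)
        tto_mw = {"U": u, "p": p}
    pd.DataFrame(summaries).to_csv(outdir / "tto_summaries.csv", index=False)
    if curves:
        pd.concat(curves).to_csv(outdir / "tto_curves.csv", index=False)

    or_table = pd.DataFrame()
    model_df = build_model_frame(reports, dictionary, tma)
    if model_df["outcome"].nunique() == 2 and len(model_df) > 50:
        design = model_df[["gender", "age_band", "drug_class"]]
        ulr = covariates.fit_logistic(model_df["outcome"], design,
                                      mode="univariate")
        mlr = covariates.fit_logistic(model_df["outcome"], design,
                                      mode="multivariate")
        tables = []
        for fit in list(ulr.values()) + [mlr]:
            if fit.converged:
                tables.append(covariates.odds_ratio_table(fit))
        if tables:
            or_table = pd.concat(tables, ignore_index=True)
    or_table.to_csv(outdir / "odds_ratio_table.csv", index=False)

    counts = {"raw_reports": n_raw, "after_dedup": n_dedup,
              "cohort": n_cohort, "tma_reports": int(len(tma_reports)),
              "signals": int(signals["is_signal"].sum()) if len(signals) else 0,
              "tto_mann_whitney": tto_mw}
    _write_manifest(outdir, "signal_scan", config, counts,
                    ["signal_table.csv", "tto_summaries.csv",
                     "tto_curves.csv", "odds_ratio_table.csv"])
    return counts


def build_model_frame(reports: pd.DataFrame, dictionary: DrugDictionary,
                      event_set: EventSet) -> pd.DataFrame:
    """Per-report modelling frame: TMA outcome vs gender/age band/drug class,
    restricted to reports suspect-exposed to exactly one study class."""
    from .icsr import drug_mask
    vegfi = drug_mask(reports, dictionary.class_members("VEGFi"))
    vegfri = drug_mask(reports, dictionary.class_members("VEGFRi"))
    keep = vegfi ^ vegfri
    df = pd.DataFrame({
        "outcome": event_set.match_mask(reports["events"]).astype(int),
        "gender": reports["gender"],
        "age_band": reports["age_band"],
        "drug_class": pd.Series("VEGFRi", index=reports.index).where(~vegfi,
                                                                     "VEGFi"),
    })[keep]
    df = df[df["gender"].isin(["female", "male"])
            & (df["age_band"] != "unknown")]
    return df.reset_index(drop=True)


def run_biomarker_assessment(config: dict, outdir) -> dict:
    """Figure-3-style chain: marker tests, per-patient assessments, tier and
    TTP transition analyses."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "panels_csv" in config:
        panels = pd.read_csv(config["panels_csv"])
    else:
        sim = synthetic.BiochemSimConfig(
            **{**config.get("biochem_sim", {}), "seed": seed})
        panels, truth = synthetic.generate_biochem_cohort(sim)
        synthetic.write_truth(truth, outdir / "biochem_truth.json")

    pre = panels[panels["timepoint"] == "pre"].reset_index(drop=True)
    post = panels[panels["timepoint"] == "post"].reset_index(drop=True)

    marker_tests = biomarker.paired_marker_tests(pre, post)
    marker_tests.to_csv(outdir / "marker_tests.csv", index=False)

    baseline = biomarker.BaselineStats.from_panels(pre)
    z_pre = biomarker.zscore_panel(pre, baseline)
    z_post = biomarker.zscore_panel(post, baseline)
    score_pre = biomarker.composite_score(z_pre)
    score_post = biomarker.composite_score(z_post)
    cuts = biomarker.tier_cutpoints(score_pre)
    tiers_pre = biomarker.assign_tier(score_pre, cuts)
    tiers_post = biomarker.assign_tier(score_post, cuts)
    tiers_pre.index = pre["patient_id"]
    tiers_post.index = post["patient_id"]

    ttp_pre = biomarker.ttp_rule(pre)
    ttp_post = biomarker.ttp_rule(post)
    ttp_pre.index = pre["patient_id"]
    ttp_post.index = post["patient_id"]

    assessment = pd.DataFrame({
        "patient_id": pre["patient_id"],
        "score_pre": score_pre.to_numpy(),
        "score_post": score_post.to_numpy(),
        "tier_pre": tiers_pre.to_numpy(),
        "tier_post": tiers_post.to_numpy(),
        "ttp_pre": ttp_pre.to_numpy(),
        "ttp_post": ttp_post.to_numpy(),
    })
    assessment.to_csv(outdir / "risk_assessments.csv", index=False)

    trans, g_results = biomarker.tier_shift_analysis(tiers_pre, tiers_post)
    trans.to_csv(outdir / "tier_transitions.csv")
    ttp_trans, fisher_p = biomarker.ttp_shift_analysis(ttp_pre, ttp_post)
    ttp_trans.to_csv(outdir / "ttp_transitions.csv")

    counts = {
        "patients": int(pre["patient_id"].nunique()),
        "tier_counts_pre": tiers_pre.value_counts().to_dict(),
        "tier_counts_post": tiers_post.value_counts().to_dict(),
        "ttp_pre": int(ttp_pre.fillna(False).sum()),
        "ttp_post": int(ttp_post.fillna(False).sum()),
        "tier_g_test_marginal_p": g_results["marginal"][2],
        "ttp_fisher_p": fisher_p,
    }
    _write_manifest(outdir, "biomarker", config, counts,
                    ["marker_tests.csv", "risk_assessments.csv",
                     "tier_transitions.csv", "ttp_transitions.csv"])
    return counts


def run_pathway_correlation(config: dict, outdir) -> dict:
    """Figure-4B-style chain: per-cancer pathway scores vs per-cancer ROR."""
    from . import enrichment
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "scores_csv" in config and "ror_csv" in config:
        scores = pd.read_csv(config["scores_csv"], index_col=0)
        ror = pd.read_csv(config["ror_csv"], index_col=0).iloc[:, 0]
    else:
        sim = {**config.get("pathway_sim", {})}
        scores, ror, truth = synthetic.generate_pathway_ror_dataset(
            n_cancers=sim.get("n_cancers", 13),
            n_pathways=sim.get("n_pathways", 5),
            planted_rho=sim.get("planted_rho", 0.8), seed=seed)
        synthetic.write_truth(truth, outdir / "pathway_truth.json")

    scores.to_csv(outdir / "pathway_scores.csv")
    ror.to_frame().to_csv(outdir / "cancer_ror.csv")
    rho_table = enrichment.correlate_ror_pathways(scores, ror)
    rho_table.to_csv(outdir / "rho_table.csv", index=False)

    counts = {"cancers": int(len(scores)), "pathways": int(scores.shape[1]),
              "significant": int((rho_table["p"] < config.get("alpha", 0.05)
                                  ).sum())}
    _write_manifest(outdir, "pathway", config, counts,
                    ["pathway_scores.csv", "cancer_ror.csv", "rho_table.csv"])
    return counts


def run_all(config: dict, outdir) -> dict:
    outdir = Path(outdir)
    return {
        "signal_scan": run_signal_scan(config.get("signal_scan", config),
                                       outdir / "signal_scan"),
        "biomarker": run_biomarker_assessment(config.get("biomarker", config),
                                              outdir / "biomarker"),
        "pathway": run_pathway_correlation(config.get("pathway", config),
                                           outdir / "pathway"),
    }
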