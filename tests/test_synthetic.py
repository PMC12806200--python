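"""Generator contracts: determinism, planted structure, validation."""

import numpy as np
import pandas as pd
import pytest

from pharmvig_tma import biomarker
from pharmvig_tma.icsr import deduplicate
from pharmvig_tma.synthetic import (BiochemSimConfig, ConfigError,
                                    ExpressionSimConfig, IcsrSimConfig,
                                    generate_biochem_cohort,
                                    generate_expression_experiment,
                                    generate_icsr_cohort,
                                    generate_pathway_ror_dataset)


class TestDeterminism:
    def test_icsr_identical_seed_identical_output(self):
        cfg = IcsrSimConfig(n_reports=2000, seed=31)
        df1, t1 = generate_icsr_cohort(cfg)
        df2, t2 = generate_icsr_cohort(IcsrSimConfig(n_reports=2000, seed=31))
        pd.testing.assert_frame_equal(df1, df2)
        assert t1 == t2

    def test_biochem_and_expression_and_pathway_deterministic(self):
        p1, _ = generate_biochem_cohort(BiochemSimConfig(n_patients=100,
                                                         seed=32))
        p2, _ = generate_biochem_cohort(BiochemSimConfig(n_patients=100,
                                                         seed=32))
        pd.testing.assert_frame_equal(p1, p2)
        e1, l1, s1, _ = generate_expression_experiment(
            ExpressionSimConfig(n_genes=50, seed=33))
        e2, l2, s2, _ = generate_expression_experiment(
            ExpressionSimConfig(n_genes=50, seed=33))
        pd.testing.assert_frame_equal(e1, e2)
        assert s1 == s2
        r1 = generate_pathway_ror_dataset(seed=34)
        r2 = generate_pathway_ror_dataset(seed=34)
        pd.testing.assert_frame_equal(r1[0], r2[0])
        pd.testing.assert_series_equal(r1[1], r2[1])


class TestIcsrGenerator:
    def test_excessive_planted_probability_rejected_before_sampling(self):
        with pytest.raises(ConfigError):
            IcsrSimConfig(background_event_rate=0.5,
                          planted_associations={("VEGFi", "tma_core"): 3.0})

    def test_duplicate_fraction_bounds(self):
        with pytest.raises(ConfigError):
            IcsrSimConfig(duplicate_fraction=1.0)

    def test_injected_duplicates_recovered_by_dedup(self):
        cfg = IcsrSimConfig(n_reports=1000, duplicate_fraction=0.1, seed=35)
        df, truth = generate_icsr_cohort(cfg)
        assert len(truth["duplicate_report_ids"]) == 100
        out = deduplicate(df)
        removed = len(df) - len(out)
        assert abs(removed - 100) <= 3  # rare natural key collisions

    def test_tto_medians_match_planted_class_medians(self, dictionary,
                                                     tma_events):
        from pharmvig_tma.onset import extract_tto, summarize
        cfg = IcsrSimConfig(n_reports=300_000, duplicate_fraction=0.0,
                            background_event_rate=0.004,
                            class_exposure_fractions={"VEGFi": 0.4,
                                                      "VEGFRi": 0.4,
                                                      "other": 0.2},
                            seed=36)
        df, _ = generate_icsr_cohort(cfg)
        tma = df[tma_events.match_mask(df["events"])]
        samples = extract_tto(tma, "drug_class", dictionary)
        med_i, *_ = summarize(samples["VEGFi"])
        med_ri, *_ = summarize(samples["VEGFRi"])
        assert med_i == pytest.approx(201.0, rel=0.15)
        assert med_ri == pytest.approx(35.0, rel=0.15)

    def test_null_association_means_unit_ror(self, dictionary, tma_events):
        from pharmvig_tma.disproportionality import build_contingency, compute_ror
        rors = []
        for seed in range(20):
            cfg = IcsrSimConfig(
                n_reports=60_000, duplicate_fraction=0.0,
                planted_associations={("VEGFi", "tma_core"): 1.0,
                                      ("VEGFRi", "tma_core"): 1.0},
                background_event_rate=0.02, seed=seed)
            df, _ = generate_icsr_cohort(cfg)
            tab = build_contingency(df, "bevacizumab", tma_events, dictionary)
            rors.append(compute_ror(tab).ror)
        assert np.mean(rors) == pytest.approx(1.0, abs=0.1)


class TestBiochemGenerator:
    def test_nonpositive_sd_rejected(self):
        bad = dict(BiochemSimConfig().pre_sds)
        bad["platelet"] = 0.0
        with pytest.raises(ConfigError):
            BiochemSimConfig(pre_sds=bad)

    def test_marker_names_fixed(self):
        with pytest.raises(ConfigError):
            BiochemSimConfig(pre_means={"platelet": 1.0})

    def test_means_within_three_se(self):
        """Per-marker sample means track the configured means.

        50 marker-timepoint z-scores across 5 seeds: under a correct
        generator ~99.7% lie within 3 SE, so at most a couple of exceedances
        are compatible with chance; a systematic shift is not.
        """
        zs = []
        for seed in range(5):
            cfg = BiochemSimConfig(n_patients=1698, ttp_fraction_pre=0.0,
                                   ttp_fraction_post=0.0, seed=100 + seed)
            panels, _ = generate_biochem_cohort(cfg)
            for tp, means, sds in (("pre", cfg.pre_means, cfg.pre_sds),
                                   ("post", cfg.post_means, cfg.post_sds)):
                sub = panels[panels.timepoint == tp]
                for m in biomarker.MARKERS:
                    se = sds[m] / np.sqrt(cfg.n_patients)
                    zs.append((sub[m].mean() - means[m]) / se)
        zs = np.asarray(zs)
        assert (np.abs(zs) < 3).mean() >= 0.95
        assert np.abs(zs).max() < 5
        assert abs(zs.mean()) < 1  # no systematic drift

    def test_mixture_platelet_mean_matches_target_with_ttp_fraction(self):
        cfg = BiochemSimConfig(n_patients=120_000, seed=38)
        panels, _ = generate_biochem_cohort(cfg)
        post = panels[panels.timepoint == "post"]
        se = cfg.post_sds["platelet"] / np.sqrt(cfg.n_patients)
        assert abs(post["platelet"].mean() - cfg.post_means["platelet"]) < 4 * se

    def test_pre_post_correlation_recovered(self):
        cfg = BiochemSimConfig(n_patients=5000, pre_post_correlation=0.9,
                               ttp_fraction_pre=0.0, ttp_fraction_post=0.0,
                               seed=39)
        panels, _ = generate_biochem_cohort(cfg)
        pre = panels[panels.timepoint == "pre"].set_index("patient_id")
        post = panels[panels.timepoint == "post"].set_index("patient_id")
        r = np.corrcoef(pre["mcv"], post.loc[pre.index, "mcv"])[0, 1]
        assert r == pytest.approx(0.9, abs=0.03)

    def test_no_effect_config_keeps_marker_tests_null(self):
        rejections = 0
        for seed in range(10):
            cfg = BiochemSimConfig(
                n_patients=400, post_means=dict(BiochemSimConfig().pre_means),
                post_sds=dict(BiochemSimConfig().pre_sds),
                pre_post_correlation=0.9, ttp_fraction_pre=0.0,
                ttp_fraction_post=0.0, seed=seed)
            panels, _ = generate_biochem_cohort(cfg)
            pre = panels[panels.timepoint == "pre"]
            post = panels[panels.timepoint == "post"]
            tests = biomarker.paired_marker_tests(pre, post)
            rejections += int((tests["p"] < 0.05).any())
        assert rejections <= 3  # five markers at alpha=0.05 per seed

    def test_zero_ttp_fraction_yields_zero_flags(self):
        cfg = BiochemSimConfig(n_patients=3000, ttp_fraction_pre=0.0,
                               ttp_fraction_post=0.0, seed=40)
        panels, _ = generate_biochem_cohort(cfg)
        post = panels[panels.timepoint == "post"]
        assert biomarker.ttp_rule(post).fillna(False).sum() == 0

    def test_forced_ids_match_rule_flags(self):
        cfg = BiochemSimConfig(n_patients=2000, seed=41)
        panels, truth = generate_biochem_cohort(cfg)
        post = panels[panels.timepoint == "post"].set_index("patient_id")
        flagged = set(post.index[biomarker.ttp_rule(post).fillna(False)])
        assert flagged == set(truth["ttp_forced_post"])


class TestExpressionGenerator:
    def test_empty_gene_set_rejected(self):
        with pytest.raises(ConfigError):
            ExpressionSimConfig(gene_sets={"s": []})

    def test_matrix_nonnegative_and_shift_applied(self):
        cfg = ExpressionSimConfig(n_genes=200, planted_sets={"planted": 1.5},
                                  seed=42)
        expr, labels, sets, truth = generate_expression_experiment(cfg)
        assert (expr.to_numpy() > 0).all()
        members = sets["planted"]
        log2 = np.log2(expr)
        shift = (log2.loc[list(members), labels == "treated"].mean().mean()
                 - log2.loc[list(members), labels == "control"].mean().mean())
        assert shift == pytest.approx(1.5, abs=0.4)


class TestPathwayGenerator:
    def test_invalid_rho_and_size_rejected(self):
        with pytest.raises(ConfigError):
            generate_pathway_ror_dataset(planted_rho=1.5)
        with pytest.raises(ConfigError):
            generate_pathway_ror_dataset(n_cancers=3)

    def test_monotone_copula_gives_exact_unit_rho(self):
        from scipy.stats import spearmanr
        scores, ror, truth = generate_pathway_ror_dataset(planted_rho=1.0,
                                                          seed=43)
        rho = spearmanr(scores[truth["target_pathway"]], ror).statistic
        assert rho == 1.0

    def test_null_rho_centred_at_zero(self):
        from scipy.stats import spearmanr
        rhos = []
        for seed in range(500):
            scores, ror, truth = generate_pathway_ror_dataset(
                planted_rho=0.0, seed=seed)
            rhos.append(spearmanr(scores[truth["target_pathway"]],
                                  ror).statistic)
        assert abs(np.mean(rhos)) < 0.05
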