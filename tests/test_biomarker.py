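"""Composite biochemical risk scoring, tiers, TTP rule, G/Fisher tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pharmvig_tma.biomarker import (MARKERS, BaselineStats, assign_tier,
                                    composite_score, fisher_exact, g_test,
                                    tier_cutpoints, tier_shift_analysis,
                                    transition_matrix, ttp_rule,
                                    ttp_shift_analysis, zscore_panel)


def panel_frame(**overrides):
    base = {"platelet": 200.0, "creatinine": 70.0, "indirect_bilirubin": 5.0,
            "rbc": 4.0, "mcv": 90.0}
    base.update(overrides)
    return pd.DataFrame([base])


@pytest.fixture()
def baseline():
    return BaselineStats(
        means=pd.Series({"platelet": 200.0, "creatinine": 70.0,
                         "indirect_bilirubin": 5.0, "rbc": 4.0, "mcv": 90.0}),
        sds=pd.Series({"platelet": 50.0, "creatinine": 20.0,
                       "indirect_bilirubin": 2.0, "rbc": 0.5, "mcv": 5.0}))


class TestZscore:
    def test_value_at_baseline_mean_is_zero(self, baseline):
        z = zscore_panel(panel_frame(), baseline)
        assert (z.iloc[0].abs() < 1e-12).all()

    def test_platelet_drop_is_positive_risk(self, baseline):
        z = zscore_panel(panel_frame(platelet=150.0), baseline)  # 1 SD below
        assert z.iloc[0]["platelet"] == pytest.approx(1.0)

    def test_creatinine_rise_is_positive_risk(self, baseline):
        z = zscore_panel(panel_frame(creatinine=90.0), baseline)
        assert z.iloc[0]["creatinine"] == pytest.approx(1.0)

    def test_standardization_property_on_cohort(self):
        from pharmvig_tma.synthetic import (BiochemSimConfig,
                                            generate_biochem_cohort)
        panels, _ = generate_biochem_cohort(BiochemSimConfig(
            n_patients=2000, ttp_fraction_pre=0.0, ttp_fraction_post=0.0,
            seed=8))
        pre = panels[panels.timepoint == "pre"]
        stats_ = BaselineStats.from_panels(pre)
        z = zscore_panel(pre, stats_)
        assert np.allclose(z.mean(), 0.0, atol=1e-10)
        assert np.allclose(z.std(ddof=1).abs(), 1.0, atol=1e-10)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            BaselineStats(means=pd.Series({m: 1.0 for m in MARKERS}),
                          sds=pd.Series({m: 0.0 for m in MARKERS}))


class TestCompositeScore:
    def test_all_zero_scores_zero(self):
        z = pd.DataFrame([{m: 0.0 for m in MARKERS}])
        assert composite_score(z).iloc[0] == 0.0

    def test_single_unit_z_gives_one(self):
        z = pd.DataFrame([{m: 0.0 for m in MARKERS}])
        z.loc[0, "platelet"] = 1.0
        assert composite_score(z).iloc[0] == pytest.approx(1.0)  # log2(2)

    def test_missing_marker_rejected_by_default(self):
        z = pd.DataFrame([{m: 0.0 for m in MARKERS}])
        z.loc[0, "mcv"] = np.nan
        with pytest.raises(ValueError):
            composite_score(z)

    @given(st.lists(st.floats(-5, 5), min_size=5, max_size=5),
           st.integers(0, 4), st.floats(0.01, 2.0))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_strictly_increasing_in_each_oriented_z(self, zs, idx, bump):
        z = pd.DataFrame([dict(zip(MARKERS, zs))])
        z2 = z.copy()
        z2.iloc[0, idx] += bump
        assert composite_score(z2).iloc[0] > composite_score(z).iloc[0]

    def test_unit_invariance_through_zscores(self, baseline):
        """The composite depends only on Z-scores, hence is invariant to
        affine rescaling of marker units applied to data and baseline."""
        panels = panel_frame(platelet=150.0, mcv=96.0)
        score1 = composite_score(zscore_panel(panels, baseline))
        scaled = panels * 10.0
        baseline2 = BaselineStats(means=baseline.means * 10.0,
                                  sds=baseline.sds * 10.0)
        score2 = composite_score(zscore_panel(scaled, baseline2))
        assert score1.iloc[0] == pytest.approx(score2.iloc[0], rel=1e-12)


class TestTiers:
    def test_below_first_cutpoint_is_low(self):
        tiers = assign_tier([-5.0], [0.0, 1.0, 2.0])
        assert tiers.iloc[0] == "low"

    def test_boundary_goes_to_upper_tier(self):
        tiers = assign_tier([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert tiers.tolist() == ["medium-low", "medium-high", "high"]

    def test_non_monotone_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            assign_tier([0.0], [1.0, 0.5, 2.0])

    def test_quartile_cutpoints_split_evenly(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.uniform(-3, 3, size=4000))
        tiers = assign_tier(scores, tier_cutpoints(scores))
        frac = tiers.value_counts(normalize=True)
        assert np.allclose(frac.reindex(
            ["low", "medium-low", "medium-high", "high"]), 0.25, atol=0.02)


class TestTtpRule:
    @pytest.mark.parametrize("plt,cre,expected", [
        (25.0, 150.0, True),
        (25.0, 250.0, False),   # conjunction
        (30.0, 150.0, False),   # strict threshold
        (29.999, 198.999, True),
    ])
    def test_conjunction_and_strictness(self, plt, cre, expected):
        out = ttp_rule(panel_frame(platelet=plt, creatinine=cre))
        assert bool(out.iloc[0]) is expected

    def test_missing_marker_is_undetermined(self):
        out = ttp_rule(panel_frame(platelet=np.nan))
        assert out.isna().iloc[0]

    def test_risk_region_is_lower_left_orthant(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            plt, cre = rng.uniform(1, 60), rng.uniform(30, 400)
            flagged = bool(ttp_rule(panel_frame(platelet=plt,
                                                creatinine=cre)).iloc[0])
            if flagged:
                lower = ttp_rule(panel_frame(platelet=plt * 0.5,
                                             creatinine=cre * 0.5))
                assert bool(lower.iloc[0])


class TestGTest:
    def test_observed_equals_expected_gives_zero(self):
        g, dof, p = g_test([[20, 20], [20, 20]])
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_direct_formula_hand_evaluation(self):
        obs = np.array([[20.0, 10.0], [10.0, 20.0]])
        g, dof, p = g_test(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        g_hand = 2 * np.sum(obs * np.log(obs / expected))
        assert g == pytest.approx(g_hand, rel=1e-12)
        assert dof == 1
        assert p == pytest.approx(stats.chi2.sf(g_hand, 1), rel=1e-12)

    def test_approaches_pearson_on_large_balanced_tables(self):
        obs = np.array([[500, 460], [470, 520]])
        g, _, _ = g_test(obs)
        chi2 = stats.chi2_contingency(obs, correction=False)[0]
        assert abs(g - chi2) / chi2 < 0.01

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            g, dof, p = g_test([[10, 5, 0], [20, 10, 0]])
        assert dof == 1


class TestFisher:
    def test_hand_enumerated_example(self):
        # all same-margin tables: p = sum of hypergeom pmfs <= observed's
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(0.485714285714,
                                                               rel=1e-9)

    def test_zero_margin_gives_unity(self):
        assert fisher_exact([[0, 0], [5, 10]]) == pytest.approx(1.0)

    def test_agrees_with_g_test_on_well_filled_tables(self):
        rng = np.random.default_rng(12)
        agree = 0
        trials = 200
        for _ in range(trials):
            tab = rng.integers(20, 200, size=(2, 2))
            p_f = fisher_exact(tab)
            _, _, p_g = g_test(tab)
            agree += (p_f < 0.05) == (p_g < 0.05)
        assert agree / trials >= 0.95


class TestShiftAnalyses:
    def test_no_change_gives_diagonal_and_p_one(self):
        tiers = pd.Series(["low", "high", "medium-low", "medium-high"] * 5,
                          index=[f"P{i}" for i in range(20)])
        trans, g_results = tier_shift_analysis(tiers, tiers.copy())
        off_diag = trans.to_numpy() - np.diag(np.diag(trans.to_numpy()))
        assert (off_diag == 0).all()
        assert g_results["marginal"][2] == pytest.approx(1.0)

    def test_transition_bookkeeping(self):
        rng = np.random.default_rng(13)
        idx = [f"P{i}" for i in range(300)]
        cats = ["low", "medium-low", "medium-high", "high"]
        pre = pd.Series(rng.choice(cats, 300), index=idx)
        post = pd.Series(rng.choice(cats, 300), index=idx)
        trans, _ = tier_shift_analysis(pre, post)
        assert trans.sum(axis=1).tolist() == \
            pre.value_counts().reindex(cats, fill_value=0).tolist()
        assert trans.sum(axis=0).tolist() == \
            post.value_counts().reindex(cats, fill_value=0).tolist()

    def test_unmatched_ids_rejected(self):
        pre = pd.Series(["low"], index=["P1"])
        post = pd.Series(["low"], index=["P2"])
        with pytest.raises(ValueError):
            tier_shift_analysis(pre, post)

    def test_ttp_shift_detects_planted_increase(self):
        rng = np.random.default_rng(14)
        idx = [f"P{i}" for i in range(1698)]
        pre = pd.Series(rng.random(1698) < 0.0118, index=idx)
        post = pd.Series(rng.random(1698) < 0.0377, index=idx)
        trans, p = ttp_shift_analysis(pre, post)
        assert trans.to_numpy().sum() == 1698
        assert p < 0.05
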