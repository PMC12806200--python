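"""Biochemical TMA/TTP risk assessment for a treated patient cohort.

Five markers per patient and timepoint: platelet count (x10^9/L), creatinine
(umol/L), indirect bilirubin (umol/L), red-cell count (x10^12/L), and mean
corpuscular volume (fL).  Each marker is standardised against pre-treatment
baseline statistics, oriented so that larger values mean higher TMA risk
(platelet and RBC decreases are risk-increasing), combined into a composite
score via a signed log2 transform, and binned into four risk tiers by
baseline quartiles.  A TTP ("French criteria") rule flags patients with
platelet < 30 x10^9/L and creatinine < 199 umol/L.

The composite uses the signed transform sign(z) * log2(1 + |z|): a plain
log2 of a Z-score is undefined for z <= 0, while this variant is defined
everywhere, odd, strictly monotone, and approaches log2|z| for large |z|.
A raw Z-score sum is available via ``method="raw"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .onset import mann_whitney

MARKERS = ["platelet", "creatinine", "indirect_bilirubin", "rbc", "mcv"]

#: risk orientation: -1 where a *decrease* signals risk
ORIENTATION = {"platelet": -1.0, "creatinine": 1.0, "indirect_bilirubin": 1.0,
               "rbc": -1.0, "mcv": 1.0}

TIERS = ["low", "medium-low", "medium-high", "high"]

TTP_PLATELET_MAX = 30.0     # x10^9/L, strict
TTP_CREATININE_MAX = 199.0  # umol/L, strict


@dataclass(frozen=True)
class BaselineStats:
    means: pd.Series
    sds: pd.Series

    def __post_init__(self):
        if (self.sds <= 0).any():
            raise ValueError("baseline SDs must be positive")

    @classmethod
    def from_panels(cls, pre_panels: pd.DataFrame) -> "BaselineStats":
        vals = pre_panels[MARKERS]
        return cls(means=vals.mean(), sds=vals.std(ddof=1))


def zscore_panel(panels: pd.DataFrame, baseline: BaselineStats
                 ) -> pd.DataFrame:
    """Oriented Z-scores: (value - baseline mean)/SD times the per-marker risk
    orientation, so that larger always means worse."""
    z = (panels[MARKERS] - baseline.means) / baseline.sds
    for m in MARKERS:
        z[m] = z[m] * ORIENTATION[m]
    return z


def composite_score(oriented_z: pd.DataFrame, method: str = "signed_log2",
                    allow_missing: bool = False) -> pd.Series:
    """Sum of transformed oriented Z-scores; one score per patient row."""
    z = oriented_z[MARKERS] if set(MARKERS) <= set(oriented_z.columns) else oriented_z
    if not allow_missing and z.isna().any().any():
        raise ValueError("missing marker value(s); enable allow_missing to skip")
    if method == "signed_log2":
        t = np.sign(z) * np.log2(1.0 + np.abs(z))
    elif method == "raw":
        t = z
    else:
        raise ValueError(f"unknown method {method!r}")
    return t.sum(axis=1, skipna=allow_missing)


def tier_cutpoints(baseline_scores: pd.Series) -> np.ndarray:
    """Quartile cutpoints (q25, q50, q75) of the pre-treatment scores."""
    return np.percentile(np.asarray(baseline_scores, dtype=float), [25, 50, 75])


def assign_tier(scores, cutpoints) -> pd.Series:
    """Four tiers by half-open intervals: score in [q_k, q_{k+1}) -> tier k;
    a score exactly at a cutpoint falls in the upper tier."""
    cut = np.asarray(cutpoints, dtype=float)
    if len(cut) != 3 or not (cut[0] <= cut[1] <= cut[2]):
        raise ValueError("cutpoints must be three non-decreasing values")
    index = scores.index if isinstance(scores, pd.Series) else None
    s = pd.Series(np.asarray(scores, dtype=float), index=index)
    idx = np.searchsorted(cut, s.to_numpy(), side="right")
    return pd.Series(pd.Categorical.from_codes(idx, categories=TIERS,
                                               ordered=True), index=s.index)


def ttp_rule(panels: pd.DataFrame) -> pd.Series:
    """French-criteria TTP flag: platelet < 30 AND creatinine < 199 (strict).

    Rows missing either marker get pd.NA (undetermined), not False.
    """
    plt, cre = panels["platelet"], panels["creatinine"]
    flag = (plt < TTP_PLATELET_MAX) & (cre < TTP_CREATININE_MAX)
    out = flag.astype("boolean")
    out[plt.isna() | cre.isna()] = pd.NA
    return out


def paired_marker_tests(pre: pd.DataFrame, post: pd.DataFrame
                        ) -> pd.DataFrame:
    """Per-marker two-sided Mann-Whitney U of pre vs post values.

    The study design is paired, but the comparison follows the named unpaired
    test; align on patient_id first.
    """
    merged = pre.set_index("patient_id")[MARKERS].join(
        post.set_index("patient_id")[MARKERS], how="inner",
        lsuffix="_pre", rsuffix="_post")
    if len(merged) < 2:
        raise ValueError("need at least 2 matched patients")
    rows = []
    for m in MARKERS:
        u, p = mann_whitney(merged[f"{m}_pre"].dropna(),
                            merged[f"{m}_post"].dropna())
        rows.append({"marker": m, "U": u, "p": p})
    return pd.DataFrame(rows)


def g_test(table) -> tuple[float, int, float]:
    """Log-likelihood-ratio (G) test of independence on an r x c table.

    G = 2 * sum O * ln(O/E), df = (r-1)(c-1), p from the chi-square upper
    tail.  No Williams correction.  Zero-margin rows/columns are dropped with
    a warning.
    """
    obs = np.asarray(table, dtype=float)
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns from G-test table")
        obs = obs[row_ok][:, col_ok]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("G-test needs at least a 2x2 table after dropping "
                         "zero margins")
    g, p, dof, _ = stats.chi2_contingency(obs, correction=False,
                                          lambda_="log-likelihood")
    return float(g), int(dof), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    same-margin tables no more probable than the observed one."""
    obs = np.asarray(table, dtype=float)
    _, p = stats.fisher_exact(obs, alternative="two-sided")
    return float(p)


def transition_matrix(pre_labels: pd.Series, post_labels: pd.Series,
                      categories) -> pd.DataFrame:
    """Pre (rows) -> post (columns) transition counts over matched patients."""
    if not pre_labels.index.equals(post_labels.index):
        raise ValueError("pre and post labels must share matched patient ids")
    tab = pd.crosstab(pre_labels, post_labels, dropna=False)
    return tab.reindex(index=categories, columns=categories, fill_value=0)


def tier_shift_analysis(pre_tiers: pd.Series, post_tiers: pd.Series):
    """4x4 tier transition matrix plus G-tests.

    The primary test compares the *marginal* pre vs post tier distributions
    (2 x 4 table); the G-test on the full transition matrix is also returned
    since the choice is ambiguous for this design.
    """
    trans = transition_matrix(pre_tiers, post_tiers, TIERS)
    marginal = np.vstack([trans.sum(axis=1).to_numpy(),
                          trans.sum(axis=0).to_numpy()])
    g_marg = g_test(marginal)
    try:
        g_full = g_test(trans.to_numpy())
    except ValueError:
        g_full = (np.nan, 0, np.nan)
    return trans, {"marginal": g_marg, "transition": g_full}


def ttp_shift_analysis(pre_flags: pd.Series, post_flags: pd.Series):
    """2x2 TTP-flag transition matrix plus Fisher p on the marginal
    at-risk/not-at-risk counts pre vs post."""
    pre = pre_flags.astype("boolean")
    post = post_flags.astype("boolean")
    if not pre.index.equals(post.index):
        raise ValueError("pre and post flags must share matched patient ids")
    keep = pre.notna() & post.notna()
    pre, post = pre[keep].astype(bool), post[keep].astype(bool)
    trans = transition_matrix(pre.map({True: "at-risk", False: "not-at-risk"}),
                              post.map({True: "at-risk", False: "not-at-risk"}),
                              ["at-risk", "not-at-risk"])
    marginal = [[int(pre.sum()), int((~pre).sum())],
                [int(post.sum()), int((~post).sum())]]
    return trans, fisher_exact(marginal)
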