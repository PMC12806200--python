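"""Reporting odds ratio (ROR) disproportionality analysis.

The ROR compares the odds of a given adverse event among reports exposed to a
drug (or drug class) against the odds among all other reports in the cohort:

    ROR = (a/b) / (c/d) = ad / (bc)

with the Woolf (log-normal) confidence interval

    exp( ln ROR  +/-  z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) ).

A drug-event pair is a signal when it has at least ``min_reports`` exposed
event reports and the lower CI bound exceeds 1.  When any cell is zero the
Haldane-Anscombe 0.5 continuity correction is applied to all four cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .icsr import DrugDictionary, EventSet, drug_mask


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-event counts over a report cohort."""

    a: int  # exposed, event
    b: int  # exposed, no event
    c: int  # unexposed, event
    d: int  # unexposed, no event
    exposure_label: str = ""
    event_label: str = ""
    stratum: str = ""

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    ror: float
    ci_low: float
    ci_high: float
    n_reports: int
    alpha: float
    is_signal: bool
    correction_applied: bool
    exposure_label: str = ""
    event_label: str = ""
    stratum: str = ""


def build_contingency(reports: pd.DataFrame, exposure, event_set: EventSet,
                      dictionary: DrugDictionary | None = None,
                      suspect_only: bool = True, stratum: str = ""
                      ) -> ContingencyTable:
    """Cross-tabulate exposure vs event over the supplied cohort.

    ``exposure`` is a drug name, a class label ("VEGFi"/"VEGFRi", requires a
    dictionary; members are aggregated into one exposure), or an explicit
    set of drug names.  Each report is counted exactly once.
    """
    if len(reports) == 0:
        raise ValueError("empty cohort")
    drugs = resolve_exposure(exposure, dictionary)
    exposed = drug_mask(reports, drugs, suspect_only)
    has_event = event_set.match_mask(reports["events"])
    a = int((exposed & has_event).sum())
    b = int((exposed & ~has_event).sum())
    c = int((~exposed & has_event).sum())
    d = int((~exposed & ~has_event).sum())
    label = exposure if isinstance(exposure, str) else "+".join(sorted(drugs))
    return ContingencyTable(a, b, c, d, exposure_label=label,
                            event_label=event_set.name, stratum=stratum)


def resolve_exposure(exposure, dictionary: DrugDictionary | None
                     ) -> frozenset[str]:
    if isinstance(exposure, str):
        if exposure in ("VEGFi", "VEGFRi"):
            if dictionary is None:
                raise ValueError("class exposure needs a DrugDictionary")
            return dictionary.class_members(exposure)
        if exposure == "All":
            if dictionary is None:
                raise ValueError("'All' exposure needs a DrugDictionary")
            return frozenset(dictionary.generics)
        return frozenset([exposure.strip().casefold()])
    return frozenset(d.strip().casefold() for d in exposure)


def compute_ror(table: ContingencyTable, alpha: float = 0.05,
                min_reports: int = 3) -> SignalResult:
    """ROR point estimate with Woolf CI and the signal classification."""
    a, b, c, d = (float(table.a), float(table.b), float(table.c),
                  float(table.d))
    correction = min(a, b, c, d) == 0
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(ror) - z * se))
    ci_high = float(np.exp(np.log(ror) + z * se))
    result = SignalResult(
        ror=float(ror), ci_low=ci_low, ci_high=ci_high,
        n_reports=table.a, alpha=alpha,
        is_signal=False, correction_applied=correction,
        exposure_label=table.exposure_label, event_label=table.event_label,
        stratum=table.stratum)
    return _with_signal(result, min_reports)


def _with_signal(result: SignalResult, min_reports: int) -> SignalResult:
    from dataclasses import replace
    return replace(result, is_signal=classify(result, min_reports))


def classify(result: SignalResult, min_reports: int = 3) -> bool:
    """Signal rule: at least ``min_reports`` exposed event reports and the
    95% CI lower bound strictly above 1."""
    return bool(result.n_reports >= min_reports and result.ci_low > 1.0)


def scan_signals(reports: pd.DataFrame, exposures, event_sets,
                 dictionary: DrugDictionary | None = None,
                 strata: str | None = None, alpha: float = 0.05,
                 min_reports: int = 3, suspect_only: bool = True
                 ) -> pd.DataFrame:
    """One SignalResult row per (exposure, event set[, stratum]).

    ``strata`` names a column (e.g. ``cancer_type``); strata with fewer than
    ``min_reports`` exposed event reports are emitted with ``excluded=True``
    and ``is_signal=False``.  Results are sorted by ROR descending.
    """
    if isinstance(event_sets, EventSet):
        event_sets = [event_sets]
    if isinstance(exposures, str):
        exposures = [exposures]

    # precompute masks once per exposure / event set; strata reuse them
    exp_masks = {}
    for exposure in exposures:
        drugs = resolve_exposure(exposure, dictionary)
        label = exposure if isinstance(exposure, str) else "+".join(sorted(drugs))
        exp_masks[label] = drug_mask(reports, drugs, suspect_only).to_numpy()
    ev_masks = {es.name: es.match_mask(reports["events"]).to_numpy()
                for es in event_sets}

    if strata is None:
        strata_masks = {"": np.ones(len(reports), dtype=bool)}
    else:
        col = reports[strata].astype(str)
        strata_masks = {s: (col == s).to_numpy() for s in sorted(col.unique())}

    rows = []
    for stratum, sel in strata_masks.items():
        n_str = int(sel.sum())
        if n_str == 0:
            continue
        for label, exposed in exp_masks.items():
            for es in event_sets:
                has_event = ev_masks[es.name]
                a = int((exposed & has_event & sel).sum())
                b = int((exposed & ~has_event & sel).sum())
                c = int((~exposed & has_event & sel).sum())
                d = n_str - a - b - c
                tab = ContingencyTable(a, b, c, d, exposure_label=label,
                                       event_label=es.name, stratum=stratum)
                res = compute_ror(tab, alpha=alpha, min_reports=min_reports)
                rows.append({
                    "exposure": label, "event_set": es.name,
                    "stratum": stratum,
                    "a": a, "b": b, "c": c, "d": d,
                    "ror": res.ror, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "n": res.n_reports,
                    "is_signal": res.is_signal,
                    "correction_applied": res.correction_applied,
                    "excluded": res.n_reports < min_reports,
                })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("ror", ascending=False, kind="mergesort"
                              ).reset_index(drop=True)
    return out


def ror_vectorized(a, b, c, d, alpha: float = 0.05):
    """Vectorised ROR + Woolf CI over arrays of cells (zero cells corrected).

    Returns (ror, ci_low, ci_high) arrays; used by simulation-based checks.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
    a, b, c, d = (x + 0.5 * zero for x in (a, b, c, d))
    ror = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, np.exp(np.log(ror) - z * se), np.exp(np.log(ror) + z * se)
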