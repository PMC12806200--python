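"""Time-to-onset (TTO) analysis.

TTO is the number of whole days from therapy start to adverse-event onset.
Groups (drug class, gender, or single drug) are summarised by median and
interquartile range, compared with the Mann-Whitney U test, and displayed as
cumulative-onset step curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .icsr import DrugDictionary, drug_mask


@dataclass
class TtoSample:
    group: str
    onset_days: np.ndarray          # strictly positive
    n_excluded: int = 0             # missing-date or non-positive intervals

    def __post_init__(self):
        self.onset_days = np.asarray(self.onset_days, dtype=float)
        if len(self.onset_days) and (self.onset_days <= 0).any():
            raise ValueError("onset_days must be strictly positive")


def extract_tto(reports: pd.DataFrame, grouping: str = "drug_class",
                dictionary: DrugDictionary | None = None,
                drugs: list[str] | None = None) -> dict[str, TtoSample]:
    """Per-group TTO samples from reports carrying both dates.

    ``grouping`` is one of ``drug_class`` (VEGFi vs VEGFRi suspect exposure),
    ``gender``, or ``drug`` (one sample per generic in ``drugs``).  Intervals
    that are missing or not strictly positive are excluded and counted.
    """
    days = (reports["event_onset"] - reports["therapy_start"]).dt.days
    days = pd.to_numeric(days, errors="coerce")

    if grouping == "drug_class":
        if dictionary is None:
            raise ValueError("drug_class grouping needs a DrugDictionary")
        groups = {cls: drug_mask(reports, dictionary.class_members(cls))
                  for cls in ("VEGFi", "VEGFRi")}
    elif grouping == "gender":
        groups = {g: reports["gender"] == g
                  for g in ("female", "male")}
    elif grouping == "drug":
        if not drugs:
            raise ValueError("drug grouping needs a drug list")
        groups = {d: drug_mask(reports, frozenset([d.casefold()]))
                  for d in drugs}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    out = {}
    for name, mask in groups.items():
        vals = days[mask]
        good = vals[vals > 0]
        out[name] = TtoSample(group=name, onset_days=good.to_numpy(),
                              n_excluded=int(mask.sum() - len(good)))
    return out


def summarize(sample: TtoSample) -> tuple[float, float, float, int]:
    """(median, q1, q3, n) with type-7 linear-interpolation quartiles."""
    x = sample.onset_days
    if len(x) == 0:
        raise ValueError("empty TTO sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # numpy 'linear' = type 7
    return float(med), float(q1), float(q3), int(len(x))


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of x, p).

    Exact p by enumeration when n_x + n_y <= 20 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def cumulative_curve(sample: TtoSample) -> pd.DataFrame:
    """Right-continuous cumulative-onset step curve reaching 100%.

    One row per distinct onset day with the cumulative percentage of events
    on or before that day.
    """
    x = sample.onset_days
    if len(x) == 0:
        raise ValueError("empty TTO sample")
    days, counts = np.unique(x, return_counts=True)
    cum_pct = 100.0 * np.cumsum(counts) / len(x)
    return pd.DataFrame({"group": sample.group, "day": days,
                         "cum_pct": cum_pct})
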