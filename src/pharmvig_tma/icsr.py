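"""Individual case safety report (ICSR) store.

Reports live in a pandas DataFrame with one row per report.  Multi-valued
fields (drugs, adverse-event terms) are stored as ``;``-joined, sorted,
casefolded strings so that the frame round-trips through CSV and supports
vectorised set operations.

Columns
-------
report_id : str
gender : {"female", "male", "unknown"}
age_years : float (NaN allowed)
age_band : str, derived half-open bands
region : {"Americas", "Europe", "Asia", "other", "unknown"}
event_date : datetime64 (NaT allowed)
suspect_drugs : ";"-joined drug names (non-empty for analyzable reports)
concomitant_drugs : ";"-joined drug names (may be empty)
indication : free-text cancer label
cancer_type : derived code ("other" when unmapped)
events : ";"-joined adverse-event preferred terms (non-empty)
outcome : {"fatal", "nonfatal", "unknown"}
therapy_start, event_onset : datetime64 (NaT allowed)
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

REQUIRED_COLUMNS = [
    "report_id", "gender", "age_years", "region", "event_date",
    "suspect_drugs", "indication", "events", "outcome",
    "therapy_start", "event_onset",
]

#: the seven deduplication key fields; "medication" is the union of suspect
#: and concomitant drugs, order-insensitive.
DEDUP_KEYS = [
    "gender", "age_years", "region", "event_date", "events",
    "medication", "indication",
]

DEFAULT_AGE_BANDS = [(0.0, 45.0, "0-44"), (45.0, 65.0, "45-64"),
                     (65.0, 75.0, "65-74"), (75.0, np.inf, "75+")]

DATE_COLUMNS = ["event_date", "therapy_start", "event_onset"]


def _data_path(name: str):
    return importlib.resources.files("pharmvig_tma.data") / name


def join_terms(terms) -> str:
    """Canonical ;-joined representation of a set of terms."""
    return ";".join(sorted(t.strip().casefold() for t in terms if t and t.strip()))


def split_terms(joined: str) -> list[str]:
    if not isinstance(joined, str) or not joined:
        return []
    return joined.split(";")


@dataclass(frozen=True)
class DrugDictionary:
    """Brand/synonym -> (generic name, class) mapping for the study drugs."""

    generics: dict[str, str]            # generic -> class (VEGFi | VEGFRi)
    synonyms: dict[str, str] = field(default_factory=dict)  # synonym -> generic

    def __post_init__(self):
        bad = set(self.generics.values()) - {"VEGFi", "VEGFRi"}
        if bad:
            raise ValueError(f"unknown drug classes: {sorted(bad)}")
        for syn, gen in self.synonyms.items():
            if gen not in self.generics:
                raise ValueError(f"synonym {syn!r} maps to unknown generic {gen!r}")

    @classmethod
    def bundled(cls) -> "DrugDictionary":
        with _data_path("drug_dictionary.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls(generics=raw["generics"], synonyms=raw.get("synonyms", {}))

    @classmethod
    def from_yaml(cls, path) -> "DrugDictionary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(generics=raw["generics"], synonyms=raw.get("synonyms", {}))

    def normalize_name(self, name: str) -> str:
        """Map a (possibly branded) name to its generic; unknown names verbatim."""
        key = name.strip().casefold()
        if key in self.generics:
            return key
        return self.synonyms.get(key, key)

    def drug_class(self, name: str) -> str | None:
        """Class of a normalized name, or None for unclassified drugs."""
        return self.generics.get(self.normalize_name(name))

    def class_members(self, cls_label: str) -> frozenset[str]:
        return frozenset(g for g, c in self.generics.items() if c == cls_label)


@dataclass(frozen=True)
class EventSet:
    """Named set of adverse-event preferred terms, matched case-insensitively."""

    name: str
    terms: frozenset[str]

    def __post_init__(self):
        if not self.terms:
            raise ValueError("event set must be non-empty")
        object.__setattr__(self, "terms",
                           frozenset(t.strip().casefold() for t in self.terms))

    @classmethod
    def bundled_tma(cls) -> "EventSet":
        with _data_path("event_sets.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls(name="tma_core", terms=frozenset(raw["tma_core"]))

    @classmethod
    def from_yaml(cls, path, name: str) -> "EventSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(name=name, terms=frozenset(raw[name]))

    def match_mask(self, events_col: pd.Series) -> pd.Series:
        """Boolean mask: does a report's event set intersect this term set?"""
        return _member_mask(events_col, self.terms)


def load_cancer_lookup() -> dict[str, str]:
    """indication text (casefolded) -> cancer-type code."""
    with _data_path("cancer_types.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    lut: dict[str, str] = {}
    for code, labels in raw.items():
        for label in labels:
            lut[label.strip().casefold()] = code
    return lut


def assign_age_band(age: pd.Series, bands=None) -> pd.Series:
    """Bin ages into half-open [lo, hi) bands; missing age -> 'unknown'."""
    bands = bands or DEFAULT_AGE_BANDS
    out = pd.Series("unknown", index=age.index, dtype=object)
    for lo, hi, label in bands:
        out[(age >= lo) & (age < hi)] = label
    return out


def map_cancer_type(indication: pd.Series, lookup: dict[str, str] | None = None
                    ) -> pd.Series:
    lookup = lookup if lookup is not None else load_cancer_lookup()
    return indication.fillna("").str.strip().str.casefold().map(lookup).fillna("other")


def ingest_reports(raw: pd.DataFrame, age_bands=None,
                   cancer_lookup: dict[str, str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a raw report table.

    Returns ``(reports, quarantine)``: well-formed rows with parsed dates and
    derived ``age_band`` / ``cancer_type`` columns, and malformed rows with a
    ``quarantine_reason`` column.  A missing required column aborts.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise KeyError(f"missing required column(s): {missing}")

    df = raw.copy()
    if "concomitant_drugs" not in df.columns:
        df["concomitant_drugs"] = ""
    df["concomitant_drugs"] = df["concomitant_drugs"].fillna("")

    reasons = pd.Series("", index=df.index, dtype=object)

    for col in DATE_COLUMNS:
        orig = df[col]
        parsed = pd.to_datetime(orig, errors="coerce", format="ISO8601")
        had_value = orig.notna() & (orig.astype(str).str.strip() != "")
        bad = had_value & parsed.isna()
        reasons[bad] += f"unparseable {col};"
        df[col] = parsed

    age = pd.to_numeric(df["age_years"], errors="coerce")
    bad_age = df["age_years"].notna() & age.isna()
    reasons[bad_age] += "unparseable age_years;"
    reasons[age < 0] += "negative age_years;"
    df["age_years"] = age

    for col in ("events", "suspect_drugs"):
        df[col] = df[col].fillna("").map(lambda s: join_terms(split_terms_any(s)))
    df["concomitant_drugs"] = df["concomitant_drugs"].map(
        lambda s: join_terms(split_terms_any(s)))
    reasons[df["events"] == ""] += "no adverse-event terms;"
    reasons[df["suspect_drugs"] == ""] += "no suspect drugs;"

    quarantined = reasons != ""
    quarantine = df[quarantined].copy()
    quarantine["quarantine_reason"] = reasons[quarantined].str.rstrip(";")

    good = df[~quarantined].copy()
    good["age_band"] = assign_age_band(good["age_years"], age_bands)
    good["cancer_type"] = map_cancer_type(good["indication"], cancer_lookup)
    good["gender"] = good["gender"].fillna("unknown")
    good["region"] = good["region"].fillna("unknown")
    good["outcome"] = good["outcome"].fillna("unknown")
    return good.reset_index(drop=True), quarantine.reset_index(drop=True)


def split_terms_any(s) -> list[str]:
    """Split on ';' (accepting stray whitespace); tolerant of non-strings."""
    if not isinstance(s, str):
        return []
    return [t for t in (p.strip() for p in s.split(";")) if t]


def _medication_key(df: pd.DataFrame) -> pd.Series:
    sus = df["suspect_drugs"].fillna("")
    con = df.get("concomitant_drugs", pd.Series("", index=df.index)).fillna("")
    joined = (sus + ";" + con).map(lambda s: join_terms(split_terms_any(s)))
    return joined


def deduplicate(reports: pd.DataFrame) -> pd.DataFrame:
    """Drop records identical on the seven key fields, keeping first by input order.

    Keys: gender, age, region, event date, adverse-event set, medication
    (suspect plus concomitant, order-insensitive), indication.  Missing values
    participate as a distinct sentinel, so two records both missing age can
    still match.  Idempotent.
    """
    df = reports.copy()
    key = pd.DataFrame({
        "gender": df["gender"].fillna("\0"),
        "age_years": df["age_years"].astype(float),
        "region": df["region"].fillna("\0"),
        "event_date": df["event_date"],
        "events": df["events"].fillna("\0"),
        "medication": _medication_key(df),
        "indication": df["indication"].fillna("\0").astype(str).str.strip().str.casefold(),
    })
    # NaN != NaN breaks "missingness matches"; stringify with a sentinel
    keep = ~key.astype(str).duplicated(keep="first")
    out = df[keep].reset_index(drop=True)
    out.attrs["n_duplicates_removed"] = int((~keep).sum())
    return out


def normalize_drugs(reports: pd.DataFrame, dictionary: DrugDictionary
                    ) -> pd.DataFrame:
    """Replace recognized brand/synonym names by generics (case/whitespace
    insensitive); unrecognized names are kept verbatim (unclassified)."""
    df = reports.copy()

    def norm(joined: str) -> str:
        return join_terms(dictionary.normalize_name(t)
                          for t in split_terms_any(joined))

    for col in ("suspect_drugs", "concomitant_drugs"):
        if col in df.columns:
            df[col] = df[col].fillna("").map(norm)
    return df


_FILTER_KEYS = {"cancer_type", "drug_class", "drug", "gender", "region",
                "date_range"}


def _member_mask(col: pd.Series, members) -> pd.Series:
    """Vectorised 'does the ;-joined cell intersect members'; single-token
    cells go through isin, multi-token cells through a per-row check."""
    members = frozenset(members)
    col = col.fillna("")
    mask = col.isin(members)
    multi = col.str.contains(";", regex=False).to_numpy()
    if multi.any():
        arr = mask.to_numpy().copy()
        arr[multi] = [any(t in members for t in split_terms(s))
                      for s in col.to_numpy()[multi]]
        mask = pd.Series(arr, index=col.index)
    return mask.astype(bool)


def drug_mask(reports: pd.DataFrame, drugs: frozenset[str],
              suspect_only: bool = True) -> pd.Series:
    """Mask of reports whose (suspect) drug set intersects ``drugs``."""
    mask = _member_mask(reports["suspect_drugs"], drugs)
    if not suspect_only and "concomitant_drugs" in reports.columns:
        mask = mask | _member_mask(reports["concomitant_drugs"], drugs)
    return mask


def select_cohort(reports: pd.DataFrame, filters: dict | None = None,
                  dictionary: DrugDictionary | None = None,
                  suspect_only: bool = True) -> pd.DataFrame:
    """Subset reports by the conjunction of filters.

    Supported keys: ``cancer_type``, ``drug_class`` (VEGFi | VEGFRi),
    ``drug`` (generic name), ``gender``, ``region``,
    ``date_range`` = (start, end) on event_date.  Unknown keys are rejected.
    By default only the suspect role counts as drug exposure.
    """
    filters = filters or {}
    unknown = set(filters) - _FILTER_KEYS
    if unknown:
        raise KeyError(f"unknown filter key(s): {sorted(unknown)}")
    mask = pd.Series(True, index=reports.index)
    if "cancer_type" in filters:
        mask &= reports["cancer_type"] == filters["cancer_type"]
    if "drug_class" in filters:
        if dictionary is None:
            raise ValueError("drug_class filter needs a DrugDictionary")
        members = dictionary.class_members(filters["drug_class"])
        mask &= drug_mask(reports, members, suspect_only)
    if "drug" in filters:
        mask &= drug_mask(reports, frozenset([filters["drug"]]), suspect_only)
    if "gender" in filters:
        mask &= reports["gender"] == filters["gender"]
    if "region" in filters:
        mask &= reports["region"] == filters["region"]
    if "date_range" in filters:
        lo, hi = filters["date_range"]
        mask &= reports["event_date"].between(pd.Timestamp(lo), pd.Timestamp(hi))
    return reports[mask].reset_index(drop=True)
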