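"""Seeded synthetic inputs for every pipeline stage.

Real spontaneous-report databases (FAERS, Vigibase), hospital biochemistry
panels, and TCGA expression matrices are not redistributable, so these
generators produce tables with the same schema and the statistical structure
each downstream stage assumes, with the planted ground truth (association
ratios, injected duplicates, shifted gene sets, target rank correlation)
returned as a sidecar for recovery tests.

Default parameters are anchored to the study conditions: a TMA background
reporting rate of 0.2% of oncology reports, planted reporting-ratio 5 for
VEGF-ligand inhibitors versus 1.2 for receptor inhibitors, log-normal
time-to-onset with class medians 201 vs 35 days (IQR-calibrated dispersion),
a 1698-patient biochemistry cohort at the printed pre/post marker means, and
TTP-flag fractions 1.18% pre / 3.77% post.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarker import MARKERS, TTP_CREATININE_MAX, TTP_PLATELET_MAX
from .icsr import assign_age_band, join_terms, map_cancer_type

TMA_TERMS = [
    "thrombotic microangiopathy", "thrombotic thrombocytopenic purpura",
    "haemolytic uraemic syndrome", "atypical haemolytic uraemic syndrome",
    "microangiopathic haemolytic anaemia", "renal thrombotic microangiopathy",
]

BACKGROUND_TERMS = [
    "nausea", "fatigue", "hypertension", "diarrhoea", "rash", "anaemia",
    "vomiting", "pyrexia", "headache", "neutropenia", "proteinuria",
    "dizziness",
]

STUDY_VEGFI = ["bevacizumab", "ranibizumab", "brolucizumab", "aflibercept",
               "conbercept", "pegaptanib"]
STUDY_VEGFRI = ["ramucirumab", "nintedanib", "apatinib", "axitinib",
                "sunitinib", "sorafenib", "regorafenib", "vandetanib",
                "cabozantinib", "pazopanib", "lenvatinib", "anlotinib",
                "fruquintinib", "tivozanib", "cediranib", "brivanib"]
OTHER_DRUGS = ["paclitaxel", "cisplatin", "carboplatin", "pembrolizumab",
               "nivolumab", "doxorubicin", "gemcitabine", "fluorouracil"]

DEFAULT_CATALOG = ([(d, "VEGFi") for d in STUDY_VEGFI]
                   + [(d, "VEGFRi") for d in STUDY_VEGFRI]
                   + [(d, "other") for d in OTHER_DRUGS])

CANCER_LABELS = [
    "endometrial cancer", "ovarian cancer", "gastric cancer", "glioblastoma",
    "breast cancer", "renal cell carcinoma", "colon cancer", "rectal cancer",
    "hepatocellular carcinoma", "lung squamous cell carcinoma",
    "lung adenocarcinoma", "soft tissue sarcoma", "thyroid cancer",
    "pancreatic cancer",  # maps to "other"
]

TCGA_CODES_13 = ["UCEC", "OV", "STAD", "GBM", "BRCA", "KIRC", "COAD", "READ",
                 "LIHC", "LUSC", "LUAD", "SARC", "THCA"]

#: 0.6745 = standard-normal upper quartile; log-normal sigma from a printed
#: median/IQR via sigma = ln(q3/q1) / (2 * 0.6745)
_Z75 = 0.6744897501960817

DEFAULT_TTO = {
    # (median days, log-scale sigma): medians 201 / 35, IQRs 70-415 / 21-70
    "VEGFi": (201.0, float(np.log(415.0 / 70.0) / (2 * _Z75))),
    "VEGFRi": (35.0, float(np.log(70.0 / 21.0) / (2 * _Z75))),
    "other": (60.0, 1.0),
}

DEFAULT_DEMOGRAPHICS = {
    "gender": {"female": 0.45, "male": 0.40, "unknown": 0.15},
    "age_band": {"0-44": 0.20, "45-64": 0.35, "65-74": 0.25, "75+": 0.15,
                 "unknown": 0.05},
    "region": {"Americas": 0.45, "Europe": 0.30, "Asia": 0.15, "other": 0.05,
               "unknown": 0.05},
}

DEFAULT_OUTCOME = {"nonfatal": 0.84, "fatal": 0.10, "unknown": 0.06}

_AGE_RANGES = {"0-44": (18.0, 45.0), "45-64": (45.0, 65.0),
               "65-74": (65.0, 75.0), "75+": (75.0, 90.0)}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _check_probs(probs: dict, name: str) -> None:
    vals = np.array(list(probs.values()), dtype=float)
    if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
        raise ConfigError(f"{name} probabilities must be non-negative and sum to 1")


@dataclass
class IcsrSimConfig:
    n_reports: int = 200_000
    drug_catalog: list = field(default_factory=lambda: list(DEFAULT_CATALOG))
    background_event_rate: float = 0.002
    #: share of reports whose suspect drug falls in each class; study drugs
    #: are a small minority of an oncology report universe
    class_exposure_fractions: dict = field(
        default_factory=lambda: {"VEGFi": 0.045, "VEGFRi": 0.055,
                                 "other": 0.90})
    planted_associations: dict = field(
        default_factory=lambda: {("VEGFi", "tma_core"): 5.0,
                                 ("VEGFRi", "tma_core"): 1.2})
    tto_distributions: dict = field(default_factory=lambda: dict(DEFAULT_TTO))
    demographic_mix: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_DEMOGRAPHICS.items()})
    outcome_mix: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME))
    duplicate_fraction: float = 0.05
    co_medication_rate: float = 0.0
    event_terms: dict = field(default_factory=lambda: {"tma_core": list(TMA_TERMS)})
    seed: int = 0

    def __post_init__(self):
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        if not 0 < self.background_event_rate < 1:
            raise ConfigError("background_event_rate must be in (0, 1)")
        if not 0 <= self.duplicate_fraction < 1:
            raise ConfigError("duplicate_fraction must be in [0, 1)")
        # YAML-sourced configs use "drug|event_set" (or bare drug) string keys
        normalized = {}
        for key, ratio in self.planted_associations.items():
            if isinstance(key, str):
                key = tuple(key.split("|", 1)) if "|" in key \
                    else (key, "tma_core")
            normalized[key] = ratio
        self.planted_associations = normalized
        for key, ratio in self.planted_associations.items():
            if not np.isfinite(ratio) or ratio < 0:
                raise ConfigError(f"planted ratio for {key} must be finite, >= 0")
            if ratio * self.background_event_rate > 1:
                raise ConfigError(
                    f"planted ratio {ratio} x background rate "
                    f"{self.background_event_rate} exceeds probability 1")
        classes = {c for _, c in self.drug_catalog}
        if not classes <= {"VEGFi", "VEGFRi", "other"}:
            raise ConfigError("drug classes must be VEGFi, VEGFRi or other")
        _check_probs({c: self.class_exposure_fractions.get(c, 0.0)
                      for c in ("VEGFi", "VEGFRi", "other")},
                     "class_exposure_fractions")
        for part in ("gender", "age_band", "region"):
            _check_probs(self.demographic_mix[part], part)
        _check_probs(self.outcome_mix, "outcome")


def _drug_ratios(config: IcsrSimConfig) -> dict[str, float]:
    """Per-drug TMA reporting ratio, resolving class-level plantings."""
    by_class: dict[str, float] = {}
    by_drug: dict[str, float] = {}
    for (target, _event_set), ratio in config.planted_associations.items():
        if target in ("VEGFi", "VEGFRi", "other"):
            by_class[target] = ratio
        else:
            by_drug[target.casefold()] = ratio
    out = {}
    for drug, cls in config.drug_catalog:
        out[drug] = by_drug.get(drug.casefold(), by_class.get(cls, 1.0))
    return out


def generate_icsr_cohort(config: IcsrSimConfig
                         ) -> tuple[pd.DataFrame, dict]:
    """Synthetic ICSR cohort in the validated report schema, plus ground truth.

    Each report carries one suspect drug (plus optional concomitants); the
    probability of a TMA-spectrum event given the drug is its planted ratio
    times the background rate.  TMA reports get onset dates drawn from the
    drug class's log-normal time-to-onset distribution.  A configured
    fraction of records are exact copies of earlier records on all
    deduplication key fields (fresh report ids), recorded in the truth
    sidecar.
    """
    rng = np.random.default_rng(config.seed)
    n_dup = int(round(config.n_reports * config.duplicate_fraction))
    n = config.n_reports - n_dup

    drugs = np.array([d for d, _ in config.drug_catalog])
    classes = np.array([c for _, c in config.drug_catalog])
    # class share set by class_exposure_fractions, uniform within class
    class_counts = {c: int((classes == c).sum()) for c in np.unique(classes)}
    weights = np.array([config.class_exposure_fractions.get(c, 0.0)
                        / class_counts[c] for c in classes])
    weights = weights / weights.sum()
    drug_idx = rng.choice(len(drugs), size=n, p=weights)
    drug = drugs[drug_idx]
    drug_class = classes[drug_idx]

    ratios = _drug_ratios(config)
    p_event = np.array([ratios[d] for d in drugs])[drug_idx] \
        * config.background_event_rate
    has_tma = rng.random(n) < p_event

    events = np.array(BACKGROUND_TERMS)[
        rng.integers(0, len(BACKGROUND_TERMS), size=n)].astype(object)
    tma_terms = np.array(config.event_terms.get("tma_core", TMA_TERMS))
    events[has_tma] = tma_terms[rng.integers(0, len(tma_terms),
                                             size=int(has_tma.sum()))]
    # some reports carry a second, unrelated event term
    extra = rng.random(n) < 0.3
    extra_terms = np.array(BACKGROUND_TERMS)[
        rng.integers(0, len(BACKGROUND_TERMS), size=n)]
    events = pd.Series(events)
    events[extra] = [join_terms([a, b]) for a, b
                     in zip(events[extra], extra_terms[extra])]

    def sample_cat(mix: dict, size: int) -> np.ndarray:
        keys = np.array(list(mix.keys()))
        return keys[rng.choice(len(keys), size=size,
                               p=np.array(list(mix.values())))]

    gender = sample_cat(config.demographic_mix["gender"], n)
    band = sample_cat(config.demographic_mix["age_band"], n)
    age = np.full(n, np.nan)
    for b, (lo, hi) in _AGE_RANGES.items():
        m = band == b
        age[m] = np.floor(rng.uniform(lo, hi, size=int(m.sum())))
    region = sample_cat(config.demographic_mix["region"], n)
    outcome = sample_cat(config.outcome_mix, n)
    indication = np.array(CANCER_LABELS)[
        rng.integers(0, len(CANCER_LABELS), size=n)]

    start = (np.datetime64("2013-01-01")
             + rng.integers(0, 3650, size=n).astype("timedelta64[D]"))
    delay = np.ceil(rng.uniform(1, 365, size=n))
    for cls, (median, sigma) in config.tto_distributions.items():
        m = has_tma & (drug_class == cls)
        k = int(m.sum())
        if k:
            delay[m] = np.maximum(
                1.0, np.round(rng.lognormal(np.log(median), sigma, size=k)))
    onset = start + delay.astype("timedelta64[D]")

    suspect = pd.Series(drug).str.casefold()
    comed = rng.random(n) < config.co_medication_rate
    concomitant = pd.Series("", index=range(n), dtype=object)
    if comed.any():
        extra_drug = drugs[rng.integers(0, len(drugs), size=n)]
        concomitant[comed] = pd.Series(extra_drug).str.casefold()[comed]

    df = pd.DataFrame({
        "report_id": [f"R{i:07d}" for i in range(n)],
        "gender": gender,
        "age_years": age,
        "region": region,
        "event_date": pd.to_datetime(onset),
        "suspect_drugs": suspect,
        "concomitant_drugs": concomitant,
        "indication": indication,
        "events": events,
        "outcome": outcome,
        "therapy_start": pd.to_datetime(start),
        "event_onset": pd.to_datetime(onset),
    })

    dup_ids: list[str] = []
    if n_dup:
        src = rng.integers(0, n, size=n_dup)
        copies = df.iloc[src].copy().reset_index(drop=True)
        copies["report_id"] = [f"D{i:07d}" for i in range(n_dup)]
        dup_ids = copies["report_id"].tolist()
        df = pd.concat([df, copies], ignore_index=True)

    df["age_band"] = assign_age_band(df["age_years"])
    df["cancer_type"] = map_cancer_type(df["indication"])

    truth = {
        "planted_associations": [
            {"target": t, "event_set": es, "ratio": r}
            for (t, es), r in config.planted_associations.items()],
        "per_drug_ratio": ratios,
        "background_event_rate": config.background_event_rate,
        "duplicate_report_ids": dup_ids,
        "n_tma_reports": int(has_tma.sum()),
        "seed": config.seed,
    }
    return df, truth


# ---------------------------------------------------------------------------
# biochemistry cohort
# ---------------------------------------------------------------------------

DEFAULT_PRE_MEANS = {"platelet": 233.4, "creatinine": 76.4,
                     "indirect_bilirubin": 6.9, "rbc": 3.9, "mcv": 90.19}
DEFAULT_POST_MEANS = {"platelet": 171.1, "creatinine": 76.7,
                      "indirect_bilirubin": 7.9, "rbc": 3.8, "mcv": 91.3}
DEFAULT_PRE_SDS = {"platelet": 55.0, "creatinine": 22.0,
                   "indirect_bilirubin": 3.0, "rbc": 0.5, "mcv": 5.5}
DEFAULT_POST_SDS = {"platelet": 45.0, "creatinine": 23.0,
                    "indirect_bilirubin": 3.5, "rbc": 0.5, "mcv": 5.5}


@dataclass
class BiochemSimConfig:
    n_patients: int = 1698
    pre_means: dict = field(default_factory=lambda: dict(DEFAULT_PRE_MEANS))
    pre_sds: dict = field(default_factory=lambda: dict(DEFAULT_PRE_SDS))
    post_means: dict = field(default_factory=lambda: dict(DEFAULT_POST_MEANS))
    post_sds: dict = field(default_factory=lambda: dict(DEFAULT_POST_SDS))
    pre_post_correlation: float = 0.7
    ttp_fraction_pre: float = 0.0118
    ttp_fraction_post: float = 0.0377
    seed: int = 0

    def __post_init__(self):
        for d in (self.pre_means, self.pre_sds, self.post_means, self.post_sds):
            if set(d) != set(MARKERS):
                raise ConfigError(f"marker names must be exactly {MARKERS}")
        for d in (self.pre_sds, self.post_sds):
            if any(v <= 0 for v in d.values()):
                raise ConfigError("marker SDs must be positive")
        if not 0 <= self.pre_post_correlation < 1:
            raise ConfigError("pre_post_correlation must be in [0, 1)")
        for f in (self.ttp_fraction_pre, self.ttp_fraction_post):
            if not 0 <= f < 1:
                raise ConfigError("ttp fractions must be in [0, 1)")
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")


def _truncate_positive(x: np.ndarray, rng, mean, sd) -> np.ndarray:
    """Resample non-positive draws (physiologic floor), clip as last resort."""
    for _ in range(20):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(x, 1e-3, None)


def generate_biochem_cohort(config: BiochemSimConfig
                            ) -> tuple[pd.DataFrame, dict]:
    """Paired pre/post marker panels, long format, plus ground truth.

    Each marker is bivariate normal across timepoints with the configured
    correlation, truncated at physiologic floors (> 0).  TTP-flagged
    patients are a planted Bernoulli fraction per timepoint whose platelet
    is drawn uniformly below the 30 x10^9/L threshold; the bulk platelet
    mean is adjusted so the mixture mean equals the configured mean, and
    bulk draws below the threshold are clipped to it so the flagged fraction
    matches the configured fraction in expectation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    rho = config.pre_post_correlation
    data = {"pre": {}, "post": {}}

    forced = {"pre": rng.random(n) < config.ttp_fraction_pre,
              "post": rng.random(n) < config.ttp_fraction_post}
    frac = {"pre": config.ttp_fraction_pre, "post": config.ttp_fraction_post}
    ttp_platelet_mean = (5.0 + TTP_PLATELET_MAX) / 2  # U(5, 30) mean

    for marker in MARKERS:
        m1, s1 = config.pre_means[marker], config.pre_sds[marker]
        m2, s2 = config.post_means[marker], config.post_sds[marker]
        if marker == "platelet":
            # bulk mean adjusted so mixture (bulk + forced-TTP) hits the target
            m1 = ((m1 - frac["pre"] * ttp_platelet_mean)
                  / (1 - frac["pre"])) if frac["pre"] else m1
            m2 = ((m2 - frac["post"] * ttp_platelet_mean)
                  / (1 - frac["post"])) if frac["post"] else m2
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        pre = _truncate_positive(m1 + s1 * z1, rng, m1, s1)
        post = _truncate_positive(m2 + s2 * z2, rng, m2, s2)
        if marker == "platelet":
            # keep unforced patients strictly above the TTP threshold
            pre = np.maximum(pre, TTP_PLATELET_MAX)
            post = np.maximum(post, TTP_PLATELET_MAX)
            pre[forced["pre"]] = rng.uniform(5.0, TTP_PLATELET_MAX,
                                             int(forced["pre"].sum()))
            post[forced["post"]] = rng.uniform(5.0, TTP_PLATELET_MAX,
                                               int(forced["post"].sum()))
        if marker == "creatinine":
            # forced-TTP patients must sit below the TTP creatinine bound
            for tp, arr in (("pre", pre), ("post", post)):
                high = forced[tp] & (arr >= TTP_CREATININE_MAX)
                arr[high] = rng.uniform(40.0, TTP_CREATININE_MAX - 1.0,
                                        int(high.sum()))
        data["pre"][marker] = pre
        data["post"][marker] = post

    frames = []
    ids = [f"P{i:05d}" for i in range(n)]
    for tp in ("pre", "post"):
        frames.append(pd.DataFrame({"patient_id": ids, "timepoint": tp,
                                    **data[tp]}))
    panels = pd.concat(frames, ignore_index=True)
    truth = {
        "ttp_forced_pre": [ids[i] for i in np.flatnonzero(forced["pre"])],
        "ttp_forced_post": [ids[i] for i in np.flatnonzero(forced["post"])],
        "pre_means": dict(config.pre_means),
        "post_means": dict(config.post_means),
        "seed": config.seed,
    }
    return panels, truth


# ---------------------------------------------------------------------------
# expression experiment
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    n_genes: int = 1000
    n_samples_per_group: int = 6
    gene_sets: dict = field(default_factory=dict)   # name -> list of genes
    planted_sets: dict = field(default_factory=dict)  # name -> log2 shift
    dispersion: float = 1.0
    n_random_sets: int = 10     # auto-generated null sets when gene_sets empty
    random_set_size: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ConfigError("n_genes and n_samples_per_group must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        for name, members in self.gene_sets.items():
            if not members:
                raise ConfigError(f"gene set {name!r} is empty")
        unknown = set(self.planted_sets) - set(self.gene_sets) \
            if self.gene_sets else set()
        if unknown:
            raise ConfigError(f"planted sets not in gene_sets: {sorted(unknown)}")


def generate_expression_experiment(config: ExpressionSimConfig
                                   ) -> tuple[pd.DataFrame, np.ndarray, dict, dict]:
    """(expression genes x samples, group labels, gene sets, truth).

    Log2 expression is normal around per-gene baselines with the configured
    dispersion; member genes of planted sets are shifted by the configured
    amount (log2 scale) in the treated group.  The linear-scale matrix is
    strictly positive.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]

    gene_sets = {k: list(v) for k, v in config.gene_sets.items()}
    if not gene_sets:
        for j in range(config.n_random_sets):
            members = rng.choice(genes, size=min(config.random_set_size,
                                                 config.n_genes),
                                 replace=False)
            gene_sets[f"set_{j:02d}"] = list(members)
        planted = dict(config.planted_sets)
        for name in planted:
            if name not in gene_sets:
                members = rng.choice(genes, size=min(config.random_set_size,
                                                     config.n_genes),
                                     replace=False)
                gene_sets[name] = list(members)
    else:
        planted = dict(config.planted_sets)

    n_per = config.n_samples_per_group
    labels = np.array(["control"] * n_per + ["treated"] * n_per)
    cols = [f"ctrl_{i}" for i in range(n_per)] + [f"trt_{i}" for i in range(n_per)]

    base = rng.uniform(3.0, 9.0, size=config.n_genes)
    log2e = rng.normal(base[:, None], config.dispersion,
                       size=(config.n_genes, 2 * n_per))
    gene_index = {g: i for i, g in enumerate(genes)}
    for name, shift in planted.items():
        rows = [gene_index[g] for g in gene_sets[name] if g in gene_index]
        log2e[np.ix_(rows, np.flatnonzero(labels == "treated"))] += shift

    expr = pd.DataFrame(np.power(2.0, log2e), index=genes, columns=cols)
    truth = {"planted_sets": planted, "seed": config.seed}
    return expr, labels, gene_sets, truth


# ---------------------------------------------------------------------------
# per-cancer pathway scores vs ROR
# ---------------------------------------------------------------------------

def generate_pathway_ror_dataset(n_cancers: int = 13, n_pathways: int = 5,
                                 planted_rho: float = 0.8, seed: int = 0,
                                 target_pathway: str | None = None
                                 ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """(per-cancer pathway-score table, per-cancer ROR vector, truth).

    The designated pathway column and log-ROR follow a Gaussian copula whose
    Pearson parameter r = 2 sin(pi * rho_s / 6) targets the requested
    Spearman correlation; |rho| = 1 uses an exact monotone transform so the
    sample rank correlation is exactly +/-1.  Other pathways are independent
    noise.
    """
    if n_cancers < 4:
        raise ConfigError("n_cancers must be >= 4")
    if abs(planted_rho) > 1:
        raise ConfigError("|planted_rho| must be <= 1")
    rng = np.random.default_rng(seed)
    cancers = TCGA_CODES_13 if n_cancers == 13 else \
        [f"C{i:02d}" for i in range(n_cancers)]
    pathways = [f"pathway_{j:02d}" for j in range(n_pathways)]
    target = target_pathway or pathways[0]
    if target not in pathways:
        raise ConfigError(f"target pathway {target!r} not among columns")

    scores = pd.DataFrame(rng.standard_normal((n_cancers, n_pathways)),
                          index=cancers, columns=pathways)
    z = scores[target].to_numpy()
    if abs(planted_rho) == 1.0:
        log_ror = np.sign(planted_rho) * z
    else:
        r = 2 * np.sin(np.pi * planted_rho / 6)
        log_ror = r * z + np.sqrt(1 - r ** 2) * rng.standard_normal(n_cancers)
    ror = pd.Series(np.exp(0.5 * log_ror), index=cancers, name="ror")
    truth = {"planted_rho": planted_rho, "target_pathway": target,
             "seed": seed}
    return scores, ror, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
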