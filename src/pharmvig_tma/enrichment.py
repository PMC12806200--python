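"""Gene-set enrichment scoring.

Two scorers over a genes x samples expression matrix:

* ``ssgsea_scores`` — single-sample GSEA: per sample, genes are ranked by
  expression (average ranks for ties) and a gene set's score is the sum over
  the ordered gene list of the difference between the weighted in-set ECDF
  (weights proportional to rank^alpha) and the uniform out-of-set ECDF.
* ``gsea_two_group`` — two-group GSEA: genes ranked by a signal-to-noise
  ratio, enrichment score (ES) as the maximum deviation of the weighted
  Kolmogorov-Smirnov running sum, null distribution by seeded gene-label
  permutation, normalized ES against same-sign null magnitudes, and
  Benjamini-Hochberg adjustment across sets.

Gene-label (rather than phenotype) permutation is used because two-group
designs with few samples per group admit too few distinct phenotype
permutations for a useful null.

``correlate_ror_pathways`` closes the loop: Spearman rank correlation of a
per-cancer pathway-score summary against per-cancer reporting odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float | None
    p_perm: float
    p_adj: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.es))


# ---------------------------------------------------------------------------
# GMT gene-set files
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """GMT: tab-separated lines of name, description, member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def restrict_to_matrix(collection: dict, genes, min_size: int = 2
                       ) -> dict[str, set[str]]:
    """Drop set members absent from the matrix; skip sets left with fewer
    than ``min_size`` genes (warned, with drop counts logged)."""
    present = set(genes)
    out = {}
    for name, members in collection.items():
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        kept = set(members) & present
        dropped = len(members) - len(kept)
        if dropped:
            warnings.warn(f"{name}: {dropped} member gene(s) absent from matrix")
        if len(kept) < min_size:
            warnings.warn(f"{name}: fewer than {min_size} genes present; skipped")
            continue
        out[name] = kept
    return out


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_scores(expr: pd.DataFrame, collection: dict,
                  alpha: float = 0.25, normalize: bool = True,
                  min_size: int = 2) -> pd.DataFrame:
    """Per-sample enrichment scores, sets x samples.

    For each sample: genes ordered by decreasing expression rank r (average
    ranks for ties); for each set S the score is

        sum_i [ P_in(i) - P_out(i) ],
        P_in(i)  = sum_{j in S, j <= i} r_j^alpha / sum_{j in S} r_j^alpha,
        P_out(i) = #{j not in S, j <= i} / (N - |S|).

    With ``normalize`` the whole score matrix is divided by its range
    (max - min), a sign-preserving min-max scaling that makes scores
    comparable across samples.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    sets = restrict_to_matrix(collection, expr.index, min_size=min_size)
    if not sets:
        raise ValueError("no usable gene sets after matrix restriction")
    genes = np.asarray(expr.index)
    n = len(genes)
    scores = np.zeros((len(sets), expr.shape[1]))
    set_masks = {name: np.isin(genes, list(members))
                 for name, members in sets.items()}
    for s_idx, sample in enumerate(expr.columns):
        vals = expr[sample].to_numpy(dtype=float)
        ranks = stats.rankdata(vals, method="average")
        order = np.argsort(-ranks, kind="stable")
        r_desc = ranks[order]
        for g_idx, (name, mask) in enumerate(set_masks.items()):
            in_set = mask[order]
            w = np.where(in_set, r_desc ** alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_set) / (n - in_set.sum())
            scores[g_idx, s_idx] = np.sum(p_in - p_out)
    out = pd.DataFrame(scores, index=list(sets), columns=expr.columns)
    if normalize:
        rng_ = out.to_numpy().max() - out.to_numpy().min()
        if rng_ > 0:
            out = out / rng_
    return out


# ---------------------------------------------------------------------------
# two-group GSEA
# ---------------------------------------------------------------------------

def signal_to_noise(expr: pd.DataFrame, labels, positive_label) -> pd.Series:
    """Per-gene (mean_pos - mean_neg)/(sd_pos + sd_neg) with the SD floor
    sd >= 0.2*|mean| + 0.2 in each group."""
    labels = np.asarray(labels)
    pos = expr.loc[:, labels == positive_label].to_numpy(dtype=float)
    neg = expr.loc[:, labels != positive_label].to_numpy(dtype=float)
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    m1, m2 = pos.mean(axis=1), neg.mean(axis=1)
    s1 = np.maximum(pos.std(axis=1, ddof=1), 0.2 * np.abs(m1) + 0.2)
    s2 = np.maximum(neg.std(axis=1, ddof=1), 0.2 * np.abs(m2) + 0.2)
    return pd.Series((m1 - m2) / (s1 + s2), index=expr.index)


def _running_es(weights_hit: np.ndarray, miss: np.ndarray) -> float:
    """Signed max-deviation of the weighted KS running sum (1-D)."""
    p_hit = np.cumsum(weights_hit) / weights_hit.sum()
    p_miss = np.cumsum(miss) / miss.sum()
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def _null_es(absr_pow: np.ndarray, set_size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES for random gene sets of the given size on the fixed ranking.

    Gene-label permutation is equivalent to drawing uniform random sets of
    the same size over the ranked list; fully vectorised.
    """
    n = len(absr_pow)
    # n_perm random index sets without replacement
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :set_size]
    hit = np.zeros((n_perm, n))
    rows = np.arange(n_perm)[:, None]
    hit[rows, idx] = absr_pow[idx]
    p_hit = np.cumsum(hit, axis=1) / hit.sum(axis=1, keepdims=True)
    miss = np.ones((n_perm, n))
    miss[rows, idx] = 0.0
    p_miss = np.cumsum(miss, axis=1) / (n - set_size)
    dev = p_hit - p_miss
    arg = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(n_perm), arg]


def gsea_two_group(expr: pd.DataFrame, labels, collection: dict,
                   n_perm: int = 1000, seed: int = 0, weight: float = 1.0,
                   positive_label=None) -> list[EnrichmentResult]:
    """Two-group permutation GSEA; one EnrichmentResult per usable set.

    ES uses weights |metric|^weight for in-set genes; p_perm is the plus-one
    permutation estimator (1 + #{|ES_null| >= |ES|}) / (n_perm + 1); NES is
    ES divided by the mean |null ES| of the same sign; p_adj is BH across
    sets.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must define exactly two groups")
    if positive_label is None:
        positive_label = uniq[1]
    metric = signal_to_noise(expr, labels, positive_label)
    if np.allclose(metric.to_numpy(), metric.to_numpy()[0]):
        raise ValueError("degenerate ranking: metric constant across genes")

    order = np.argsort(-metric.to_numpy(), kind="stable")
    genes = np.asarray(expr.index)[order]
    absr_pow = np.abs(metric.to_numpy()[order]) ** weight

    sets = restrict_to_matrix(collection, expr.index)
    rng = np.random.default_rng(seed)
    results = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        in_set = np.isin(genes, list(members))
        k = int(in_set.sum())
        es = _running_es(np.where(in_set, absr_pow, 0.0),
                         (~in_set).astype(float))
        if k not in null_cache:
            null_cache[k] = _null_es(absr_pow, k, n_perm, rng)
        null = null_cache[k]
        p_perm = (1 + int(np.sum(np.abs(null) >= abs(es)))) / (n_perm + 1)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
        nes = es / denom if denom > 0 else np.nan
        results.append((name, es, nes, p_perm))

    p_adj = multipletests([r[3] for r in results], method="fdr_bh")[1]
    return [EnrichmentResult(set_name=n_, es=e, nes=nes_, p_perm=pp,
                             p_adj=float(pa))
            for (n_, e, nes_, pp), pa in zip(results, p_adj)]


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{"set": r.set_name, "es": r.es, "nes": r.nes,
                          "p_perm": r.p_perm, "p_adj": r.p_adj}
                         for r in results])


# ---------------------------------------------------------------------------
# per-cancer correlation
# ---------------------------------------------------------------------------

def summarize_scores_by_cancer(scores: pd.DataFrame, sample_cancer
                               ) -> pd.DataFrame:
    """Mean ssGSEA score per (pathway, cancer type): cancers x pathways."""
    return scores.T.groupby(pd.Series(sample_cancer, index=scores.columns)).mean()


def correlate_ror_pathways(score_summary: pd.DataFrame, ror: pd.Series
                           ) -> pd.DataFrame:
    """Spearman rho of each pathway column against the per-cancer ROR vector.

    Average ranks for ties; two-sided p via the t-distribution approximation;
    cancers without an ROR (excluded strata) are dropped pairwise.  Requires
    at least 4 paired cancer types.
    """
    common = score_summary.index.intersection(ror.dropna().index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired cancer types")
    y = ror.loc[common].to_numpy(dtype=float)
    rows = []
    for pathway in score_summary.columns:
        x = score_summary.loc[common, pathway].to_numpy(dtype=float)
        rho, p = stats.spearmanr(x, y)
        rows.append({"pathway": pathway, "rho": float(rho), "p": float(p),
                     "n": len(common)})
    return pd.DataFrame(rows)
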