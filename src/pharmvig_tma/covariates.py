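"""Logistic covariate models for event occurrence.

Univariate (one factor at a time) and multivariate logistic regression of a
binary outcome on categorical risk factors, reporting odds ratios with Wald
confidence intervals — the standard pharmacovigilance presentation.  Fitting
is maximum likelihood (Newton scoring) via statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

#: reference levels matching the study's implicit choices
DEFAULT_REFERENCES = {"gender": "male", "age_band": "0-44",
                      "drug_class": "VEGFRi"}


@dataclass
class ModelFit:
    """A fitted logistic model for one factor (ULR) or all factors (MLR)."""

    coefficients: pd.Series
    standard_errors: pd.Series
    covariance: pd.DataFrame
    converged: bool
    n_obs: int
    reference_levels: dict[str, str]
    model: str = "ULR"            # "ULR" or "MLR"
    diagnostic: str = ""
    factors: list[str] = field(default_factory=list)


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation: the MLE does not exist."""


def _encode(design: pd.DataFrame, factors: list[str],
            references: dict[str, str]) -> pd.DataFrame:
    """Dummy-encode categorical factors, dropping each reference level."""
    cols = {}
    for f in factors:
        levels = pd.unique(design[f].astype(str))
        ref = references.get(f)
        if ref is None or ref not in levels:
            ref = sorted(levels)[0]
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{f}[{lev}]"] = (design[f].astype(str) == lev).astype(float)
    X = pd.DataFrame(cols, index=design.index)
    return sm.add_constant(X, has_constant="add")


def _fit_one(y: np.ndarray, X: pd.DataFrame, references, model_label,
             factors) -> ModelFit:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, maxiter=200,
                                     tol=1e-10)
        converged = bool(res.mle_retvals.get("converged", False))
        # blown-up SEs flag quasi-separation even when the optimizer "converged"
        if converged and (res.bse.max() > 1e3 or not np.isfinite(res.bse).all()):
            converged = False
            diag = "separation suspected: unbounded standard errors"
        else:
            diag = "" if converged else "maximum-likelihood iteration did not converge"
        return ModelFit(
            coefficients=res.params, standard_errors=res.bse,
            covariance=pd.DataFrame(res.cov_params(), index=res.params.index,
                                    columns=res.params.index),
            converged=converged, n_obs=int(res.nobs),
            reference_levels=dict(references), model=model_label,
            diagnostic=diag, factors=list(factors))
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        empty = pd.Series(dtype=float)
        return ModelFit(coefficients=empty, standard_errors=empty,
                        covariance=pd.DataFrame(), converged=False,
                        n_obs=len(y), reference_levels=dict(references),
                        model=model_label,
                        diagnostic=f"complete separation: {err}",
                        factors=list(factors))


def fit_logistic(outcome, design: pd.DataFrame, mode: str = "multivariate",
                 references: dict[str, str] | None = None):
    """Fit logistic regression of a 0/1 outcome on categorical factors.

    ``mode="univariate"`` returns ``{factor: ModelFit}`` with one single-factor
    model per column of ``design``; ``mode="multivariate"`` returns one
    ModelFit with all factors entered jointly.  Rows with missing outcome or
    factor values are dropped (complete-case analysis).
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y[~np.isnan(y)], [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    references = {**DEFAULT_REFERENCES, **(references or {})}
    factors = list(design.columns)

    keep = ~np.isnan(y)
    for f in factors:
        keep &= design[f].notna().to_numpy()
    y, design = y[keep], design.loc[keep]

    if mode == "univariate":
        fits = {}
        for f in factors:
            X = _encode(design, [f], references)
            fits[f] = _fit_one(y, X, references, "ULR", [f])
        return fits
    if mode == "multivariate":
        X = _encode(design, factors, references)
        return _fit_one(y, X, references, "MLR", factors)
    raise ValueError(f"unknown mode {mode!r}")


def odds_ratio_table(fits, alpha: float = 0.05) -> pd.DataFrame:
    """Per-level odds ratios exp(beta) with Wald CIs and two-sided p-values.

    Accepts a single ModelFit, a {factor: ModelFit} dict, or a list of either.
    Non-converged fits are rejected (their diagnostic is raised).
    """
    if isinstance(fits, ModelFit):
        fits = [fits]
    elif isinstance(fits, dict):
        fits = list(fits.values())
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for fit in fits:
        if not fit.converged:
            raise SeparationError(fit.diagnostic or "model did not converge")
        for term in fit.coefficients.index:
            if term == "const":
                continue
            factor, level = term.rstrip("]").split("[", 1)
            beta = fit.coefficients[term]
            se = fit.standard_errors[term]
            rows.append({
                "factor": factor, "level": level, "model": fit.model,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - z * se)),
                "ci_high": float(np.exp(beta + z * se)),
                "p": float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0,
            })
    return pd.DataFrame(rows)
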