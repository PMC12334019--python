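"""Questionnaire preprocessing: acquiescence, composites, reliability.

The target scale here is unbalanced (no reverse-keyed items), so a yea-saying
response style is confounded with trait content.  Following standard practice
the acquiescence score is computed on a separate, perfectly balanced inventory
as the mean of the *raw* (un-recoded) item responses minus the scale midpoint:
on a balanced scale trait content cancels and only the agreement tendency
remains.  Composites are then regression-adjusted for that score, and all
analysis variables are residualized for age and sex before twin modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class ScaleDefinition:
    """Scoring recipe for one subscale."""

    name: str
    item_ids: list[str]
    reverse_keyed: list[str] = field(default_factory=list)
    response_min: int = 1
    response_max: int = 5
    excluded_items: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.item_ids:
            raise PreprocessError(f"scale {self.name}: item_ids empty")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise PreprocessError(f"scale {self.name}: duplicate item ids")
        for sub, label in ((self.reverse_keyed, "reverse_keyed"),
                           (self.excluded_items, "excluded_items")):
            extra = set(sub) - set(self.item_ids)
            if extra:
                raise PreprocessError(
                    f"scale {self.name}: {label} not in item_ids: {extra}")

    @property
    def active_items(self) -> list[str]:
        return [i for i in self.item_ids if i not in self.excluded_items]

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.response_min + self.response_max)

    @property
    def is_balanced(self) -> bool:
        return 2 * len(self.reverse_keyed) == len(self.item_ids)


@dataclass
class ReliabilityResult:
    alpha: float
    n_items: int
    n_respondents: int


def _as_matrix(responses) -> np.ndarray:
    arr = np.asarray(responses, float)
    if arr.ndim != 2:
        raise PreprocessError("responses must be respondents x items")
    return arr


def acquiescence_score(responses, scale: ScaleDefinition) -> np.ndarray:
    """Per-respondent agreement bias from a balanced inventory.

    Mean of all raw item responses (no reverse-recoding) minus the scale
    midpoint; respondents with missing items are scored on the items they
    answered.  Only identified when keyed and reverse-keyed items balance,
    hence the hard error on unbalanced scales.
    """
    if not scale.is_balanced:
        raise PreprocessError(
            f"scale {scale.name} is not balanced; acquiescence is not "
            "identified (trait content does not cancel)")
    arr = _as_matrix(responses)
    _check_range(arr, scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.nanmean(arr, axis=1) - scale.midpoint


def _check_range(arr: np.ndarray, scale: ScaleDefinition) -> None:
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < scale.response_min
                        or finite.max() > scale.response_max):
        raise PreprocessError(
            f"scale {scale.name}: responses outside "
            f"[{scale.response_min}, {scale.response_max}]")


def adjust_for_acquiescence(composite, acq) -> tuple[np.ndarray, float]:
    """Regress a composite on the acquiescence score; z-score the residuals.

    Returns ``(z_residuals, adjusted_r2)``.  A constant acquiescence vector
    degenerates to plain z-scoring with ``r2_adj = 0`` (warning logged); a
    composite fully explained by acquiescence leaves nothing to standardize
    and raises.
    """
    y = np.asarray(composite, float).ravel()
    x = np.asarray(acq, float).ravel()
    if y.size != x.size:
        raise PreprocessError("composite and acquiescence lengths differ")
    mask = np.isfinite(y) & np.isfinite(x)
    if np.std(y[mask]) == 0:
        raise PreprocessError("composite is constant")
    if np.std(x[mask]) == 0:
        log.warning("acquiescence score constant; returning plain z-scores")
        resid = np.full_like(y, np.nan)
        resid[mask] = _zscore(y[mask])
        return resid, 0.0
    X = np.column_stack([np.ones(mask.sum()), x[mask]])
    beta, *_ = np.linalg.lstsq(X, y[mask], rcond=None)
    res = y[mask] - X @ beta
    n = mask.sum()
    ss_res = float(res @ res)
    ss_tot = float(((y[mask] - y[mask].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if np.std(res) < 1e-10 * np.std(y[mask]):
        raise PreprocessError("residuals constant after adjustment "
                              "(composite collinear with acquiescence)")
    out = np.full_like(y, np.nan)
    out[mask] = _zscore(res)
    return out, r2_adj


def composite_score(responses, scale: ScaleDefinition,
                    item_ids: list[str] | None = None) -> np.ndarray:
    """Mean of recoded, non-excluded items; NaN if under half answered.

    Reverse-keyed items are recoded as ``min + max - x`` before averaging.
    ``item_ids`` names the columns of ``responses`` (defaults to the scale's
    own ordering).
    """
    arr = _as_matrix(responses).copy()
    ids = list(item_ids) if item_ids is not None else list(scale.item_ids)
    if arr.shape[1] != len(ids):
        raise PreprocessError("responses width does not match item ids")
    _check_range(arr, scale)
    active = [i for i, iid in enumerate(ids) if iid in scale.active_items]
    if not active:
        raise PreprocessError(f"scale {scale.name}: all items excluded")
    for i, iid in enumerate(ids):
        if iid in scale.reverse_keyed:
            arr[:, i] = scale.response_min + scale.response_max - arr[:, i]
    sub = arr[:, active]
    answered = np.isfinite(sub).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = np.nanmean(sub, axis=1)
    score[answered * 2 < len(active)] = np.nan
    return score


def cronbach_alpha(responses, scale: ScaleDefinition,
                   item_ids: list[str] | None = None) -> ReliabilityResult:
    """Internal consistency over complete-case rows, items recoded first."""
    arr = _as_matrix(responses).copy()
    ids = list(item_ids) if item_ids is not None else list(scale.item_ids)
    for i, iid in enumerate(ids):
        if iid in scale.reverse_keyed:
            arr[:, i] = scale.response_min + scale.response_max - arr[:, i]
    active = [i for i, iid in enumerate(ids) if iid in scale.active_items]
    sub = arr[:, active]
    sub = sub[np.isfinite(sub).all(axis=1)]
    k = sub.shape[1]
    if k < 2:
        raise PreprocessError("Cronbach's alpha needs at least two items")
    total_var = sub.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise PreprocessError("zero total-score variance")
    item_vars = sub.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_vars / total_var)
    return ReliabilityResult(alpha=float(alpha), n_items=k,
                             n_respondents=sub.shape[0])


def residualize_age_sex(y, age, sex) -> np.ndarray:
    """OLS residuals of y on intercept + age + sex, z-standardized.

    Applied to every analysis variable before twin modelling so mean effects
    of the covariates cannot masquerade as shared environment.  Collinear
    covariate columns are dropped with a warning.
    """
    y = np.asarray(y, float).ravel()
    cols = [np.ones(y.size), np.asarray(age, float).ravel(),
            np.asarray(sex, float).ravel()]
    names = ["intercept", "age", "sex"]
    mask = np.isfinite(y)
    for c in cols:
        mask &= np.isfinite(c)
    if np.std(y[mask]) == 0:
        raise PreprocessError("y is constant")
    X = np.column_stack(cols)[mask]
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            log.warning("dropping collinear covariate %s", names[j])
    X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y[mask], rcond=None)
    res = y[mask] - X @ beta
    if np.std(res) < 1e-10 * np.std(y[mask]):
        raise PreprocessError("residuals constant (y lies in covariate span)")
    out = np.full_like(y, np.nan)
    out[mask] = _zscore(res)
    return out


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def preprocess_cohort(cohort_df: pd.DataFrame, scales: list[ScaleDefinition],
                      acquiescence_scale: ScaleDefinition | None = None,
                      item_prefix: str = "item_") -> pd.DataFrame:
    """Score every scale, optionally acquiescence-adjust, then residualize.

    Returns a copy of the cohort frame with one ``pheno_<scale>`` column per
    scale holding the fully preprocessed (adjusted, residualized,
    standardized) score.
    """
    df = cohort_df.copy()
    acq = None
    if acquiescence_scale is not None:
        cols = [f"{item_prefix}{i}" for i in acquiescence_scale.item_ids]
        acq = acquiescence_score(df[cols].to_numpy(float), acquiescence_scale)
    for scale in scales:
        cols = [f"{item_prefix}{i}" for i in scale.item_ids]
        comp = composite_score(df[cols].to_numpy(float), scale)
        if acq is not None:
            comp, _ = adjust_for_acquiescence(comp, acq)
        df[f"pheno_{scale.name}"] = residualize_age_sex(
            comp, df["age"], df["sex"])
    return df
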