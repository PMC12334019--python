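"""Phenotypic layer: correlations, clustered regression, FDR, facet selection.

Twins are not independent observations, so ordinary regression standard
errors are too small.  Each target dimension is regressed on all personality
facets plus age and sex with generalized estimating equations (GEE),
clustering on family and using the robust sandwich covariance; predictors
passing a stringent raw-p screen feed the downstream twin models.  Raw
p-values are additionally Benjamini-Hochberg adjusted within each model,
excluding the covariates from the family of tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

COVARIATES = ("age", "sex", "const", "Intercept")


class AssociationError(ValueError):
    pass


@dataclass
class AssocResult:
    """Per-predictor clustered-regression results for one target."""

    table: pd.DataFrame  # index: predictor; beta, robust_se, p_raw, p_fdr
    marginal_r2: float
    n_clusters: int
    n_obs: int
    target: str = ""
    fitted: np.ndarray = field(default=None, repr=False)
    dropped: list[str] = field(default_factory=list)

    def facet_rows(self) -> pd.DataFrame:
        keep = [ix for ix in self.table.index if ix not in COVARIATES]
        return self.table.loc[keep]


def pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n <= 3:
        raise AssociationError("need n > 3 for a Fisher-z interval")
    if abs(r) >= 1:
        raise AssociationError("|r| must be < 1")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def clustered_regression(y, X: pd.DataFrame, cluster,
                         working: str = "exchangeable",
                         standardize: bool = True,
                         fdr: bool = True) -> AssocResult:
    """GEE regression of y on X with family-clustered sandwich errors.

    ``X`` must not contain an intercept (one is added).  With
    ``standardize``, y and all non-binary predictors are z-scored first so
    coefficients are standardized betas; binary columns (e.g. sex) are left
    on their 0/1 scale.  Collinear columns are dropped with a log message.
    p-values are two-sided normal; the BH adjustment excludes ``age``/``sex``.
    """
    y = np.asarray(y, float).ravel()
    X = pd.DataFrame(X).copy()
    cluster = np.asarray(cluster)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy(float)).all(axis=1)
    y, X, cluster = y[mask], X.loc[mask], cluster[mask]
    if len(np.unique(cluster)) < 2:
        raise AssociationError("need at least two clusters")
    sizes = pd.Series(cluster).value_counts()
    if (sizes > 2).any():
        raise AssociationError("clusters larger than two are not twin data")

    dropped = []
    cols = list(X.columns)
    arr = X.to_numpy(float)
    keep_idx: list[int] = []
    for j in range(arr.shape[1]):
        trial = arr[:, keep_idx + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), trial])) \
                > len(keep_idx) + 1:
            keep_idx.append(j)
        else:
            dropped.append(cols[j])
            log.warning("dropping collinear predictor %s", cols[j])
    X = X.iloc[:, keep_idx]

    if standardize:
        y = (y - y.mean()) / y.std(ddof=0)
        for c in X.columns:
            v = X[c].to_numpy(float)
            if set(np.unique(v)) <= {0.0, 1.0}:
                continue
            X[c] = (v - v.mean()) / v.std(ddof=0)

    design = sm.add_constant(X, prepend=True)
    cov_struct = {"independence": sm.cov_struct.Independence,
                  "exchangeable": sm.cov_struct.Exchangeable}[working]()
    model = sm.GEE(y, design, groups=cluster,
                   family=sm.families.Gaussian(), cov_struct=cov_struct)
    res = model.fit()

    table = pd.DataFrame({
        "beta": res.params,
        "robust_se": res.bse,
        "p_raw": res.pvalues,
    })
    table = table.drop(index="const")
    facet_ix = [ix for ix in table.index if ix not in COVARIATES]
    table["p_fdr"] = np.nan
    if fdr and facet_ix:
        table.loc[facet_ix, "p_fdr"] = bh_fdr(
            table.loc[facet_ix, "p_raw"].to_numpy())
    fitted = np.asarray(res.fittedvalues, float)
    r2 = marginal_r2(fitted, y)
    return AssocResult(table=table, marginal_r2=r2,
                       n_clusters=len(np.unique(cluster)), n_obs=len(y),
                       fitted=fitted, dropped=dropped)


def marginal_r2(fitted, y) -> float:
    """Squared Pearson correlation between fitted values and observations."""
    fitted = np.asarray(fitted, float).ravel()
    y = np.asarray(y, float).ravel()
    if np.std(fitted) == 0:
        log.warning("constant fitted values; marginal R^2 set to 0")
        return 0.0
    return float(np.corrcoef(fitted, y)[0, 1] ** 2)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def select_facets(result: AssocResult, threshold: float = 0.01) -> list[str]:
    """Facets with raw p below the screening threshold, covariates excluded.

    An empty selection means the downstream twin model for this target is
    skipped (warning logged).
    """
    rows = result.facet_rows()
    selected = [ix for ix in rows.index if rows.loc[ix, "p_raw"] < threshold]
    if not selected:
        log.warning("no facet passes p < %g for target %s; "
                    "twin model will be skipped", threshold, result.target)
    log.info("selected %d facets at p < %g: %s",
             len(selected), threshold, selected)
    return selected


def correlation_subsample(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """One member per family for unbiased phenotypic correlations.

    Deterministic rule: keep twin_order 1 (plus all unpaired responders,
    who are already single).
    """
    return cohort_df[cohort_df["twin_order"] == 1].reset_index(drop=True)


def correlation_matrix(df: pd.DataFrame, columns: list[str],
                       level: float = 0.95) -> pd.DataFrame:
    """Long-format pairwise Pearson correlations with Fisher-z intervals."""
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            sub = df[[a, b]].dropna()
            n = len(sub)
            r = float(sub[a].corr(sub[b]))
            lo, hi = pearson_ci(r, n, level)
            t = r * np.sqrt((n - 2) / max(1e-300, 1 - r ** 2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            rows.append({"var1": a, "var2": b, "r": r, "n": n,
                         "ci_lower": lo, "ci_upper": hi, "p": p})
    return pd.DataFrame(rows)
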