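"""Likelihood engine for the classical twin design.

The model: for ``p`` traits, each twin pair's 2p observation vector is
multivariate normal with within-twin covariance ``A + C + E`` and cross-twin
covariance ``A + C`` (MZ) or ``0.5 A + C`` (DZ), where A, C and E are the
additive-genetic, shared-environment and unique-environment covariance
contributions.  Estimation is full-information maximum likelihood: complete
pairs use the 2p-variate density, unpaired responders the p-variate marginal,
and per-record missing entries drop the corresponding rows/columns.  Records
sharing a missingness pattern are collapsed to sufficient statistics (count,
mean, scatter), which is algebraically identical to record-wise evaluation
and much faster.

Two parameterizations are supported: ``cholesky`` (components are L Lᵀ, PSD
by construction) and ``direct`` (unconstrained symmetric matrices, so
negative variance estimates are possible, as in the direct-variance-component
approach).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
from scipy import stats

from .cohort import PHENO_PREFIX, TwinCohort

log = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))
#: -2LL returned when the implied covariance is not positive-definite
PENALTY = 1e10
COMPONENT_ORDER = ("A", "C", "E")


class BiometricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class BiometricParamsFit:
    """Parameter state of a biometric model.

    ``matrices`` maps each included component to its raw parameter matrix:
    a lower-triangular Cholesky factor under ``parameterization='cholesky'``
    or a symmetric matrix under ``'direct'``.
    """

    parameterization: str
    matrices: dict[str, np.ndarray]
    means: np.ndarray
    trait_names: list[str]

    def component(self, name: str) -> np.ndarray:
        """Implied covariance contribution of one component (zero if absent)."""
        p = len(self.trait_names)
        if name not in self.matrices:
            return np.zeros((p, p))
        m = self.matrices[name]
        if self.parameterization == "cholesky":
            return m @ m.T
        return 0.5 * (m + m.T)

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(c for c in COMPONENT_ORDER if c in self.matrices)

    def total_covariance(self) -> np.ndarray:
        return sum(self.component(c) for c in COMPONENT_ORDER)


@dataclass
class ModelFit:
    """A fitted biometric model with fit statistics and diagnostics."""

    params: BiometricParamsFit
    minus2LL: float
    n_params: int
    aic: float
    standardized: dict[str, np.ndarray]
    converged: bool
    n_pairs_used: dict[str, int]
    n_singles_used: int
    label: str = ""
    ci: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    data: "FimlData | None" = field(default=None, repr=False)
    config: dict = field(default_factory=dict, repr=False)

    @property
    def fingerprint(self) -> str:
        return self.data.fingerprint if self.data is not None else ""


@dataclass
class IntraclassResult:
    r: float
    se: float
    n_pairs: int
    zygosity: str


@dataclass
class ComparisonResult:
    delta_minus2LL: float
    delta_df: int
    p_value: float
    delta_aic: float
    preferred: str
    full_label: str = ""
    nested_label: str = ""


@dataclass
class HeuristicFlags:
    A_suggested: bool
    C_suggested: bool
    D_suggested: bool
    E_included: bool = True


# ---------------------------------------------------------------------------
# expected covariance structure
# ---------------------------------------------------------------------------

def expected_pair_covariance(params: BiometricParamsFit,
                             zygosity: str) -> np.ndarray:
    """Implied 2p x 2p covariance for a twin pair of the given zygosity."""
    if zygosity not in ("MZ", "DZ"):
        raise BiometricError(f"unknown zygosity {zygosity!r}")
    A, C, E = (params.component(c) for c in COMPONENT_ORDER)
    within = A + C + E
    rho = 1.0 if zygosity == "MZ" else 0.5
    cross = rho * A + C
    return np.block([[within, cross], [cross, within]])


# ---------------------------------------------------------------------------
# FIML data: sufficient statistics per (group, missingness pattern)
# ---------------------------------------------------------------------------

@dataclass
class _PatternStats:
    idx: np.ndarray      # observed column indices
    n: int
    mean: np.ndarray
    scatter: np.ndarray  # sum over records of (x - mean)(x - mean)^T


def _pattern_stats(arr: np.ndarray) -> list[_PatternStats]:
    out: list[_PatternStats] = []
    if arr.size == 0:
        return out
    finite = np.isfinite(arr)
    arr = arr[finite.any(axis=1)]
    finite = np.isfinite(arr)
    keys = [tuple(row) for row in finite]
    df = pd.DataFrame({"key": keys})
    for key, grp in df.groupby("key", sort=False):
        idx = np.flatnonzero(np.array(key))
        sub = arr[np.ix_(grp.index.to_numpy(), idx)]
        mean = sub.mean(axis=0)
        dev = sub - mean
        out.append(_PatternStats(idx=idx, n=sub.shape[0], mean=mean,
                                 scatter=dev.T @ dev))
    return out


class FimlData:
    """Precomputed sufficient statistics for repeated likelihood evaluation."""

    def __init__(self, cohort: TwinCohort, traits: list[str] | None = None,
                 include_singles: bool = True):
        if traits is None:
            traits = cohort.phenotype_names
        if not traits:
            raise BiometricError("cohort has no phenotype columns")
        arrays = cohort.to_arrays(traits)
        if not include_singles:
            arrays["single"] = arrays["single"][:0]
        self.traits = list(traits)
        self.p = len(traits)
        self.include_singles = include_singles
        self.stats = {g: _pattern_stats(arrays[g])
                      for g in ("MZ", "DZ", "single")}
        self.n_pairs = {z: int(np.isfinite(arrays[z]).any(axis=1).sum())
                        for z in ("MZ", "DZ")}
        self.n_singles = int(np.isfinite(arrays["single"]).any(axis=1).sum())
        self.n_obs = sum(st.n * st.idx.size
                         for group in self.stats.values() for st in group)
        h = hashlib.sha256()
        for g in ("MZ", "DZ", "single"):
            a = np.ascontiguousarray(np.sort(arrays[g], axis=0) if len(arrays[g])
                                     else arrays[g])
            h.update(str(a.shape).encode())
            h.update(np.nan_to_num(a, nan=-9e99).tobytes())
        self.fingerprint = h.hexdigest()


def _stats_m2ll(stats_list: list[_PatternStats], sigma: np.ndarray,
                mu: np.ndarray) -> float | None:
    total = 0.0
    for st in stats_list:
        sub = sigma[np.ix_(st.idx, st.idx)]
        try:
            cf = sla.cho_factor(sub, lower=True, check_finite=False)
        except sla.LinAlgError:
            return None
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        d = st.mean - mu[st.idx]
        m = st.scatter + st.n * np.outer(d, d)
        quad = float(np.trace(sla.cho_solve(cf, m, check_finite=False)))
        total += st.n * (st.idx.size * LOG2PI + logdet) + quad
    return total


def _m2ll_from_data(params: BiometricParamsFit, data: FimlData) -> float:
    mu = np.asarray(params.means, float)
    mu_pair = np.concatenate([mu, mu])
    total = 0.0
    for zyg in ("MZ", "DZ"):
        if data.stats[zyg]:
            sigma = expected_pair_covariance(params, zyg)
            val = _stats_m2ll(data.stats[zyg], sigma, mu_pair)
            if val is None:
                return _penalized(sigma)
            total += val
    if data.stats["single"]:
        sigma = params.total_covariance()
        val = _stats_m2ll(data.stats["single"], sigma, mu)
        if val is None:
            return _penalized(sigma)
        total += val
    return total


def _penalized(sigma: np.ndarray) -> float:
    mineig = float(np.linalg.eigvalsh(0.5 * (sigma + sigma.T)).min())
    return PENALTY * (1.0 + max(0.0, -mineig))


def fiml_minus2LL(params: BiometricParamsFit,
                  cohort: TwinCohort | FimlData,
                  traits: list[str] | None = None,
                  include_singles: bool = True) -> float:
    """-2 log-likelihood of the cohort under the implied twin structure.

    Singular implied covariances yield a large penalized value rather than an
    exception, so optimizers can back out of the infeasible region.
    """
    data = (cohort if isinstance(cohort, FimlData)
            else FimlData(cohort, traits, include_singles))
    if data.n_obs == 0:
        raise BiometricError("no observed phenotype values")
    return _m2ll_from_data(params, data)


# ---------------------------------------------------------------------------
# free-parameter layout
# ---------------------------------------------------------------------------

class _Layout:
    """Maps between a flat free-parameter vector and BiometricParamsFit."""

    def __init__(self, p: int, components: tuple[str, ...],
                 parameterization: str, trait_names: list[str],
                 free_means: bool = True):
        self.p = p
        self.components = tuple(c for c in COMPONENT_ORDER if c in components)
        self.parameterization = parameterization
        self.trait_names = list(trait_names)
        self.free_means = free_means
        self.tril = np.tril_indices(p)
        self.ntri = p * (p + 1) // 2
        self.n_free = self.ntri * len(self.components) + (p if free_means else 0)

    def unpack(self, vec: np.ndarray,
               means: np.ndarray | None = None) -> BiometricParamsFit:
        vec = np.asarray(vec, float)
        mats = {}
        off = 0
        for c in self.components:
            m = np.zeros((self.p, self.p))
            m[self.tril] = vec[off:off + self.ntri]
            if self.parameterization == "direct":
                m = m + np.tril(m, -1).T
            mats[c] = m
            off += self.ntri
        if self.free_means:
            mu = vec[off:off + self.p]
        else:
            mu = np.zeros(self.p) if means is None else np.asarray(means, float)
        return BiometricParamsFit(self.parameterization, mats, mu,
                                  self.trait_names)

    def pack(self, params: BiometricParamsFit) -> np.ndarray:
        parts = [params.matrices[c][self.tril] for c in self.components]
        if self.free_means:
            parts.append(np.asarray(params.means, float))
        return np.concatenate(parts)


def _start_params(data: FimlData, layout: _Layout) -> np.ndarray:
    """Phenotypic-covariance-based start: split the sample covariance evenly
    across the included components."""
    p = data.p
    # pooled individual-level moments from the pattern statistics
    total_n = np.zeros(p)
    total_sum = np.zeros(p)
    total_sq = np.zeros((p, p))
    for group, stats_list in data.stats.items():
        width = 2 * p if group in ("MZ", "DZ") else p
        for st in stats_list:
            m = np.zeros(width)
            m[st.idx] = st.mean
            sc = np.zeros((width, width))
            sc[np.ix_(st.idx, st.idx)] = st.scatter + st.n * np.outer(st.mean, st.mean)
            cnt = np.zeros(width)
            cnt[st.idx] = st.n
            for blk in range(width // p):
                sl = slice(blk * p, (blk + 1) * p)
                total_n += cnt[sl]
                total_sum += st.n * m[sl]
                total_sq += sc[sl, sl]
    total_n = np.maximum(total_n, 1)
    mean = total_sum / total_n
    cov = total_sq / total_n[:, None] - np.outer(mean, mean)
    cov = 0.5 * (cov + cov.T) + 1e-6 * np.eye(p)
    share = cov / len(layout.components)
    mats = {}
    for c in layout.components:
        if layout.parameterization == "cholesky":
            mats[c] = np.linalg.cholesky(share)
        else:
            mats[c] = share.copy()
    params = BiometricParamsFit(layout.parameterization, mats, mean,
                                layout.trait_names)
    return layout.pack(params)


def fit_biometric(cohort: TwinCohort | FimlData,
                  components=("A", "E"),
                  parameterization: str = "cholesky",
                  n_starts: int = 5,
                  seed: int = 0,
                  traits: list[str] | None = None,
                  include_singles: bool = True,
                  free_means: bool = True) -> ModelFit:
    """Fit an ACE-family model by FIML with multi-start quasi-Newton search.

    ``components`` must contain ``E``; models including A or C require both
    zygosity groups (otherwise the contrast identifying them is absent).
    Starting values split the pooled phenotypic covariance evenly across
    components; subsequent starts are multiplicatively jittered.  The fit is
    flagged converged when the best gradient is small and, with multiple
    starts, the best two objective values agree within 0.01.
    """
    components = tuple(c for c in COMPONENT_ORDER if c in components)
    if "E" not in components:
        raise BiometricError("E must always be included")
    data = (cohort if isinstance(cohort, FimlData)
            else FimlData(cohort, traits, include_singles))
    if ("A" in components or "C" in components) and (
            data.n_pairs["MZ"] == 0 or data.n_pairs["DZ"] == 0):
        raise BiometricError(
            "A/C are unidentified without both MZ and DZ pairs")
    layout = _Layout(data.p, components, parameterization, data.traits,
                     free_means)

    def objective(vec: np.ndarray) -> float:
        return _m2ll_from_data(layout.unpack(vec), data)

    x0 = _start_params(data, layout)
    rng = np.random.default_rng(seed)
    results = []
    for s in range(max(1, n_starts)):
        x = x0 if s == 0 else x0 * (1 + 0.2 * rng.standard_normal(x0.size)) \
            + 0.05 * rng.standard_normal(x0.size)
        try:
            res = opt.minimize(objective, x, method="L-BFGS-B",
                               options={"maxiter": 2000, "maxfun": 200000,
                                        "ftol": 1e-12, "gtol": 1e-7})
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("start %d failed: %s", s, exc)
            continue
        results.append(res)
    if not results:
        raise BiometricError("all optimization starts failed")
    results.sort(key=lambda r: r.fun)
    best = results[0]
    grad_ok = float(np.abs(best.jac).max()) < 1e-3 * max(1.0, abs(best.fun)) ** 0.5
    starts_ok = (len(results) < 2
                 or results[1].fun - results[0].fun < 0.01
                 or not np.isfinite(results[1].fun))
    converged = bool(best.fun < PENALTY and grad_ok and starts_ok)
    params = layout.unpack(best.x)
    n_params = layout.n_free
    m2ll = float(best.fun)
    try:
        standardized = standardize_components(params)
    except BiometricError:
        standardized = {}
    fit = ModelFit(params=params, minus2LL=m2ll, n_params=n_params,
                   aic=m2ll + 2 * n_params, standardized=standardized,
                   converged=converged, n_pairs_used=dict(data.n_pairs),
                   n_singles_used=data.n_singles,
                   label="".join(components),
                   diagnostics={"grad_max": float(np.abs(best.jac).max()),
                                "n_starts": len(results),
                                "best_two_gap": (results[1].fun - results[0].fun
                                                 if len(results) > 1 else 0.0)},
                   data=data,
                   config={"components": components,
                           "parameterization": parameterization,
                           "free_means": free_means})
    return fit


def standardize_components(params: BiometricParamsFit) -> dict[str, np.ndarray]:
    """Per-trait variance shares: X_tt / (A_tt + C_tt + E_tt).

    Under the direct parameterization, estimates may lie outside [0, 1]; they
    are reported as-is (with a warning) rather than truncated.
    """
    total = np.diag(params.total_covariance())
    if np.any(total <= 0):
        raise BiometricError("nonpositive total variance; shares undefined")
    shares = {c: np.diag(params.component(c)) / total
              for c in params.components}
    if any(np.any((s < -1e-12) | (s > 1 + 1e-12)) for s in shares.values()):
        log.warning("standardized shares outside [0, 1] "
                    "(direct parameterization can yield these)")
    return shares


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def share_quantity(component: str, trait: int = 0):
    """Standardized variance share of one component for one trait."""
    def g(params: BiometricParamsFit) -> float:
        total = np.diag(params.total_covariance())[trait]
        return float(np.diag(params.component(component))[trait] / total)
    g.search_bounds = (0.0, 1.0)
    g.__name__ = f"{component.lower()}2[{trait}]"
    return g


def corr_quantity(component: str, i: int, j: int):
    """Component correlation r_X[i, j] = X_ij / sqrt(X_ii X_jj)."""
    def g(params: BiometricParamsFit) -> float:
        x = params.component(component)
        denom = x[i, i] * x[j, j]
        if denom <= 0:
            return np.nan
        return float(x[i, j] / np.sqrt(denom))
    g.search_bounds = (-1.0, 1.0)
    g.__name__ = f"r{component}[{i},{j}]"
    return g


def _refit_machinery(fit: ModelFit):
    if fit.data is None or not fit.config:
        raise BiometricError("fit lacks attached data; cannot profile")
    layout = _Layout(fit.data.p, fit.config["components"],
                     fit.config["parameterization"], fit.data.traits,
                     fit.config["free_means"])
    data = fit.data

    def objective(vec):
        return _m2ll_from_data(layout.unpack(vec), data)

    return layout, objective


def wald_se(fit: ModelFit, quantity) -> float:
    """Delta-method standard error from the numerical Hessian of -2LL."""
    layout, objective = _refit_machinery(fit)
    x = layout.pack(fit.params)
    h = 1e-4 * np.maximum(np.abs(x), 1.0)
    n = x.size
    hess = np.empty((n, n))
    f0 = objective(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = h[i], h[j]
            if i == j:
                fp = objective(_bump(x, [(i, xi)]))
                fm = objective(_bump(x, [(i, -xi)]))
                hess[i, i] = (fp - 2 * f0 + fm) / xi ** 2
            else:
                fpp = objective(_bump(x, [(i, xi), (j, xj)]))
                fpm = objective(_bump(x, [(i, xi), (j, -xj)]))
                fmp = objective(_bump(x, [(i, -xi), (j, xj)]))
                fmm = objective(_bump(x, [(i, -xi), (j, -xj)]))
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * xi * xj)
    cov = 2.0 * np.linalg.pinv(hess)  # -2LL Hessian = 2 * information
    grad = np.empty(n)
    for i in range(n):
        gp = quantity(layout.unpack(_bump(x, [(i, h[i])])))
        gm = quantity(layout.unpack(_bump(x, [(i, -h[i])])))
        grad[i] = (gp - gm) / (2 * h[i])
    var = float(grad @ cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def _bump(x, deltas):
    y = x.copy()
    for i, d in deltas:
        y[i] += d
    return y


def profile_ci(fit: ModelFit, quantity, level: float = 0.95,
               tol: float = 1e-4) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a scalar quantity.

    The bound is the value of the quantity at which the re-optimized -2LL
    rises above the minimum by the chi-square(1) critical value (3.841 at
    95%), located by bracketing and bisection.  If the critical rise is not
    reached inside the quantity's natural search window, the bound is
    returned at the window edge and flagged open in ``fit.ci``.  Falls back
    to a Wald interval if the constrained re-optimization fails throughout.
    """
    if not fit.converged:
        log.warning("profiling a non-converged fit")
    layout, objective = _refit_machinery(fit)
    x_hat = layout.pack(fit.params)
    f0 = fit.minus2LL
    crit = stats.chi2.ppf(level, 1)
    v0 = quantity(fit.params)
    lo_win, hi_win = getattr(quantity, "search_bounds", (-np.inf, np.inf))
    if not np.isfinite(lo_win):
        lo_win = v0 - 50 * (abs(v0) + 1)
    if not np.isfinite(hi_win):
        hi_win = v0 + 50 * (abs(v0) + 1)

    def profiled(v: float, x_start: np.ndarray) -> tuple[float, np.ndarray]:
        cons = [{"type": "eq",
                 "fun": lambda th: quantity(layout.unpack(th)) - v}]
        res = opt.minimize(objective, x_start, method="SLSQP",
                           constraints=cons,
                           options={"maxiter": 300, "ftol": 1e-10})
        return float(res.fun), res.x

    flags = {}
    bounds = []
    for direction, window in ((-1.0, lo_win), (1.0, hi_win)):
        step = max(0.25 * abs(hi_win - lo_win) / 10, 0.02)
        inner_v, inner_x = v0, x_hat
        outer_v = None
        v = v0
        ok = True
        for _ in range(40):
            v = v + direction * step
            if (direction < 0 and v <= window) or (direction > 0 and v >= window):
                v = window + direction * (-1e-9)
            try:
                fv, xv = profiled(v, inner_x)
            except Exception:
                ok = False
                break
            if fv >= PENALTY:
                # infeasible; treat as beyond the bound
                outer_v = v
                break
            if fv - f0 > crit:
                outer_v = v
                break
            inner_v, inner_x = v, xv
            if abs(v - window) < 1e-9:
                break
            step *= 1.6
        if not ok:
            se = wald_se(fit, quantity)
            log.warning("profiling failed; Wald fallback")
            z = stats.norm.ppf(0.5 + level / 2)
            return (v0 - z * se, v0 + z * se)
        if outer_v is None:
            bounds.append(window)
            flags["lower_open" if direction < 0 else "upper_open"] = True
            continue
        lo_b, hi_b = sorted((inner_v, outer_v))
        while hi_b - lo_b > tol:
            mid = 0.5 * (lo_b + hi_b)
            fv, xv = profiled(mid, inner_x)
            if fv - f0 > crit:
                if direction < 0:
                    lo_b = mid
                else:
                    hi_b = mid
            else:
                inner_x = xv
                if direction < 0:
                    hi_b = mid
                else:
                    lo_b = mid
        bounds.append(0.5 * (lo_b + hi_b))
    lower, upper = bounds[0], bounds[1]
    fit.ci[getattr(quantity, "__name__", repr(quantity))] = {
        "lower": lower, "upper": upper, "level": level, **flags}
    return lower, upper


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(full: ModelFit, nested: ModelFit) -> ComparisonResult:
    """Likelihood-ratio comparison of a nested model against the full model."""
    if full.fingerprint and nested.fingerprint \
            and full.fingerprint != nested.fingerprint:
        raise BiometricError("fits are not on the same cohort")
    if nested.n_params >= full.n_params:
        raise BiometricError("nested model must have fewer parameters")
    delta = nested.minus2LL - full.minus2LL
    if delta < 0:
        if delta < -0.01:
            log.warning("nested model fits better by %.4f -2LL units "
                        "(optimizer noise); clipping to 0", -delta)
        delta = 0.0
    ddf = full.n_params - nested.n_params
    p = float(stats.chi2.sf(delta, ddf)) if delta > 0 else 1.0
    delta_aic = nested.aic - full.aic
    preferred = nested.label if p >= 0.05 else full.label
    return ComparisonResult(delta_minus2LL=float(delta), delta_df=ddf,
                            p_value=p, delta_aic=float(delta_aic),
                            preferred=preferred, full_label=full.label,
                            nested_label=nested.label)


# ---------------------------------------------------------------------------
# saturated-model assumption tests
# ---------------------------------------------------------------------------

class _SaturatedLayout:
    """Free-parameter layout for the saturated chain on complete pairs.

    Mean structure: ``free`` (2p per zygosity), ``pair`` (equal within pair;
    p per zygosity) or ``zyg`` (also equal across zygosity; p total).
    Variance structure: ``free`` or ``equal`` (diagonal tied across twin
    order and zygosity; off-diagonal covariances stay free per group).
    Covariances are parameterized directly; non-PD states are penalized.
    """

    def __init__(self, p: int, mean_structure: str, var_structure: str):
        self.p = p
        self.mean_structure = mean_structure
        self.var_structure = var_structure
        k = 2 * p
        self.k = k
        self.offdiag = [(i, j) for i in range(k) for j in range(i)]
        self.n_mean = {"free": 2 * k, "pair": 2 * p, "zyg": p}[mean_structure]
        n_var = {"free": 2 * k, "equal": p}[var_structure]
        self.n_free = self.n_mean + n_var + 2 * len(self.offdiag)

    def unpack(self, vec: np.ndarray):
        p, k = self.p, self.k
        off = 0
        means = {}
        if self.mean_structure == "free":
            for z in ("MZ", "DZ"):
                means[z] = vec[off:off + k]
                off += k
        elif self.mean_structure == "pair":
            for z in ("MZ", "DZ"):
                means[z] = np.tile(vec[off:off + p], 2)
                off += p
        else:
            mu = np.tile(vec[off:off + p], 2)
            off += p
            means = {"MZ": mu, "DZ": mu}
        covs = {}
        if self.var_structure == "free":
            diags = {}
            for z in ("MZ", "DZ"):
                diags[z] = vec[off:off + k]
                off += k
        else:
            d = np.tile(vec[off:off + p], 2)
            diags = {"MZ": d, "DZ": d}
            off += p
        for z in ("MZ", "DZ"):
            m = np.zeros((k, k))
            for (i, j) in self.offdiag:
                m[i, j] = m[j, i] = vec[off]
                off += 1
            np.fill_diagonal(m, diags[z])
            covs[z] = m
        return means, covs

    def start(self, stats_by_zyg) -> np.ndarray:
        p, k = self.p, self.k
        means_emp, covs_emp = {}, {}
        for z in ("MZ", "DZ"):
            st = stats_by_zyg[z][0]
            means_emp[z] = st.mean
            covs_emp[z] = st.scatter / st.n + 1e-6 * np.eye(k)
        parts = []
        if self.mean_structure == "free":
            parts += [means_emp["MZ"], means_emp["DZ"]]
        elif self.mean_structure == "pair":
            parts += [0.5 * (means_emp[z][:p] + means_emp[z][p:])
                      for z in ("MZ", "DZ")]
        else:
            pooled = 0.25 * sum(means_emp[z][:p] + means_emp[z][p:]
                                for z in ("MZ", "DZ"))
            parts.append(pooled)
        if self.var_structure == "free":
            parts += [np.diag(covs_emp["MZ"]), np.diag(covs_emp["DZ"])]
        else:
            pooled = 0.25 * sum(np.diag(covs_emp[z])[:p]
                                + np.diag(covs_emp[z])[p:] for z in ("MZ", "DZ"))
            parts.append(pooled)
        for z in ("MZ", "DZ"):
            parts.append(np.array([covs_emp[z][i, j] for i, j in self.offdiag]))
        return np.concatenate(parts)


def _fit_saturated(data: FimlData, mean_structure: str, var_structure: str,
                   label: str) -> ModelFit:
    pair_stats = {z: data.stats[z] for z in ("MZ", "DZ")}
    for z in ("MZ", "DZ"):
        if len(pair_stats[z]) != 1 or pair_stats[z][0].idx.size != 2 * data.p:
            raise BiometricError(
                "assumption tests require complete pairs in both groups")
    layout = _SaturatedLayout(data.p, mean_structure, var_structure)

    def objective(vec):
        means, covs = layout.unpack(vec)
        total = 0.0
        for z in ("MZ", "DZ"):
            val = _stats_m2ll(pair_stats[z], covs[z], means[z])
            if val is None:
                return _penalized(covs[z])
            total += val
        return total

    x0 = layout.start(pair_stats)
    res = opt.minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": 5000, "maxfun": 500000,
                                "ftol": 1e-13, "gtol": 1e-8})
    m2ll = float(res.fun)
    params = BiometricParamsFit("direct", {}, np.zeros(data.p), data.traits)
    return ModelFit(params=params, minus2LL=m2ll, n_params=layout.n_free,
                    aic=m2ll + 2 * layout.n_free, standardized={},
                    converged=bool(res.fun < PENALTY),
                    n_pairs_used=dict(data.n_pairs), n_singles_used=0,
                    label=label, data=data, config={})


def assumption_tests(cohort: TwinCohort | FimlData,
                     traits: list[str] | None = None) -> list[ComparisonResult]:
    """Likelihood-ratio tests of the classical twin-design assumptions.

    Fits the saturated two-group model (free means and covariances per
    zygosity on complete pairs), then the constraint chain -- means equal
    within pairs, means also equal across zygosity, variances equal within
    pairs and across zygosity -- comparing each constrained model to the
    saturated one.
    """
    data = (cohort if isinstance(cohort, FimlData)
            else FimlData(cohort, traits, include_singles=False))
    saturated = _fit_saturated(data, "free", "free", "saturated")
    chain = [("pair", "free", "equal means within pairs"),
             ("zyg", "free", "equal means across zygosity"),
             ("zyg", "equal", "equal variances")]
    out = []
    for mean_s, var_s, label in chain:
        fit = _fit_saturated(data, mean_s, var_s, label)
        out.append(compare_models(saturated, fit))
    return out


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def intraclass_corr(cohort: TwinCohort, trait: str,
                    zygosity: str) -> IntraclassResult:
    """Twin correlation (Pearson over complete pairs) with analytic SE.

    ``se = (1 - r^2) / sqrt(n_pairs - 1)``.
    """
    wide = cohort.complete_pairs(zygosity=zygosity)
    col = PHENO_PREFIX + trait
    pairs = wide[[f"{col}_1", f"{col}_2"]].dropna()
    n = len(pairs)
    if n < 3:
        raise BiometricError(f"fewer than 3 complete {zygosity} pairs")
    r = float(np.corrcoef(pairs.iloc[:, 0], pairs.iloc[:, 1])[0, 1])
    se = (1.0 - r ** 2) / np.sqrt(n - 1)
    return IntraclassResult(r=r, se=float(se), n_pairs=n, zygosity=zygosity)


def heuristic_components(r_mz: float, r_dz: float) -> HeuristicFlags:
    """Correlation-pattern heuristic for which components to entertain.

    A if rMZ > rDZ; C if rMZ < 2 rDZ; D (dominance; flagged only, never
    fitted here) if rMZ > 2 rDZ.  Both comparisons strict, so an exact 2:1
    ratio suggests neither C nor D.
    """
    return HeuristicFlags(A_suggested=r_mz > r_dz,
                          C_suggested=r_mz < 2 * r_dz,
                          D_suggested=r_mz > 2 * r_dz)


# ---------------------------------------------------------------------------
# noiseless moment-matched cohorts (oracle inputs for recovery tests)
# ---------------------------------------------------------------------------

def moment_matched_cohort(params: BiometricParamsFit, n_mz: int, n_dz: int,
                          seed: int = 0) -> TwinCohort:
    """A cohort whose group sample moments equal the implied moments exactly.

    Draws are empirically whitened and recoloured so that, in each zygosity
    group, the sample mean equals the model mean and the ML (1/n) sample
    covariance equals the implied pair covariance.  On such data the FIML
    optimum coincides with the generating parameters, which makes this the
    oracle input for noiseless recovery tests.
    """
    rng = np.random.default_rng(seed)
    p = len(params.trait_names)
    frames = []
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        k = 2 * p
        if n <= k:
            raise BiometricError("need more pairs than 2*p for moment matching")
        sigma = expected_pair_covariance(params, zyg)
        x = rng.standard_normal((n, k))
        xc = x - x.mean(axis=0)
        s = xc.T @ xc / n
        w = np.linalg.cholesky(s)
        target = np.linalg.cholesky(sigma)
        y = xc @ np.linalg.inv(w).T @ target.T + np.concatenate(
            [params.means, params.means])
        for order in (1, 2):
            block = y[:, (order - 1) * p: order * p]
            frames.append(pd.DataFrame({
                "family_id": [f"{zyg}{i:06d}" for i in range(n)],
                "zygosity": zyg, "twin_order": order,
                "sex": 0, "age": 43.0,
            } | {PHENO_PREFIX + t: block[:, j]
                 for j, t in enumerate(params.trait_names)}))
    return TwinCohort(pd.concat(frames, ignore_index=True),
                      meta={"moment_matched": True, "seed": int(seed)})
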