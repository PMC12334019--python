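"""Multivariate structure on top of the twin likelihood engine.

Genetic (rA) and unique-environmental (rE) correlations are read off the
fitted component covariance matrices.  The ordered Cholesky model enters
predictor traits (e.g. personality facets, strongest regression coefficient
first) before a target trait; the target's variance then splits into the part
flowing through paths from its predecessors ("shared") and the part carried
by its own residual path ("unique"), separately for the genetic and
environmental components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .biometric import (BiometricError, FimlData, ModelFit, corr_quantity,
                        fit_biometric, profile_ci)
from .cohort import TwinCohort

log = logging.getLogger(__name__)


@dataclass
class DecompositionResult:
    """Shared-vs-unique decomposition of the last trait in an ordered Cholesky."""

    ordering: list[str]
    rA: np.ndarray
    rE: np.ndarray
    target_total_a2: float
    target_total_e2: float
    shared_a_fraction: float
    shared_e_fraction: float
    fit: ModelFit = field(repr=False, default=None)
    rA_ci: dict = field(default_factory=dict)
    rE_ci: dict = field(default_factory=dict)

    @property
    def unique_a_fraction(self) -> float:
        return 1.0 - self.shared_a_fraction

    @property
    def unique_e_fraction(self) -> float:
        return 1.0 - self.shared_e_fraction


def component_correlations(params_or_fit, component: str) -> np.ndarray:
    """Correlation matrix implied by one component's covariance matrix.

    Cells with a nonpositive diagonal are flagged NaN rather than fabricated.
    """
    params = getattr(params_or_fit, "params", params_or_fit)
    x = params.component(component)
    d = np.diag(x).copy()
    bad = d <= 0
    if bad.any():
        log.warning("component %s has nonpositive variances for traits %s",
                    component, list(np.flatnonzero(bad)))
    d_safe = np.where(bad, np.nan, d)
    r = x / np.sqrt(np.outer(d_safe, d_safe))
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    return r


def genetic_env_correlations(fit: ModelFit, compute_ci: bool = False,
                             level: float = 0.95):
    """rA and rE matrices from a multivariate fit including A and E.

    With ``compute_ci`` each off-diagonal cell gets a profile-likelihood
    interval (stored in ``fit.ci``); expensive, so off by default.
    """
    if "A" not in fit.params.components or "E" not in fit.params.components:
        raise BiometricError("fit must include A and E components")
    rA = component_correlations(fit, "A")
    rE = component_correlations(fit, "E")
    if compute_ci:
        p = rA.shape[0]
        for comp in ("A", "E"):
            for i in range(p):
                for j in range(i):
                    profile_ci(fit, corr_quantity(comp, i, j), level=level)
    return rA, rE


def order_by_beta(betas: dict[str, float], target: str,
                  inventory_order: list[str] | None = None) -> list[str]:
    """Cholesky entry order: facets by descending |beta|, target last.

    Ties in |beta| are broken by the facets' position in
    ``inventory_order`` (defaults to the insertion order of ``betas``) and
    logged, since the unrounded coefficients are unknown.
    """
    labels = list(betas)
    if len(set(labels)) != len(labels):
        raise BiometricError("duplicate facet labels")
    if target in betas:
        raise BiometricError("target must not appear among the betas")
    order_ref = list(inventory_order) if inventory_order else labels
    missing = set(labels) - set(order_ref)
    if missing:
        raise BiometricError(f"facets missing from inventory order: {missing}")
    mags = {lab: abs(betas[lab]) for lab in labels}
    groups: dict[float, list[str]] = {}
    for lab in labels:
        groups.setdefault(round(mags[lab], 12), []).append(lab)
    for mag, members in groups.items():
        if len(members) > 1:
            log.info("tie at |beta|=%.4g broken by inventory order: %s",
                     mag, sorted(members, key=order_ref.index))
    ordered = sorted(labels, key=lambda lab: (-mags[lab], order_ref.index(lab)))
    return ordered + [target]


def cholesky_shared_unique(cohort: TwinCohort | FimlData,
                           ordering: list[str],
                           components=("A", "E"),
                           n_starts: int = 5, seed: int = 0,
                           include_singles: bool = True,
                           compute_ci: bool = False) -> DecompositionResult:
    """Fit the ordered Cholesky and decompose the target's variance.

    For the target trait (last in ``ordering``) with Cholesky paths
    ``l_t1 ... l_tt`` in a component L, the fraction of that component's
    variance shared with the predecessors is ``sum_{j<t} l_tj^2 / sum_{j<=t}
    l_tj^2``; the remainder is unique.  In the bivariate case the shared
    genetic fraction equals rA squared.
    """
    if len(ordering) < 2:
        raise BiometricError("ordering needs at least two traits")
    fit = fit_biometric(cohort, components=components,
                        parameterization="cholesky", n_starts=n_starts,
                        seed=seed, traits=list(ordering),
                        include_singles=include_singles)
    t = len(ordering) - 1

    def split(component: str) -> float:
        l_row = fit.params.matrices[component][t, :]
        total = float(l_row @ l_row)
        if total <= 0:
            raise BiometricError(f"target has zero {component} variance")
        return float(l_row[:t] @ l_row[:t] / total)

    shared_a = split("A")
    shared_e = split("E")
    rA, rE = genetic_env_correlations(fit, compute_ci=compute_ci)
    a2 = fit.standardized.get("A", np.full(t + 1, np.nan))[t]
    e2 = fit.standardized.get("E", np.full(t + 1, np.nan))[t]
    return DecompositionResult(
        ordering=list(ordering), rA=rA, rE=rE,
        target_total_a2=float(a2), target_total_e2=float(e2),
        shared_a_fraction=shared_a, shared_e_fraction=shared_e, fit=fit)
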