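"""Synthetic twin cohorts with known genetic/environmental structure.

The generator implements the classical twin model directly: for each trait
vector, additive-genetic latents of co-twins correlate 1.0 (MZ) or 0.5 (DZ),
shared-environment latents are identical within a pair, and unique-environment
latents are independent, with the component covariances A, C and E supplied by
the user.  Likert item responses can be layered on top of a latent trait with
an acquiescence (yea-saying) intercept per respondent, emulating the response
style a balanced inventory is needed to identify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import ITEM_PREFIX, PHENO_PREFIX, TwinCohort

PSD_TOL = 1e-10


class SpecError(ValueError):
    """Inadmissible generating specification."""


def _check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise SpecError(f"component {name} must be a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise SpecError(f"component {name} is not symmetric")
    if np.linalg.eigvalsh(mat).min() < -PSD_TOL:
        raise SpecError(f"component {name} is not positive-semidefinite")
    return mat


def _psd_factor(mat: np.ndarray) -> np.ndarray:
    """Factor F with F @ F.T = mat, valid for singular PSD matrices."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


@dataclass
class BiometricSpec:
    """Generating ACE structure for ``p`` traits.

    ``A``, ``C``, ``E`` are p-by-p symmetric PSD covariance contributions;
    their sum is the within-person phenotypic covariance.  ``means``,
    ``beta_age`` and ``beta_sex`` are per-trait mean-model coefficients
    (age enters centred at the midpoint of the sampled age range so that
    ``means`` stays the mid-range expectation).
    """

    A: np.ndarray
    C: np.ndarray
    E: np.ndarray
    means: np.ndarray | None = None
    beta_age: np.ndarray | None = None
    beta_sex: np.ndarray | None = None
    trait_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.A = _check_psd(np.atleast_2d(self.A), "A")
        self.C = _check_psd(np.atleast_2d(self.C), "C")
        self.E = _check_psd(np.atleast_2d(self.E), "E")
        p = self.A.shape[0]
        if self.C.shape[0] != p or self.E.shape[0] != p:
            raise SpecError("A, C, E must share one dimension")
        total = self.A + self.C + self.E
        if np.linalg.eigvalsh(total).min() <= PSD_TOL:
            raise SpecError("total covariance A+C+E must be positive-definite")
        for attr in ("means", "beta_age", "beta_sex"):
            v = getattr(self, attr)
            v = np.zeros(p) if v is None else np.asarray(v, float).ravel()
            if v.size != p:
                raise SpecError(f"{attr} must have length {p}")
            setattr(self, attr, v)
        if self.trait_names is None:
            self.trait_names = [f"t{i + 1}" for i in range(p)]
        elif len(self.trait_names) != p:
            raise SpecError("trait_names length mismatch")

    @property
    def n_traits(self) -> int:
        return self.A.shape[0]

    @property
    def is_standardized(self) -> bool:
        return bool(np.allclose(np.diag(self.A + self.C + self.E), 1.0,
                                atol=PSD_TOL))

    @classmethod
    def from_standardized(cls, a2, c2=None, e2=None, rA=None, rC=None,
                          rE=None, trait_names=None, **kwargs):
        """Build a spec from standardized shares and component correlations.

        ``a2``/``c2``/``e2`` are per-trait variance shares (each trait's
        shares must sum to 1; omitted components default so they do), and
        ``rA``/``rC``/``rE`` are the component correlation matrices (identity
        if omitted).  Component covariance is ``r_X * sqrt(x2_i * x2_j)``.
        """
        a2 = np.atleast_1d(np.asarray(a2, float))
        p = a2.size
        c2 = np.zeros(p) if c2 is None else np.atleast_1d(np.asarray(c2, float))
        e2 = (1.0 - a2 - c2) if e2 is None else np.atleast_1d(np.asarray(e2, float))
        if np.any(a2 < 0) or np.any(c2 < 0) or np.any(e2 < 0):
            raise SpecError("standardized shares must be nonnegative")
        if not np.allclose(a2 + c2 + e2, 1.0, atol=1e-8):
            raise SpecError("standardized shares must sum to 1 per trait")

        def build(share, r, name):
            r = np.eye(p) if r is None else np.asarray(r, float)
            return _check_psd(r * np.sqrt(np.outer(share, share)), name)

        return cls(A=build(a2, rA, "A"), C=build(c2, rC, "C"),
                   E=build(e2, rE, "E"), trait_names=trait_names, **kwargs)

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "C": self.C.tolist(),
                "E": self.E.tolist(), "means": self.means.tolist(),
                "beta_age": self.beta_age.tolist(),
                "beta_sex": self.beta_sex.tolist(),
                "trait_names": list(self.trait_names)}


@dataclass
class LikertItemSpec:
    """Item model mapping a latent trait to 1-5 (or 1-k+1) categories.

    Each item's latent value is ``sign * loading * trait + acquiescence +
    uniqueness`` where the sign is -1 for reverse-keyed items; the response
    category is 1 + (number of thresholds below the latent value).  The
    acquiescence intercept is drawn once per respondent and shared by all
    items regardless of keying, which is what makes it estimable on a
    balanced scale.
    """

    n_items: int
    loading: np.ndarray | float = 1.0
    reverse_keyed: np.ndarray | None = None
    thresholds: Sequence[float] = (-1.5, -0.5, 0.5, 1.5)
    acquiescence_sd: float = 0.0
    uniqueness_sd: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        k = self.n_items
        self.loading = np.broadcast_to(np.asarray(self.loading, float), (k,)).copy()
        self.uniqueness_sd = np.broadcast_to(
            np.asarray(self.uniqueness_sd, float), (k,)).copy()
        if self.reverse_keyed is None:
            self.reverse_keyed = np.zeros(k, bool)
        else:
            self.reverse_keyed = np.asarray(self.reverse_keyed, bool)
            if self.reverse_keyed.size != k:
                raise SpecError("reverse_keyed must have length n_items")
        self.thresholds = np.asarray(self.thresholds, float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise SpecError("thresholds must be strictly increasing")
        if self.acquiescence_sd < 0 or np.any(self.uniqueness_sd < 0):
            raise SpecError("noise SDs must be nonnegative")

    @property
    def is_balanced(self) -> bool:
        nrev = int(self.reverse_keyed.sum())
        return nrev * 2 == self.n_items

    @classmethod
    def balanced(cls, n_items: int, **kwargs) -> "LikertItemSpec":
        rev = np.zeros(n_items, bool)
        rev[n_items // 2:] = True
        return cls(n_items=n_items, reverse_keyed=rev, **kwargs)


class LikertDraw(NamedTuple):
    responses: np.ndarray  # (n, n_items) int, categories 1..k+1
    acquiescence: np.ndarray  # (n,) injected person latents


def simulate_phenotypes(spec: BiometricSpec, n_mz: int, n_dz: int,
                        n_singles: int = 0, age_range=(31.0, 55.0),
                        sex_ratio: float = 0.66, seed: int = 0) -> TwinCohort:
    """Draw a twin cohort under the generating ACE structure.

    Genetic latents are built as ``g_i = sqrt(rho) * g_pair +
    sqrt(1 - rho) * g_own`` with rho = 1 for MZ and 0.5 for DZ, then coloured
    by a factor of A; this reproduces the required cross-twin genetic
    correlation exactly for any PSD A.  Shared-environment latents are one
    draw per family under C; unique-environment latents are independent under
    E.  Unpaired responders are marginal draws.  Twins share sex (same-sex
    pairs only) and age; ``sex_ratio`` is the probability of sex code 1.

    Deterministic given ``seed``.
    """
    if min(n_mz, n_dz, n_singles) < 0:
        raise SpecError("pair/single counts must be nonnegative")
    rng = np.random.default_rng(seed)
    p = spec.n_traits
    fa = _psd_factor(spec.A)
    fc = _psd_factor(spec.C)
    fe = _psd_factor(spec.E)
    lo, hi = float(age_range[0]), float(age_range[1])
    age_mid = 0.5 * (lo + hi)

    frames = []
    fam_counter = 0

    def draw_pairs(n: int, zyg: str, rho: float) -> None:
        nonlocal fam_counter
        if n == 0:
            return
        g_pair = rng.standard_normal((n, p))
        g1 = np.sqrt(rho) * g_pair + np.sqrt(1 - rho) * rng.standard_normal((n, p))
        g2 = np.sqrt(rho) * g_pair + np.sqrt(1 - rho) * rng.standard_normal((n, p))
        c = rng.standard_normal((n, p)) @ fc.T
        age = rng.uniform(lo, hi, n)
        sex = (rng.random(n) < sex_ratio).astype(int)
        base = (spec.means + np.outer(age - age_mid, spec.beta_age)
                + np.outer(sex, spec.beta_sex))
        for order, g in ((1, g1), (2, g2)):
            pheno = base + g @ fa.T + c + rng.standard_normal((n, p)) @ fe.T
            frames.append(pd.DataFrame({
                "family_id": [f"{zyg}{fam_counter + i:06d}" for i in range(n)],
                "zygosity": zyg, "twin_order": order, "sex": sex, "age": age,
            } | {PHENO_PREFIX + t: pheno[:, j]
                 for j, t in enumerate(spec.trait_names)}))
        fam_counter += n

    draw_pairs(n_mz, "MZ", 1.0)
    draw_pairs(n_dz, "DZ", 0.5)

    if n_singles:
        n = n_singles
        age = rng.uniform(lo, hi, n)
        sex = (rng.random(n) < sex_ratio).astype(int)
        zyg = np.where(rng.random(n) < 0.5, "MZ", "DZ")
        pheno = (spec.means + np.outer(age - age_mid, spec.beta_age)
                 + np.outer(sex, spec.beta_sex)
                 + rng.standard_normal((n, p)) @ fa.T
                 + rng.standard_normal((n, p)) @ fc.T
                 + rng.standard_normal((n, p)) @ fe.T)
        frames.append(pd.DataFrame({
            "family_id": [f"S{fam_counter + i:06d}" for i in range(n)],
            "zygosity": zyg, "twin_order": 1, "sex": sex, "age": age,
        } | {PHENO_PREFIX + t: pheno[:, j]
             for j, t in enumerate(spec.trait_names)}))

    data = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["family_id", "zygosity", "twin_order", "sex", "age"])
    meta = {"seed": int(seed), "n_mz": n_mz, "n_dz": n_dz,
            "n_singles": n_singles, "age_range": [lo, hi],
            "sex_ratio": float(sex_ratio), "spec": spec.to_dict()}
    return TwinCohort(data, meta=meta)


def simulate_likert_items(latent_trait, item_spec: LikertItemSpec,
                          seed: int = 0) -> LikertDraw:
    """Ordinal item responses for a latent trait vector.

    Returns the integer response matrix together with the injected per-person
    acquiescence latents (kept for validation against recovered scores).
    """
    rng = np.random.default_rng(seed)
    trait = np.asarray(latent_trait, float).ravel()
    if not np.all(np.isfinite(trait)):
        raise SpecError("latent trait must be finite")
    n, k = trait.size, item_spec.n_items
    sign = np.where(item_spec.reverse_keyed, -1.0, 1.0)
    acq = (rng.standard_normal(n) * item_spec.acquiescence_sd
           if item_spec.acquiescence_sd > 0 else np.zeros(n))
    latent = (np.outer(trait, sign * item_spec.loading) + acq[:, None]
              + rng.standard_normal((n, k)) * item_spec.uniqueness_sd)
    responses = 1 + np.searchsorted(item_spec.thresholds, latent.ravel(),
                                    side="left").reshape(n, k)
    return LikertDraw(responses.astype(int), acq)


def attach_items(cohort: TwinCohort, trait: str, scale_name: str,
                 item_spec: LikertItemSpec, seed: int = 0) -> TwinCohort:
    """Add ``item_<scale>_<k>`` columns generated from a phenotype column."""
    draw = simulate_likert_items(
        cohort.data[PHENO_PREFIX + trait].to_numpy(float), item_spec, seed)
    df = cohort.data.copy()
    for j in range(item_spec.n_items):
        df[f"{ITEM_PREFIX}{scale_name}_{j + 1}"] = draw.responses[:, j]
    meta = dict(cohort.meta)
    meta.setdefault("scales", {})[scale_name] = {
        "trait": trait, "n_items": item_spec.n_items,
        "reverse_keyed": item_spec.reverse_keyed.astype(int).tolist(),
        "seed": int(seed)}
    out = TwinCohort(df, meta=meta)
    out.meta.setdefault("_latents", {})[scale_name] = draw.acquiescence
    return out


def drop_to_singles(cohort: TwinCohort, p_drop: float,
                    seed: int = 0) -> TwinCohort:
    """Remove the second twin of each pair independently with ``p_drop``.

    Emulates unpaired responders under a missing-completely-at-random
    mechanism; family ids, zygosity and record order are preserved.
    """
    if not 0.0 <= p_drop <= 1.0:
        raise SpecError("p_drop must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = cohort.data
    sizes = df.groupby("family_id")["twin_order"].transform("size")
    pair_fams = df.loc[(sizes == 2) & (df["twin_order"] == 1), "family_id"]
    dropped = set(pair_fams[rng.random(len(pair_fams)) < p_drop])
    keep = ~(df["family_id"].isin(dropped) & (df["twin_order"] == 2))
    meta = dict(cohort.meta)
    meta["drop_to_singles"] = {"p_drop": float(p_drop), "seed": int(seed)}
    return TwinCohort(df[keep].reset_index(drop=True), meta=meta)
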