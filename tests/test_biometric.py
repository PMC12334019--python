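"""Likelihood-engine checks against closed forms and naive oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinace import (BiometricParamsFit, TwinCohort, assumption_tests,
                     compare_models, expected_pair_covariance, fiml_minus2LL,
                     fit_biometric, heuristic_components, intraclass_corr,
                     moment_matched_cohort, profile_ci, share_quantity,
                     simulate_phenotypes, standardize_components, wald_se)
from twinace.biometric import BiometricError, FimlData

from conftest import random_psd


def direct_params(A=None, C=None, E=None, means=None, p=1):
    mats = {}
    for name, m in (("A", A), ("C", C), ("E", E)):
        if m is not None:
            mats[name] = np.atleast_2d(np.asarray(m, float))
            p = mats[name].shape[0]
    return BiometricParamsFit("direct", mats,
                              np.zeros(p) if means is None else np.asarray(means, float),
                              [f"t{i+1}" for i in range(p)])


def naive_minus2LL(params, cohort, include_singles=True):
    """Record-by-record dense evaluation with multivariate_normal.logpdf."""
    traits = cohort.phenotype_names
    p = len(traits)
    mu = np.asarray(params.means, float)
    total = 0.0
    for zyg in ("MZ", "DZ"):
        wide = cohort.complete_pairs(zyg)
        sigma = expected_pair_covariance(params, zyg)
        mu2 = np.concatenate([mu, mu])
        for _, row in wide.iterrows():
            x = np.array([row[f"pheno_{t}_1"] for t in traits]
                         + [row[f"pheno_{t}_2"] for t in traits])
            obs = np.isfinite(x)
            if not obs.any():
                continue
            total += -2 * stats.multivariate_normal.logpdf(
                x[obs], mu2[obs], sigma[np.ix_(obs.nonzero()[0],
                                               obs.nonzero()[0])])
    if include_singles:
        sigma = params.total_covariance()
        for _, row in cohort.singles().iterrows():
            x = np.array([row[f"pheno_{t}"] for t in traits])
            obs = np.isfinite(x)
            if not obs.any():
                continue
            total += -2 * stats.multivariate_normal.logpdf(
                x[obs], mu[obs], sigma[np.ix_(obs.nonzero()[0],
                                              obs.nonzero()[0])])
    return total


class TestExpectedPairCovariance:
    def test_e_only_is_identity(self):
        params = direct_params(E=np.eye(1))
        np.testing.assert_allclose(
            expected_pair_covariance(params, "MZ"), np.eye(2))

    def test_standardized_ae_cross_twin_correlations(self):
        params = direct_params(A=[[0.5]], E=[[0.5]])
        mz = expected_pair_covariance(params, "MZ")
        dz = expected_pair_covariance(params, "DZ")
        assert mz[0, 1] == pytest.approx(0.50)
        assert dz[0, 1] == pytest.approx(0.25)

    def test_mz_minus_dz_cross_block_is_half_A(self, rng):
        A, C, E = (random_psd(rng, 4) for _ in range(3))
        params = direct_params(A=A, C=C, E=E)
        mz = expected_pair_covariance(params, "MZ")
        dz = expected_pair_covariance(params, "DZ")
        diff = mz[:4, 4:] - dz[:4, 4:]
        np.testing.assert_allclose(diff, 0.5 * A, atol=1e-12)
        assert np.linalg.eigvalsh(diff).min() > -1e-10


class TestFimlMinus2LL:
    def test_single_record_at_mode(self):
        params = direct_params(E=np.eye(2))
        df = pd.DataFrame({"family_id": ["f"], "zygosity": ["MZ"],
                           "twin_order": [1], "sex": [0], "age": [40.0],
                           "pheno_t1": [0.0], "pheno_t2": [0.0]})
        val = fiml_minus2LL(params, TwinCohort(df))
        assert val == pytest.approx(2 * np.log(2 * np.pi), abs=1e-9)

    def test_matches_naive_dense_evaluation_with_missingness(self, rng):
        A, C, E = random_psd(rng, 3), random_psd(rng, 3, 0.3), \
            random_psd(rng, 3) + 0.3 * np.eye(3)
        from twinace import BiometricSpec
        spec = BiometricSpec(A=A, C=C, E=E, means=[0.2, -0.1, 0.4])
        cohort = simulate_phenotypes(spec, 30, 20, n_singles=15, seed=5)
        df = cohort.data.copy()
        pheno_cols = [c for c in df.columns if c.startswith("pheno_")]
        mask = rng.random(df[pheno_cols].shape) < 0.25
        df[pheno_cols] = df[pheno_cols].mask(mask)
        cohort = TwinCohort(df)
        params = direct_params(A=A, C=C, E=E, means=[0.2, -0.1, 0.4])
        ours = fiml_minus2LL(params, cohort)
        oracle = naive_minus2LL(params, cohort)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_duplicating_records_doubles_value(self, uni_spec):
        cohort = simulate_phenotypes(uni_spec, 40, 20, seed=6)
        params = direct_params(A=[[0.5]], E=[[0.5]])
        base = fiml_minus2LL(params, cohort)
        df2 = cohort.data.copy()
        df2["family_id"] = df2["family_id"] + "_dup"
        doubled = TwinCohort(pd.concat([cohort.data, df2],
                                       ignore_index=True))
        assert fiml_minus2LL(params, doubled) == pytest.approx(2 * base,
                                                               rel=1e-12)

    def test_invariant_to_record_order(self, uni_spec, rng):
        cohort = simulate_phenotypes(uni_spec, 40, 20, n_singles=10, seed=6)
        params = direct_params(A=[[0.5]], E=[[0.5]])
        base = fiml_minus2LL(params, cohort)
        shuffled = TwinCohort(
            cohort.data.sample(frac=1, random_state=3).reset_index(drop=True))
        assert fiml_minus2LL(params, shuffled) == pytest.approx(base,
                                                                rel=1e-12)

    def test_singular_covariance_penalized_not_raised(self, uni_spec):
        cohort = simulate_phenotypes(uni_spec, 10, 10, seed=0)
        params = direct_params(A=[[0.0]], E=[[0.0]])
        assert fiml_minus2LL(params, cohort) >= 1e10


class TestFitBiometric:
    def test_noiseless_moment_matched_recovery(self):
        gen = BiometricParamsFit(
            "cholesky", {"A": np.array([[np.sqrt(0.5)]]),
                         "E": np.array([[np.sqrt(0.5)]])},
            np.zeros(1), ["t1"])
        cohort = moment_matched_cohort(gen, 400, 200, seed=1)
        fit = fit_biometric(cohort, components=("A", "E"), n_starts=2, seed=0)
        assert fit.converged
        assert fit.standardized["A"][0] == pytest.approx(0.5, abs=1e-4)
        assert fit.standardized["E"][0] == pytest.approx(0.5, abs=1e-4)

    def test_method_of_moments_oracle_ace(self):
        # generating a2=0.4, c2=0.2: rMZ=0.6, rDZ=0.4; on moment-matched
        # data ML must return a2=2(rMZ-rDZ), c2=2rDZ-rMZ, e2=1-rMZ
        gen = direct_params(A=[[0.4]], C=[[0.2]], E=[[0.4]])
        cohort = moment_matched_cohort(gen, 400, 200, seed=2)
        fit = fit_biometric(cohort, components=("A", "C", "E"),
                            parameterization="direct", n_starts=2, seed=0)
        r_mz, r_dz = 0.6, 0.4
        assert fit.standardized["A"][0] == pytest.approx(2 * (r_mz - r_dz),
                                                         abs=1e-3)
        assert fit.standardized["C"][0] == pytest.approx(2 * r_dz - r_mz,
                                                         abs=1e-3)
        assert fit.standardized["E"][0] == pytest.approx(1 - r_mz, abs=1e-3)

    def test_cholesky_and_direct_reach_same_likelihood(self, study_cohort):
        f1 = fit_biometric(study_cohort, ("A", "E"), "cholesky",
                           n_starts=2, seed=0)
        f2 = fit_biometric(study_cohort, ("A", "E"), "direct",
                           n_starts=2, seed=0)
        assert f1.minus2LL == pytest.approx(f2.minus2LL, abs=0.01)

    def test_nesting_e_never_beats_ace(self, study_cohort):
        ace = fit_biometric(study_cohort, ("A", "C", "E"), n_starts=2, seed=0)
        e = fit_biometric(study_cohort, ("E",), n_starts=2, seed=0)
        assert ace.minus2LL <= e.minus2LL + 1e-6

    def test_aic_identity_and_share_sum(self, study_cohort):
        fit = fit_biometric(study_cohort, ("A", "E"), n_starts=2, seed=0)
        assert fit.aic == pytest.approx(fit.minus2LL + 2 * fit.n_params,
                                        abs=1e-9)
        total = sum(fit.standardized[c][0] for c in fit.params.components)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_unidentified_single_group_errors(self, uni_spec):
        cohort = simulate_phenotypes(uni_spec, 50, 0, seed=0)
        with pytest.raises(BiometricError, match="unidentified"):
            fit_biometric(cohort, ("A", "E"))

    def test_e_must_be_included(self, study_cohort):
        with pytest.raises(BiometricError, match="E"):
            fit_biometric(study_cohort, ("A",))


class TestStandardize:
    def test_equal_components_give_half(self):
        params = direct_params(A=np.diag([2.0]), E=np.diag([2.0]))
        shares = standardize_components(params)
        assert shares["A"][0] == pytest.approx(0.5)

    def test_nonpositive_total_errors(self):
        params = direct_params(E=[[0.0]])
        with pytest.raises(BiometricError):
            standardize_components(params)

    def test_matches_hand_computation_multivariate(self, rng):
        A, E = random_psd(rng, 4), random_psd(rng, 4)
        params = direct_params(A=A, E=E)
        shares = standardize_components(params)
        for i in range(4):
            assert shares["A"][i] == pytest.approx(
                A[i, i] / (A[i, i] + E[i, i]))


class TestProfileCI:
    def test_close_to_wald_in_near_quadratic_regime(self, uni_spec):
        cohort = simulate_phenotypes(uni_spec, 2000, 1000, seed=13)
        fit = fit_biometric(cohort, ("A", "E"), n_starts=2, seed=0)
        q = share_quantity("A", 0)
        lo, hi = profile_ci(fit, q)
        se = wald_se(fit, q)
        a2 = fit.standardized["A"][0]
        assert lo == pytest.approx(a2 - 1.96 * se, abs=0.01)
        assert hi == pytest.approx(a2 + 1.96 * se, abs=0.01)

    def test_width_at_study_scale_matches_published_width(self, study_cohort):
        fit = fit_biometric(study_cohort, ("A", "E"), n_starts=2, seed=0)
        lo, hi = profile_ci(fit, share_quantity("A", 0))
        assert 0.08 < hi - lo < 0.20  # printed interval width ~0.13


class TestCompareModels:
    def test_identical_fit_statistics(self, study_cohort):
        full = fit_biometric(study_cohort, ("A", "C", "E"), n_starts=2, seed=0)
        nested = fit_biometric(study_cohort, ("A", "E"), n_starts=2, seed=0)
        c = compare_models(full, nested)
        assert c.delta_df == 1
        assert 0 <= c.p_value <= 1
        assert c.delta_aic == pytest.approx(
            nested.aic - full.aic, abs=1e-9)

    def test_mismatched_cohorts_rejected(self, uni_spec):
        a = fit_biometric(simulate_phenotypes(uni_spec, 50, 30, seed=1),
                          ("A", "E"), n_starts=1, seed=0)
        b = fit_biometric(simulate_phenotypes(uni_spec, 50, 30, seed=2),
                          ("E",), n_starts=1, seed=0)
        with pytest.raises(BiometricError, match="cohort"):
            compare_models(a, b)

    def test_power_against_e_only_at_study_scale(self, study_cohort):
        # generating a2=0.5: the ACE vs E contrast should be decisive
        full = fit_biometric(study_cohort, ("A", "C", "E"), n_starts=2, seed=0)
        e_only = fit_biometric(study_cohort, ("E",), n_starts=2, seed=0)
        c = compare_models(full, e_only)
        assert c.p_value < 1e-6
        assert c.preferred == "ACE"


class TestAssumptionTests:
    def test_constraints_never_improve_fit_and_null_is_calm(self, uni_spec):
        cohort = simulate_phenotypes(uni_spec, 400, 200, seed=21)
        results = assumption_tests(cohort)
        assert len(results) == 3
        for r in results:
            assert r.delta_minus2LL >= 0
            assert 0 <= r.p_value <= 1
        # well-specified generator: no constraint should be rejected hard
        assert min(r.p_value for r in results) > 0.001

    def test_mean_shift_across_zygosity_detected(self, uni_spec):
        cohort = simulate_phenotypes(uni_spec, 400, 200, seed=22)
        df = cohort.data.copy()
        df.loc[df["zygosity"] == "MZ", "pheno_mmt"] += 0.5
        results = assumption_tests(TwinCohort(df))
        by_label = {r.nested_label: r for r in results}
        assert by_label["equal means across zygosity"].p_value < 0.05


class TestDescriptives:
    @pytest.mark.parametrize("r,n,expected_se", [
        (0.50, 418, 0.04), (0.22, 188, 0.07)])
    def test_icc_se_reproduces_printed_values(self, r, n, expected_se):
        se = (1 - r ** 2) / np.sqrt(n - 1)
        assert round(se, 2) == expected_se

    def test_icc_on_identical_cotwins(self, uni_spec):
        cohort = simulate_phenotypes(uni_spec, 50, 10, seed=3)
        df = cohort.data.copy()
        wide = cohort.complete_pairs("MZ")
        mapping = dict(zip(wide.index, wide["pheno_mmt_1"]))
        sel = (df["zygosity"] == "MZ")
        df.loc[sel, "pheno_mmt"] = df.loc[sel, "family_id"].map(mapping)
        res = intraclass_corr(TwinCohort(df), "mmt", "MZ")
        assert res.r == pytest.approx(1.0)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_icc_needs_three_pairs(self, uni_spec):
        cohort = simulate_phenotypes(uni_spec, 2, 2, seed=0)
        with pytest.raises(BiometricError):
            intraclass_corr(cohort, "mmt", "MZ")

    @pytest.mark.parametrize("r_mz,r_dz,a,c,d", [
        (0.36, 0.31, True, True, False),   # C range: rMZ < 2 rDZ
        (0.50, 0.25, True, False, False),  # exact 2:1 -> neither C nor D
        (0.53, 0.15, True, False, True),   # D range: rMZ > 2 rDZ
    ])
    def test_heuristic_flags(self, r_mz, r_dz, a, c, d):
        flags = heuristic_components(r_mz, r_dz)
        assert (flags.A_suggested, flags.C_suggested,
                flags.D_suggested) == (a, c, d)
        assert flags.E_included
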