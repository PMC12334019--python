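"""Scoring checks: acquiescence, composites, reliability, residualization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinace import (LikertItemSpec, ScaleDefinition, acquiescence_score,
                     adjust_for_acquiescence, composite_score, cronbach_alpha,
                     residualize_age_sex, simulate_likert_items)
from twinace.preprocess import PreprocessError


def balanced_scale(k=4, name="bfi"):
    ids = [f"i{j}" for j in range(k)]
    return ScaleDefinition(name=name, item_ids=ids,
                           reverse_keyed=ids[k // 2:])


class TestAcquiescence:
    def test_midpoint_responses_score_zero(self):
        scale = balanced_scale(4)
        scores = acquiescence_score(np.full((6, 4), 3.0), scale)
        np.testing.assert_allclose(scores, 0.0)

    def test_all_fives_score_plus_two(self):
        scale = balanced_scale(4)
        scores = acquiescence_score(np.full((3, 4), 5.0), scale)
        np.testing.assert_allclose(scores, 2.0)

    def test_unbalanced_scale_rejected(self):
        scale = ScaleDefinition(name="mm", item_ids=["a", "b", "c"])
        with pytest.raises(PreprocessError, match="not balanced"):
            acquiescence_score(np.full((2, 3), 3.0), scale)

    def test_recovers_injected_acquiescence_better_than_any_item(self):
        spec = LikertItemSpec.balanced(16, acquiescence_sd=0.5)
        rng = np.random.default_rng(0)
        draw = simulate_likert_items(rng.standard_normal(8000), spec, seed=1)
        scale = balanced_scale(16)
        score = acquiescence_score(draw.responses.astype(float), scale)
        r_score = np.corrcoef(score, draw.acquiescence)[0, 1]
        r_items = [abs(np.corrcoef(draw.responses[:, j],
                                   draw.acquiescence)[0, 1])
                   for j in range(16)]
        assert r_score > max(r_items)

    def test_trait_content_cancels_on_balanced_scale(self):
        # noiseless symmetric loadings: score is trait-free
        spec = LikertItemSpec.balanced(8, acquiescence_sd=0, uniqueness_sd=0,
                                       thresholds=(-1.5, -0.5, 0.5, 1.5))
        trait = np.linspace(-0.4, 0.4, 11)
        draw = simulate_likert_items(trait, spec, seed=2)
        scores = acquiescence_score(draw.responses.astype(float),
                                    balanced_scale(8))
        np.testing.assert_allclose(scores, scores[0])


class TestAdjustForAcquiescence:
    def test_constant_acq_degenerates_to_zscores(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(50)
        resid, r2 = adjust_for_acquiescence(y, np.ones(50))
        assert r2 == 0.0
        np.testing.assert_allclose(resid, (y - y.mean()) / y.std())

    def test_perfect_collinearity_flagged(self):
        x = np.linspace(-1, 1, 30)
        with pytest.raises(PreprocessError, match="collinear"):
            adjust_for_acquiescence(x, x)

    def test_matches_normal_equations_oracle(self):
        # composite = trait + 0.2 * acq + noise, tuned so adj-R2 lands in
        # the few-percent range typical of acquiescence effects
        rng = np.random.default_rng(2)
        n = 4000
        acq = rng.standard_normal(n) * 0.5
        y = rng.standard_normal(n) * 0.45 + 0.2 * acq
        resid, r2 = adjust_for_acquiescence(y, acq)
        X = np.column_stack([np.ones(n), acq])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = y - X @ beta
        r2_oracle = 1 - (res @ res / ((y - y.mean()) ** 2).sum()) \
            * (n - 1) / (n - 2)
        assert 0.03 < r2 < 0.06
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)
        np.testing.assert_allclose(resid, (res - res.mean()) / res.std(),
                                   atol=1e-10)

    def test_residuals_orthogonal_to_acquiescence(self):
        rng = np.random.default_rng(3)
        acq = rng.standard_normal(500)
        y = rng.standard_normal(500) + 0.3 * acq
        resid, _ = adjust_for_acquiescence(y, acq)
        assert abs(resid @ acq) < 1e-8 * 500


class TestCompositeScore:
    def test_plain_mean(self):
        scale = ScaleDefinition(name="s", item_ids=["a", "b", "c", "d"])
        out = composite_score(np.full((3, 4), 2.0), scale)
        np.testing.assert_allclose(out, 2.0)

    def test_reverse_keyed_recode(self):
        scale = ScaleDefinition(name="s", item_ids=["a", "b"],
                                reverse_keyed=["b"])
        out = composite_score(np.array([[5.0, 1.0]]), scale)
        assert out[0] == 5.0

    def test_matches_brute_force_oracle(self, rng):
        ids = [f"q{j}" for j in range(6)]
        scale = ScaleDefinition(name="s", item_ids=ids,
                                reverse_keyed=ids[:2], excluded_items=[ids[5]])
        resp = rng.integers(1, 6, size=(40, 6)).astype(float)
        resp[rng.random((40, 6)) < 0.2] = np.nan
        out = composite_score(resp, scale)
        for i in range(40):
            vals = []
            for j in range(5):  # item 5 excluded
                x = resp[i, j]
                if np.isnan(x):
                    continue
                vals.append(6 - x if j < 2 else x)
            expected = np.mean(vals) if len(vals) * 2 >= 5 else np.nan
            if np.isnan(expected):
                assert np.isnan(out[i])
            else:
                assert out[i] == pytest.approx(expected)

    @given(perm=st.permutations(list(range(5))))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_item_relabeling(self, perm):
        ids = [f"q{j}" for j in range(5)]
        scale = ScaleDefinition(name="s", item_ids=ids, reverse_keyed=[ids[1]])
        rng = np.random.default_rng(7)
        resp = rng.integers(1, 6, size=(10, 5)).astype(float)
        base = composite_score(resp, scale)
        shuffled = composite_score(resp[:, perm], scale,
                                   item_ids=[ids[j] for j in perm])
        np.testing.assert_allclose(base, shuffled)

    def test_all_items_excluded(self):
        scale = ScaleDefinition(name="s", item_ids=["a"], excluded_items=["a"])
        with pytest.raises(PreprocessError, match="excluded"):
            composite_score(np.array([[3.0]]), scale)


class TestCronbachAlpha:
    def test_identical_items_give_alpha_one(self):
        scale = ScaleDefinition(name="s", item_ids=["a", "b"])
        x = np.tile(np.arange(1, 6, dtype=float), (2, 1)).T
        assert cronbach_alpha(x, scale).alpha == pytest.approx(1.0)

    def test_independent_items_give_alpha_near_zero(self, rng):
        scale = ScaleDefinition(name="s", item_ids=["a", "b"])
        x = rng.integers(1, 6, size=(50000, 2)).astype(float)
        assert abs(cronbach_alpha(x, scale).alpha) < 0.05

    def test_matches_closed_form_for_parallel_items(self, rng):
        # k parallel items, loading l, uniqueness u: alpha has a closed form
        k, loading, unique = 9, 0.8, 0.6
        n = 40000
        trait = rng.standard_normal(n)
        x = loading * trait[:, None] + unique * rng.standard_normal((n, k))
        scale = ScaleDefinition(name="s", item_ids=[f"i{j}" for j in range(k)],
                                response_min=-100, response_max=100)
        alpha = cronbach_alpha(x, scale).alpha
        rho = loading ** 2 / (loading ** 2 + unique ** 2)
        alpha_true = k * rho / (1 + (k - 1) * rho)  # Spearman-Brown
        assert alpha == pytest.approx(alpha_true, abs=0.01)

    def test_cross_checked_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        x = rng.standard_normal((200, 4)) + rng.standard_normal((200, 1))
        scale = ScaleDefinition(name="s", item_ids=list("abcd"),
                                response_min=-100, response_max=100)
        ours = cronbach_alpha(x, scale).alpha
        theirs = pingouin.cronbach_alpha(pd.DataFrame(x))[0]
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestResidualizeAgeSex:
    def test_no_covariate_effect_preserves_zscores(self, rng):
        y = rng.standard_normal(10000)
        age = rng.uniform(31, 55, 10000)
        sex = rng.integers(0, 2, 10000)
        out = residualize_age_sex(y, age, sex)
        z = (y - y.mean()) / y.std()
        assert np.corrcoef(out, z)[0, 1] > 0.999

    def test_pure_covariate_signal_flagged(self):
        age = np.linspace(31, 55, 100)
        with pytest.raises(PreprocessError, match="constant"):
            residualize_age_sex(2 * age, age, np.zeros(100))

    def test_residuals_uncorrelated_with_age(self, rng):
        age = rng.uniform(31, 55, 10000)
        sex = rng.integers(0, 2, 10000)
        y = 0.3 * age + rng.standard_normal(10000)
        out = residualize_age_sex(y, age, sex)
        assert abs(np.corrcoef(out, age)[0, 1]) < 0.02
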