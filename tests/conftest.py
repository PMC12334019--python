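import numpy as np
import pytest

from twinace import BiometricSpec, simulate_phenotypes


@pytest.fixture(scope="session")
def uni_spec():
    """Standardized univariate AE spec: a2 = 0.5, e2 = 0.5."""
    return BiometricSpec.from_standardized([0.5], trait_names=["mmt"])


@pytest.fixture(scope="session")
def study_cohort(uni_spec):
    """One univariate cohort at the study's complete-pair counts."""
    return simulate_phenotypes(uni_spec, n_mz=418, n_dz=188, seed=20)


@pytest.fixture(scope="session")
def four_spec():
    """Four-trait AE spec with the published shares and correlations."""
    a2 = [0.50, 0.40, 0.38, 0.52]
    rA = [[1, .85, .80, .90], [.85, 1, .75, .80],
          [.80, .75, 1, .71], [.90, .80, .71, 1]]
    rE = [[1, .75, .59, .69], [.75, 1, .48, .54],
          [.59, .48, 1, .55], [.69, .54, .55, 1]]
    return BiometricSpec.from_standardized(
        a2, rA=rA, rE=rE, trait_names=["mmt", "mme", "mms", "mmi"])


def random_psd(rng, p, scale=1.0):
    m = rng.standard_normal((p, p))
    return scale * (m @ m.T) / p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
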