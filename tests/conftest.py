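import numpy as np
import pytest

from specdcm import (
    DCMParams,
    PriorSpec,
    default_dmn,
    default_freqs,
    synthetic_lead_field,
)


@pytest.fixture(scope="session")
def spec():
    return default_dmn()


@pytest.fixture(scope="session")
def lead():
    return synthetic_lead_field(8, seed=101)


@pytest.fixture(scope="session")
def freqs():
    return default_freqs()


@pytest.fixture(scope="session")
def priors():
    return PriorSpec()


@pytest.fixture()
def prior_params():
    return DCMParams()


@pytest.fixture(scope="session")
def key_edge(spec):
    """Index of the backward mPFC -> lLP coupling, the study's key effect."""
    return spec.edge_index("mPFC", "lLP")


def make_gaussian_posteriors(
    priors, group_sizes, effects, sigma_between=0.1, like_sd=0.25, seed=0
):
    """Synthetic subject-level posteriors with exactly Gaussian structure.

    For group-level unit tests: each subject's coupling posterior is the
    conjugate combination of the shrinkage prior with a Gaussian likelihood
    of width ``like_sd`` centred on the subject's true couplings.
    """
    from specdcm import Posterior

    rng = np.random.default_rng(seed)
    n_par = priors.mean.size
    posts, labels, truths = [], [], []
    for group, size in group_sizes.items():
        eff = np.asarray(effects.get(group, np.zeros(12)), dtype=float)
        for _ in range(size):
            true_a = eff + sigma_between * rng.standard_normal(12)
            P0 = 1.0 / priors.variance[:12]
            Pl = 1.0 / like_sd**2
            post_var = 1.0 / (P0 + Pl)
            mu_like = true_a + like_sd * rng.standard_normal(12)
            mean = priors.mean.copy()
            mean[:12] = post_var * Pl * mu_like
            cov = np.zeros((n_par, n_par))
            cov[:12, :12] = np.diag(post_var)
            for j in np.where(priors.free)[0]:
                if j >= 12:
                    cov[j, j] = priors.variance[j] * 0.5
            posts.append(Posterior(mean=mean, covariance=cov, free_energy=0.0))
            labels.append(group)
            truths.append(true_a)
    return posts, labels, truths
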