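import numpy as np
import pytest
from scipy.stats import multivariate_normal

from specdcm.inversion import Posterior, PriorSpec
from specdcm.peb import (
    BMAResult,
    DesignMatrix,
    ModelSpace,
    ScoredModel,
    bma,
    bmr,
    fit_peb,
    model_search,
    threshold_bma,
)

from conftest import make_gaussian_posteriors


# ---------------------------------------------------------------------------
# design matrix


def test_design_matrix_centred_group_indicator():
    X = DesignMatrix.from_labels(
        ["a"] * 3 + ["b"] * 2, positive="b", negative="a"
    )
    assert X.matrix.shape == (5, 2)
    assert np.allclose(X.matrix[:, 0], 1.0)
    assert X.matrix[:, 1].sum() == pytest.approx(0.0)
    assert X.matrix[3, 1] > X.matrix[0, 1]


def test_rank_deficient_design_rejected():
    with pytest.raises(ValueError, match="rank"):
        DesignMatrix(np.ones((4, 2)), ["a", "b"])
    with pytest.raises(ValueError, match="both groups"):
        DesignMatrix.from_labels(["a", "a"], positive="b", negative="a")


# ---------------------------------------------------------------------------
# Bayesian model reduction


def brute_force_linear(seed):
    rng = np.random.default_rng(seed)
    p, N = 3, 12
    X = rng.standard_normal((N, p))
    C0 = np.diag(rng.uniform(0.2, 2.0, p))
    mu0 = 0.3 * rng.standard_normal(p)
    s2 = rng.uniform(0.2, 1.0)
    y = X @ (mu0 + np.linalg.cholesky(C0) @ rng.standard_normal(p))
    y = y + np.sqrt(s2) * rng.standard_normal(N)
    P = X.T @ X / s2 + np.linalg.inv(C0)
    S = np.linalg.inv(P)
    m = S @ (X.T @ y / s2 + np.linalg.solve(C0, mu0))

    def logZ(mu_p, C_p):
        return multivariate_normal(
            mean=X @ mu_p, cov=X @ C_p @ X.T + s2 * np.eye(N)
        ).logpdf(y)

    return X, y, s2, mu0, C0, m, S, logZ


def test_identity_reduction_is_neutral():
    _, _, _, mu0, C0, m, S, _ = brute_force_linear(0)
    d, (mp, cp) = bmr((mu0, C0), (m, S), (mu0, C0))
    assert abs(d) < 1e-10
    assert np.abs(mp - m).max() < 1e-10


@pytest.mark.parametrize("seed", range(10))
def test_reduction_matches_brute_force_reinversion(seed):
    X, y, s2, mu0, C0, m, S, logZ = brute_force_linear(seed)
    Cr = C0.copy()
    Cr[0, 0] = 1e-8
    mur = mu0.copy()
    mur[0] = 0.0
    d, (mp, cp) = bmr((mu0, C0), (m, S), (mur, Cr))
    assert abs(d - (logZ(mur, Cr) - logZ(mu0, C0))) < 1e-6
    Pr = X.T @ X / s2 + np.linalg.inv(Cr)
    Sr = np.linalg.inv(Pr)
    mr = Sr @ (X.T @ y / s2 + np.linalg.solve(Cr, mur))
    assert np.abs(mp - mr).max() < 1e-6
    assert np.abs(cp - Sr).max() < 1e-6


def test_pinning_an_irrelevant_parameter_is_cheap():
    rng = np.random.default_rng(5)
    p = 3
    C0 = np.eye(p)
    mu0 = np.zeros(p)
    # posterior equals prior in dimension 0 (data said nothing about it)
    S = np.diag([1.0, 0.05, 0.05])
    m = np.array([0.0, 0.7, -0.4])
    Cr = C0.copy()
    Cr[0, 0] = 1e-8
    d, _ = bmr((mu0, C0), (m, S), (mu0 * 0, Cr))
    assert abs(d) < 0.1


def test_non_psd_inputs_rejected():
    mu = np.zeros(2)
    good = np.eye(2)
    bad = np.diag([1.0, -0.5])
    with pytest.raises(ValueError, match="positive semi-definite"):
        bmr((mu, bad), (mu, good), (mu, good))


# ---------------------------------------------------------------------------
# PEB


def test_degenerate_pooling_recovers_shared_mean(priors):
    shared = np.zeros(58)
    shared[:12] = np.linspace(-0.3, 0.3, 12)
    cov = np.zeros((58, 58))
    cov[:12, :12] = 1e-8 * np.eye(12)
    posts = [
        Posterior(mean=shared.copy(), covariance=cov.copy(), free_energy=0.0)
        for _ in range(4)
    ]
    X = DesignMatrix(np.ones((4, 1)), ["common"])
    peb = fit_peb(posts, X, priors)
    # exact agreement is impossible under the group-level shrinkage prior:
    # with n subjects the pooled mean is scaled by 16n/(16n+1)
    assert np.abs(peb.beta[0] - shared[:12]).max() < 0.01
    assert np.abs(peb.beta[0] - shared[:12] * 64 / 65).max() < 1e-6


def test_group_difference_recovery_over_seeds(priors, key_edge):
    errs = []
    for seed in range(10):
        eff = np.zeros(12)
        eff[key_edge] = -0.5
        posts, labels, _ = make_gaussian_posteriors(
            priors, {"control": 11, "uws": 6}, {"uws": eff}, seed=seed
        )
        X = DesignMatrix.from_labels(labels, positive="uws", negative="control")
        peb = fit_peb(posts, X, priors)
        errs.append(peb.beta[1][key_edge] - (-0.5))
    assert abs(np.mean(errs)) < 0.2


def test_subject_count_and_rank_validation(priors):
    posts, labels, _ = make_gaussian_posteriors(priors, {"a": 2}, {}, seed=0)
    X = DesignMatrix(np.ones((2, 1)), ["common"])
    with pytest.raises(ValueError, match="3 subjects"):
        fit_peb(posts, X, priors)
    posts, labels, _ = make_gaussian_posteriors(priors, {"a": 4}, {}, seed=0)
    with pytest.raises(ValueError, match="rank"):
        DesignMatrix(np.tile(np.ones((4, 1)), (1, 2)), ["c1", "c2"])
    with pytest.raises(ValueError, match="rows"):
        fit_peb(posts, DesignMatrix(np.ones((3, 1)), ["common"]), priors)


def test_subject_order_invariance(priors, key_edge):
    eff = np.zeros(12)
    eff[key_edge] = -0.5
    posts, labels, _ = make_gaussian_posteriors(
        priors, {"control": 5, "uws": 4}, {"uws": eff}, seed=1
    )
    X = DesignMatrix.from_labels(labels, positive="uws", negative="control")
    peb = fit_peb(posts, X, priors)
    order = np.random.default_rng(0).permutation(len(posts))
    Xp = DesignMatrix.from_labels(
        [labels[i] for i in order], positive="uws", negative="control"
    )
    pebp = fit_peb([posts[i] for i in order], Xp, priors)
    assert np.allclose(peb.beta, pebp.beta, atol=1e-10)
    assert peb.free_energy == pytest.approx(pebp.free_energy, abs=1e-8)


# ---------------------------------------------------------------------------
# model search / BMA / thresholding


def strong_peb(priors, key_edge, seed=0):
    eff = np.zeros(12)
    eff[key_edge] = -0.6
    posts, labels, _ = make_gaussian_posteriors(
        priors, {"control": 11, "uws": 6}, {"uws": eff}, like_sd=0.15, seed=seed
    )
    X = DesignMatrix.from_labels(labels, positive="uws", negative="control")
    return fit_peb(posts, X, priors)


def test_exhaustive_search_scores_all_models(priors, key_edge):
    space = model_search(strong_peb(priors, key_edge), "exhaustive")
    assert len(space.models) == 4096
    masks = {tuple(m.mask) for m in space.models}
    assert len(masks) == 4096


def test_exhaustive_refuses_large_spaces(priors, key_edge):
    peb = strong_peb(priors, key_edge)
    peb.beta = np.zeros((2, 17))
    peb.covariance = np.eye(34)
    peb.prior_cov = np.eye(34)
    with pytest.raises(ValueError, match="greedy"):
        model_search(peb, "exhaustive")


def test_true_effect_usually_in_best_model(priors, key_edge):
    hits = 0
    for seed in range(10):
        space = model_search(strong_peb(priors, key_edge, seed), "exhaustive")
        best = max(space.models, key=lambda s: s.delta_f)
        hits += bool(best.mask[key_edge])
    assert hits >= 9


def test_greedy_close_to_exhaustive_optimum(priors, key_edge):
    close = 0
    for seed in range(10):
        peb = strong_peb(priors, key_edge, seed)
        fe = max(m.delta_f for m in model_search(peb, "exhaustive").models)
        fg = max(m.delta_f for m in model_search(peb, "greedy").models)
        close += (fe - fg) < 3.0
    assert close >= 8


def test_bma_probabilities_and_cap(priors, key_edge):
    space = model_search(strong_peb(priors, key_edge), "exhaustive")
    result = bma(space, top=256)
    assert len(result.model_probs) <= 256
    assert result.model_probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all((result.pp >= 0) & (result.pp <= 1))
    assert result.pp[key_edge] > 0.99
    assert result.expected_effect[1][key_edge] < -0.3


def test_two_equal_models_give_half_probability():
    masks = np.array([[True], [False]])
    models = [
        ScoredModel(masks[0], -1.0, np.array([0.5, 0.2]), np.eye(2)),
        ScoredModel(masks[1], -1.0, np.array([0.5, 0.0]), np.eye(2)),
    ]
    peb = type("P", (), {"n_covariates": 2, "n_params": 1, "param_indices": np.array([0])})()
    space = ModelSpace(peb, models, covariate=1, strategy="exhaustive")
    result = bma(space)
    assert result.pp[0] == pytest.approx(0.5)


def test_null_cohorts_rarely_pass_threshold(priors):
    false_hits = 0
    for seed in range(20):
        posts, labels, _ = make_gaussian_posteriors(
            priors, {"control": 11, "uws": 6}, {}, seed=100 + seed
        )
        X = DesignMatrix.from_labels(labels, positive="uws", negative="control")
        result = bma(model_search(fit_peb(posts, X, priors), "exhaustive"))
        false_hits += int(np.any(result.pp > 0.99))
    assert false_hits <= 2


def test_threshold_is_strictly_greater():
    result = BMAResult(
        expected_effect=np.zeros((2, 3)),
        pp=np.array([0.991, 0.99, 0.2]),
        covariate=1,
        model_probs=np.array([1.0]),
        model_masks=np.ones((1, 3), bool),
        param_indices=np.arange(3),
    )
    th = threshold_bma(result, 0.99)
    assert th.retained == [0]
    assert th.faded == [1, 2]
    with pytest.raises(ValueError):
        threshold_bma(result, 0.0)
    with pytest.raises(ValueError):
        threshold_bma(result, 1.0)


def test_empty_bma_thresholds_to_empty():
    result = BMAResult(
        expected_effect=np.zeros((2, 0)),
        pp=np.zeros(0),
        covariate=1,
        model_probs=np.array([1.0]),
        model_masks=np.ones((1, 0), bool),
        param_indices=np.arange(0),
    )
    th = threshold_bma(result)
    assert th.retained == [] and th.faded == []
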