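"""Hierarchical (parametric empirical Bayes) group model over subject posteriors.

Subject-level coupling posteriors are combined under a second-level general
linear model theta_i = (x_i kron I) beta + eps_i with Gaussian random
effects, yielding an analytic posterior over the group effects beta and a
second-level free energy.  Nested models (couplings switched off in the
group-difference effect) are scored by Bayesian model reduction -- an exact
Gaussian identity requiring no refitting -- searched exhaustively or
greedily, and averaged by model evidence (Bayesian model averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inversion import Posterior, PriorSpec

PIN_VARIANCE = 1e-8  # prior variance that switches a parameter "off"


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Subjects x covariates design; column 0 is the intercept.

    ``from_labels`` builds the canonical two-column design: intercept
    (commonalities) plus a mean-centred group indicator.
    """

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("column labels must match covariate count")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_labels(
        cls, groups: list[str], positive: str, negative: str
    ) -> "DesignMatrix":
        ind = []
        for g in groups:
            if g == positive:
                ind.append(1.0)
            elif g == negative:
                ind.append(0.0)
            else:
                raise ValueError(f"unexpected group label {g!r}")
        ind = np.asarray(ind)
        if ind.min() == ind.max():
            raise ValueError("need both groups present in the design")
        centred = ind - ind.mean()
        X = np.column_stack([np.ones_like(centred), centred])
        return cls(X, ["common", f"{positive}-vs-{negative}"])


# ---------------------------------------------------------------------------
# Gaussian algebra helpers


def _likelihood_kernel(
    m: np.ndarray, S: np.ndarray, mu0: np.ndarray, S0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic-form parameters of posterior/prior (the data kernel).

    The precision is clamped to be positive semi-definite: an approximate
    posterior can come out broader than the prior along some direction, and
    a negative-precision kernel would enter downstream sums with negative
    weight.
    """
    P = np.linalg.inv(S) - np.linalg.inv(S0)
    ev, U = np.linalg.eigh(0.5 * (P + P.T))
    P = (U * np.maximum(ev, 1e-6)) @ U.T
    b = np.linalg.solve(S, m) - np.linalg.solve(S0, mu0)
    return P, b


def _kernel_gaussian_evidence(
    P: np.ndarray, b: np.ndarray, mu: np.ndarray, Sigma: np.ndarray
) -> float:
    """log of integral exp(-theta'P theta/2 + b'theta) N(theta; mu, Sigma).

    The arbitrary normalizer of the kernel is omitted; it cancels in every
    comparison this package makes (model scoring and label evidence).
    """
    Lam = np.linalg.inv(Sigma)
    A = P + Lam
    sign, ldA = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("kernel + prior precision not PD")
    _, ldL = np.linalg.slogdet(Lam)
    h = b + Lam @ mu
    v = np.linalg.solve(A, h)
    return 0.5 * float(ldL - ldA + h @ v - mu @ (Lam @ mu))


def bmr(
    prior: tuple[np.ndarray, np.ndarray],
    posterior: tuple[np.ndarray, np.ndarray],
    reduced_prior: tuple[np.ndarray, np.ndarray],
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Bayesian model reduction for Gaussian prior/posterior pairs.

    Given the full prior p0, its posterior q, and a reduced prior pr (same
    dimension, typically with parameters pinned near zero), returns the log
    evidence change log Z_r - log Z_f and the reduced posterior, both exact
    for Gaussian models:  delta = log int q(t) pr(t) / p0(t) dt.
    """
    mu0, C0 = (np.asarray(a, dtype=float) for a in prior)
    muq, Cq = (np.asarray(a, dtype=float) for a in posterior)
    mur, Cr = (np.asarray(a, dtype=float) for a in reduced_prior)
    for C in (C0, Cq, Cr):
        ev = np.linalg.eigvalsh(0.5 * (C + C.T))
        if ev.min() < -1e-10 * max(ev.max(), 1.0):
            raise ValueError("covariances must be positive semi-definite")
    P0 = np.linalg.inv(C0)
    Pq = np.linalg.inv(Cq)
    Pr = np.linalg.inv(Cr)
    Pp = Pq + Pr - P0
    sign, ldPp = np.linalg.slogdet(Pp)
    if sign <= 0:
        raise np.linalg.LinAlgError("reduced posterior precision not PD")
    h = Pq @ muq + Pr @ mur - P0 @ mu0
    mup = np.linalg.solve(Pp, h)
    _, ldPq = np.linalg.slogdet(Pq)
    _, ldPr = np.linalg.slogdet(Pr)
    _, ldP0 = np.linalg.slogdet(P0)
    delta = 0.5 * (
        ldPq
        + ldPr
        - ldP0
        - ldPp
        + float(h @ mup)
        - float(muq @ (Pq @ muq))
        - float(mur @ (Pr @ mur))
        + float(mu0 @ (P0 @ mu0))
    )
    return float(delta), (mup, np.linalg.inv(Pp))


# ---------------------------------------------------------------------------
# PEB


@dataclass
class PEBPosterior:
    """Posterior over group effects: beta is (covariates x couplings)."""

    beta: np.ndarray
    covariance: np.ndarray  # over the flattened, covariate-major beta
    free_energy: float
    design: DesignMatrix
    param_indices: np.ndarray
    random_effect_var: np.ndarray  # diagonal of Sigma_b
    prior_cov: np.ndarray  # prior covariance over flattened beta

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[0]

    @property
    def n_params(self) -> int:
        return self.beta.shape[1]


def fit_peb(
    posteriors: list[Posterior],
    X: DesignMatrix,
    priors: PriorSpec,
    param_indices: np.ndarray | None = None,
    random_effect_scale: float = 1.0 / 16.0,
) -> PEBPosterior:
    """Empirical-Bayes posterior over group effects on the couplings.

    Subject posteriors enter through their marginal mean/covariance on
    ``param_indices`` (default: the 12 extrinsic couplings), weighted by
    their posterior precisions.  The between-subject random-effect
    covariance is diagonal: ``random_effect_scale`` times the first-level
    prior variance per coupling.  Returns the group posterior and the
    second-level free energy used for model comparison.
    """
    n = len(posteriors)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if X.n_subjects != n:
        raise ValueError("design rows must match number of subjects")
    idx = (
        np.arange(12) if param_indices is None else np.asarray(param_indices, int)
    )
    p = idx.size
    k = X.n_covariates
    mu0 = priors.mean[idx]
    S0 = np.diag(priors.variance[idx])
    sigma_b = random_effect_scale * priors.variance[idx]
    Lam_b = np.diag(1.0 / sigma_b)

    # prior over flattened beta (covariate-major): each covariate gets the
    # first-level prior variance per coupling
    C_beta = np.kron(np.eye(k), S0)
    P_beta = np.linalg.inv(C_beta)

    A_sum = np.zeros((k * p, k * p))
    l_sum = np.zeros(k * p)
    F_subjects = 0.0
    for i, post in enumerate(posteriors):
        m_i, S_i = post.marginal(idx)
        P_i, b_i = _likelihood_kernel(m_i, S_i, mu0, S0)
        M_i = np.linalg.inv(P_i + Lam_b)
        x_i = X.matrix[i]
        W_i = Lam_b - Lam_b @ M_i @ Lam_b
        A_sum += np.kron(np.outer(x_i, x_i), W_i)
        l_sum += np.kron(x_i, Lam_b @ M_i @ b_i)
        _, ldM = np.linalg.slogdet(M_i)
        _, ldLb = np.linalg.slogdet(Lam_b)
        F_subjects += 0.5 * (float(b_i @ (M_i @ b_i)) + ldM + ldLb)

    P_post = P_beta + A_sum
    Sigma_beta = np.linalg.inv(P_post)
    mu_beta = Sigma_beta @ l_sum
    _, ldPp = np.linalg.slogdet(P_post)
    _, ldCb = np.linalg.slogdet(C_beta)
    F = F_subjects + 0.5 * (-ldPp - ldCb + float(mu_beta @ (P_post @ mu_beta)))
    return PEBPosterior(
        beta=mu_beta.reshape(k, p),
        covariance=Sigma_beta,
        free_energy=float(F),
        design=X,
        param_indices=idx,
        random_effect_var=sigma_b,
        prior_cov=C_beta,
    )


# ---------------------------------------------------------------------------
# model search and averaging


@dataclass
class ScoredModel:
    mask: np.ndarray  # boolean over switchable params (difference effects)
    delta_f: float  # log evidence relative to the full model
    mean: np.ndarray  # reduced posterior mean over flattened beta
    cov: np.ndarray


@dataclass
class ModelSpace:
    peb: PEBPosterior
    models: list[ScoredModel]
    covariate: int  # which covariate's effects were switched
    strategy: str


def _reduced_prior(
    peb: PEBPosterior, mask: np.ndarray, covariate: int
) -> tuple[np.ndarray, np.ndarray]:
    p = peb.n_params
    var = np.diag(peb.prior_cov).copy()
    off = np.where(~mask)[0] + covariate * p
    var[off] = PIN_VARIANCE
    return np.zeros(var.size), np.diag(var)


def model_search(
    peb: PEBPosterior,
    strategy: str = "exhaustive",
    covariate: int | None = None,
) -> ModelSpace:
    """Score on/off patterns of one covariate's effects by model reduction.

    ``exhaustive`` scores all 2^p patterns (p <= 16 enforced); ``greedy``
    iteratively discards the parameter whose removal improves the evidence
    most, stopping when every remaining discard would reduce it.
    """
    cov_idx = peb.n_covariates - 1 if covariate is None else covariate
    p = peb.n_params
    prior = (np.zeros(peb.prior_cov.shape[0]), peb.prior_cov)
    posterior = (peb.beta.ravel(), peb.covariance)

    def score(mask: np.ndarray) -> ScoredModel:
        d, (mp, cp) = bmr(prior, posterior, _reduced_prior(peb, mask, cov_idx))
        return ScoredModel(mask.copy(), d, mp, cp)

    if strategy == "exhaustive":
        if p > 16:
            raise ValueError(
                f"{p} switchable parameters is too many for exhaustive "
                "search (2^p models); use strategy='greedy'"
            )
        models = []
        for code in range(2**p):
            mask = np.array([(code >> j) & 1 == 1 for j in range(p)])
            models.append(score(mask))
    elif strategy == "greedy":
        current = np.ones(p, dtype=bool)
        models = [score(current)]
        best_f = models[0].delta_f
        while current.any():
            candidates = []
            for j in np.where(current)[0]:
                mask = current.copy()
                mask[j] = False
                candidates.append(score(mask))
            cand_best = max(candidates, key=lambda s: s.delta_f)
            models.extend(candidates)
            if cand_best.delta_f >= best_f:
                current = cand_best.mask
                best_f = cand_best.delta_f
            else:
                break
    else:
        raise ValueError("strategy must be 'exhaustive' or 'greedy'")
    return ModelSpace(peb, models, cov_idx, strategy)


@dataclass
class BMAResult:
    """Per-connection averaged effects and posterior inclusion probabilities."""

    expected_effect: np.ndarray  # (covariates x couplings)
    pp: np.ndarray  # inclusion probability per coupling (switched covariate)
    covariate: int
    model_probs: np.ndarray  # probabilities of the averaged models
    model_masks: np.ndarray  # (n_averaged, couplings)
    param_indices: np.ndarray

    @property
    def n_params(self) -> int:
        return self.pp.size


def bma(space: ModelSpace, top: int = 256) -> BMAResult:
    """Bayesian model average over the best ``top`` models.

    Model weights are the softmax of the reduced log evidences; a
    connection's posterior probability is the total weight of averaged
    models in which its group effect is switched on.
    """
    if not space.models:
        raise ValueError("empty model space")
    models = sorted(space.models, key=lambda s: s.delta_f, reverse=True)[:top]
    lf = np.array([s.delta_f for s in models])
    w = np.exp(lf - lf.max())
    w /= w.sum()
    k = space.peb.n_covariates
    p = space.peb.n_params
    masks = np.array([s.mask for s in models])
    pp = np.clip((w[:, None] * masks).sum(axis=0), 0.0, 1.0)
    means = np.array([s.mean for s in models])  # (n, k*p)
    expected = (w[:, None] * means).sum(axis=0).reshape(k, p)
    return BMAResult(
        expected_effect=expected,
        pp=pp,
        covariate=space.covariate,
        model_probs=w,
        model_masks=masks,
        param_indices=space.peb.param_indices,
    )


@dataclass
class ThresholdedBMA:
    retained: list[int]  # connection positions with pp > threshold
    faded: list[int]
    threshold: float
    bma: BMAResult


def threshold_bma(result: BMAResult, pp: float = 0.99) -> ThresholdedBMA:
    """Retain connections whose inclusion probability strictly exceeds ``pp``."""
    if not 0.0 < pp < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    retained = [int(j) for j in range(result.n_params) if result.pp[j] > pp]
    faded = [int(j) for j in range(result.n_params) if result.pp[j] <= pp]
    return ThresholdedBMA(retained, faded, pp, result)
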