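"""Variational Laplace inversion of the spectral generative model.

The observed cross-spectra are vectorized into real features (real upper
triangle including the diagonal, then imaginary strict upper triangle, per
frequency) and modelled as Gaussian around the model prediction with one
log-precision hyperparameter per feature block (real / imaginary), shared
across frequencies.  A Gauss-Newton ascent with Levenberg-Marquardt damping
maximizes the Laplace free energy F (a lower bound on log evidence); noise
precisions are updated by Newton steps between parameter updates.  Accepted
iterations never decrease F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import json
import numpy as np

from .csd import CSDData, LeadField
from .model import UnstableModelError, predict_csd
from .network import NetworkSpec
from .params import DCMParams, load_constants, prior_variance_vector


# ---------------------------------------------------------------------------
# featurization


def featurize_csd(data: CSDData) -> tuple[np.ndarray, np.ndarray]:
    """Vectorize Hermitian cross-spectra into real features.

    Returns ``(y, blocks)`` where per frequency the features are the real
    upper triangle including the diagonal followed by the strict-upper
    imaginary parts; ``blocks`` is 0 for real features and 1 for imaginary.
    """
    data.validate(hermitian_tol=1e-8)
    m = data.n_channels
    iu = np.triu_indices(m)
    iu1 = np.triu_indices(m, 1)
    re = data.csd.real[:, iu[0], iu[1]]  # (F, m(m+1)/2)
    im = data.csd.imag[:, iu1[0], iu1[1]]  # (F, m(m-1)/2)
    y = np.concatenate([re, im], axis=1).ravel()
    blk = np.concatenate(
        [np.zeros(re.shape[1], dtype=int), np.ones(im.shape[1], dtype=int)]
    )
    blocks = np.tile(blk, data.n_freqs)
    return y, blocks


def defeaturize_csd(y: np.ndarray, freqs: np.ndarray, m: int, meta: dict | None = None) -> CSDData:
    """Exact inverse of :func:`featurize_csd`."""
    F = len(freqs)
    nre = m * (m + 1) // 2
    nim = m * (m - 1) // 2
    y = np.asarray(y, dtype=float).reshape(F, nre + nim)
    iu = np.triu_indices(m)
    iu1 = np.triu_indices(m, 1)
    csd = np.zeros((F, m, m), dtype=complex)
    csd[:, iu[0], iu[1]] += y[:, :nre]
    csd[:, iu1[0], iu1[1]] += 1j * y[:, nre:]
    lower = csd.conj().transpose(0, 2, 1).copy()
    diag = np.einsum("fii->fi", csd).copy()
    csd += lower
    for f in range(F):
        np.fill_diagonal(csd[f], diag[f])
    return CSDData(np.asarray(freqs, dtype=float), csd, dict(meta or {}))


def _featurize_matrix(G: np.ndarray, m: int) -> np.ndarray:
    iu = np.triu_indices(m)
    iu1 = np.triu_indices(m, 1)
    re = G.real[:, iu[0], iu[1]]
    im = G.imag[:, iu1[0], iu1[1]]
    return np.concatenate([re, im], axis=1).ravel()


# ---------------------------------------------------------------------------
# priors and posteriors


@dataclass
class PriorSpec:
    """Gaussian shrinkage prior over the parameter vector plus hyperpriors.

    ``variance`` is the diagonal of the prior covariance; entries with zero
    variance are fixed at the prior mean and excluded from estimation.
    ``hyper_mean`` / ``hyper_var`` parameterize the Gaussian prior over the
    log noise precisions of the feature blocks (relative to normalized
    features).
    """

    mean: np.ndarray = field(
        default_factory=lambda: np.zeros(DCMParams.n_params())
    )
    variance: np.ndarray = field(default_factory=prior_variance_vector)
    hyper_mean: float = 0.0
    hyper_var: float = 16.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("prior mean and variance dimensions differ")
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be non-negative")

    @property
    def free(self) -> np.ndarray:
        return self.variance > 0


@dataclass
class Posterior:
    """Gaussian approximate posterior with its negative free energy.

    ``mean`` and ``covariance`` span the full parameter vector (fixed
    entries keep the prior mean and zero variance).  ``trace`` records the
    free energy after each accepted iteration; ``hyper`` summarizes the
    posterior log precisions per feature block.
    """

    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    trace: list = field(default_factory=list)
    hyper: dict = field(default_factory=dict)
    converged: bool = True

    def marginal(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.asarray(idx)
        return self.mean[idx], self.covariance[np.ix_(idx, idx)]

    def credible_interval(self, i: int, level: float = 0.9) -> tuple[float, float]:
        from scipy.stats import norm

        sd = float(np.sqrt(self.covariance[i, i]))
        z = norm.ppf(0.5 + level / 2)
        return self.mean[i] - z * sd, self.mean[i] + z * sd

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "meta.json").write_text(
            json.dumps(
                {
                    "free_energy": self.free_energy,
                    "trace": list(map(float, self.trace)),
                    "hyper": {k: float(v) for k, v in self.hyper.items()},
                    "converged": bool(self.converged),
                },
                indent=2,
            )
        )
        np.savez(path / "arrays.npz", mean=self.mean, covariance=self.covariance)

    @classmethod
    def load(cls, path: str | Path) -> "Posterior":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        with np.load(path / "arrays.npz") as z:
            mean = z["mean"]
            cov = z["covariance"]
        return cls(
            mean=mean,
            covariance=cov,
            free_energy=meta["free_energy"],
            trace=meta["trace"],
            hyper=meta["hyper"],
            converged=meta["converged"],
        )


# ---------------------------------------------------------------------------
# free energy machinery (generic over a forward map on the free parameters)


def _laplace_F(
    r: np.ndarray,
    blocks: np.ndarray,
    lam: np.ndarray,
    e_theta: np.ndarray,
    P0: np.ndarray,
    H: np.ndarray,
    hyper_mean: float,
    hyper_prec: float,
    estimate_hyper: bool,
    tr_corr: float = 0.0,
) -> float:
    """Laplace free energy for residuals r at the current posterior mode."""
    pi = np.exp(lam)[blocks]
    N = r.size
    counts = np.bincount(blocks, minlength=lam.size)
    F = -0.5 * float(r @ (pi * r)) - 0.5 * tr_corr
    F += 0.5 * float(counts @ lam) - 0.5 * N * np.log(2 * np.pi)
    F += -0.5 * float(e_theta @ (P0 @ e_theta))
    sign0, ld0 = np.linalg.slogdet(P0)
    signH, ldH = np.linalg.slogdet(H)
    F += 0.5 * (ld0 - ldH)
    if estimate_hyper:
        dl = lam - hyper_mean
        F += -0.5 * hyper_prec * float(dl @ dl)
        # Laplace term for the hyperposterior
        hess = np.exp(lam) * np.array(
            [float(r[blocks == b] @ r[blocks == b]) for b in range(lam.size)]
        ) + hyper_prec
        F += 0.5 * float(np.sum(np.log(hyper_prec) - np.log(hess)))
    return F


def _numeric_jacobian(
    forward: Callable[[np.ndarray], np.ndarray],
    theta: np.ndarray,
    step: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference Jacobian of the forward map (features x params)."""
    g0 = forward(theta)
    J = np.empty((g0.size, theta.size))
    for k in range(theta.size):
        tp = theta.copy()
        tm = theta.copy()
        tp[k] += step
        tm[k] -= step
        J[:, k] = (forward(tp) - forward(tm)) / (2 * step)
    return g0, J


@dataclass
class FitOptions:
    """Options for the variational-Laplace loop.

    ``refine`` > 0 re-weights the Laplace posterior by that many importance
    draws (proposal: the Laplace Gaussian inflated by ``refine_inflate``)
    and replaces mean/covariance by the weighted moments; this corrects the
    left-skew the Gaussian approximation misses on log-scaling parameters.
    """

    max_iter: int = 128
    tol: float = 1e-2
    fd_step: float = 1e-4
    estimate_hyper: bool = True
    lm_init: float = 0.25
    max_rejects: int = 6
    refine: int = 0
    refine_inflate: float = 1.4
    refine_seed: int = 0


def fit_vl_features(
    y: np.ndarray,
    blocks: np.ndarray,
    forward: Callable[[np.ndarray], np.ndarray],
    mu0: np.ndarray,
    var0: np.ndarray,
    hyper_mean: float = 0.0,
    hyper_var: float = 16.0,
    lam_init: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> tuple[np.ndarray, np.ndarray, float, list, np.ndarray, bool]:
    """Variational Laplace over a generic forward map on free parameters.

    Returns (mean, covariance, F, trace, lam, converged) over the free
    parameter space.  ``forward`` may raise :class:`UnstableModelError` for
    infeasible candidates; such steps are rejected.
    """
    opt = options or FitOptions()
    n_blocks = int(blocks.max()) + 1
    P0 = np.diag(1.0 / var0)
    hyper_prec = 1.0 / hyper_var
    theta = mu0.copy()
    lam = (
        np.full(n_blocks, hyper_mean, dtype=float)
        if lam_init is None
        else lam_init.astype(float).copy()
    )
    counts = np.bincount(blocks, minlength=n_blocks).astype(float)

    def blk_sq(r: np.ndarray) -> np.ndarray:
        return np.array([float(r[blocks == b] @ r[blocks == b]) for b in range(n_blocks)])

    def update_lam(lam, rsq, trb):
        # Newton ascent on the (concave) lambda objective
        lam = lam.copy()
        for _ in range(8):
            e = np.exp(lam)
            grad = 0.5 * (counts - e * (rsq + trb)) - hyper_prec * (lam - hyper_mean)
            hess = 0.5 * e * (rsq + trb) + hyper_prec
            step = grad / hess
            lam = lam + np.clip(step, -4, 4)
            if np.abs(step).max() < 1e-8:
                break
        return lam

    def assemble(J, r, lam):
        pi = np.exp(lam)[blocks]
        Jw = J * pi[:, None]
        H = J.T @ Jw + P0
        Sigma = np.linalg.inv(H)
        if opt.estimate_hyper:
            trb = np.array(
                [
                    float(
                        np.einsum(
                            "ij,ji->", J[blocks == b].T @ J[blocks == b], Sigma
                        )
                    )
                    for b in range(n_blocks)
                ]
            )
            lam = update_lam(lam, blk_sq(r), trb)
            pi = np.exp(lam)[blocks]
            Jw = J * pi[:, None]
            H = J.T @ Jw + P0
            Sigma = np.linalg.inv(H)
        return lam, Jw, H, Sigma

    g0, J = _numeric_jacobian(forward, theta, opt.fd_step)
    r = y - g0
    nu = opt.lm_init
    trace: list[float] = []
    converged = False
    n_accepted = 0

    lam, Jw, H, Sigma = assemble(J, r, lam)
    F_best = _laplace_F(
        r, blocks, lam, theta - mu0, P0, H, hyper_mean, hyper_prec, opt.estimate_hyper
    )
    trace.append(F_best)
    best = (theta.copy(), lam.copy(), r.copy(), J, Jw, H, Sigma)

    for _it in range(opt.max_iter):
        theta_b, lam_b, r_b, J_b, Jw_b, H_b, Sigma_b = best
        # propose a damped Gauss-Newton step from the best point
        grad = Jw_b.T @ r_b - P0 @ (theta_b - mu0)
        cand = None
        for _try in range(opt.max_rejects):
            Hd = H_b + nu * np.diag(np.diag(H_b))
            dtheta = np.linalg.solve(Hd, grad)
            try:
                g_c = forward(theta_b + dtheta)
                cand = theta_b + dtheta
                break
            except (UnstableModelError, FloatingPointError, RuntimeError):
                nu *= 8
        if cand is None:
            converged = n_accepted > 0
            break
        r_c = y - g_c
        _, J_c = _numeric_jacobian(forward, cand, opt.fd_step)
        lam_c, Jw_c, H_c, Sigma_c = assemble(J_c, r_c, lam_b)
        F_c = _laplace_F(
            r_c, blocks, lam_c, cand - mu0, P0, H_c, hyper_mean, hyper_prec,
            opt.estimate_hyper,
        )
        if F_c > F_best - 1e-12:
            dF = F_c - F_best
            F_best = max(F_c, F_best)
            best = (cand.copy(), lam_c.copy(), r_c.copy(), J_c, Jw_c, H_c, Sigma_c)
            trace.append(F_best)
            n_accepted += 1
            nu = max(nu / 2, 1e-8)
            if dF < opt.tol:
                converged = True
                break
        else:
            nu *= 8
            if nu > 1e7:
                converged = n_accepted > 0
                break

    theta, lam, r, J, Jw, H, Sigma = best
    return theta, Sigma, F_best, trace, lam, converged


# ---------------------------------------------------------------------------
# CSD-specific wrappers


def _feature_weights(y: np.ndarray, n_freqs: int) -> np.ndarray:
    """Per-frequency normalization of the feature vector.

    Finite-epoch sampling noise on a spectral matrix scales with the local
    spectral magnitude, so features at each frequency are divided by the
    root-mean-square of the observed features there; the remaining noise is
    then approximately homoscedastic across the grid.
    """
    per_f = y.reshape(n_freqs, -1)
    rms = np.sqrt(np.mean(per_f**2, axis=1))
    rms = np.maximum(rms, 1e-30)
    return np.repeat(1.0 / rms, per_f.shape[1])


def _make_forward(
    priors: PriorSpec,
    spec: NetworkSpec,
    lead: LeadField,
    freqs: np.ndarray,
    constants: dict | None,
    scale: np.ndarray,
    m: int,
):
    free = priors.free

    def forward(theta_free: np.ndarray) -> np.ndarray:
        full = priors.mean.copy()
        full[free] = theta_free
        params = DCMParams.from_vector(full)
        G = predict_csd(params, spec, lead, freqs, constants)
        return _featurize_matrix(G.csd, m) * scale

    return forward


def free_energy(
    candidate: np.ndarray,
    data: CSDData,
    priors: PriorSpec,
    hyper: np.ndarray,
    spec: NetworkSpec,
    lead: LeadField,
    constants: dict | None = None,
) -> float:
    """Laplace free energy of a full candidate parameter vector.

    ``hyper`` gives the log precisions of the (normalized) real and
    imaginary feature blocks.  Unstable candidates receive a large penalty
    proportional to the stability violation rather than an exception.
    """
    y, blocks = featurize_csd(data)
    scale = _feature_weights(y, data.n_freqs)
    y = y * scale
    free = priors.free
    forward = _make_forward(
        priors, spec, lead, data.freqs, constants, scale, data.n_channels
    )
    theta = np.asarray(candidate, dtype=float)[free]
    P0 = np.diag(1.0 / priors.variance[free])
    try:
        g0, J = _numeric_jacobian(forward, theta)
    except UnstableModelError as err:
        margin = float(str(err).split()[-1].rstrip(")")) if "eigenvalue" in str(err) else 1.0
        return -1e8 * (1.0 + abs(margin))
    lam = np.asarray(hyper, dtype=float)
    pi = np.exp(lam)[blocks]
    H = J.T @ (J * pi[:, None]) + P0
    return _laplace_F(
        y - g0,
        blocks,
        lam,
        theta - priors.mean[free],
        P0,
        H,
        priors.hyper_mean,
        1.0 / priors.hyper_var,
        estimate_hyper=False,
    )


def _complex_wishart_const(W: np.ndarray, n: int) -> float:
    """theta-independent part of the complex-Wishart log density of W."""
    from scipy.special import gammaln

    m = W.shape[-1]
    ld = np.linalg.slogdet(W)[1].real
    lgam = m * (m - 1) / 2 * np.log(np.pi) + sum(gammaln(n - j) for j in range(m))
    return float(np.sum((n - m) * ld) + W.shape[0] * (n * m * np.log(n) - lgam))


def _wishart_loglik(W: np.ndarray, G: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    """log p(W | G) under the scaled complex Wishart and G^-1 per frequency.

    W is the observed spectral matrix stack (an average of n outer products
    of circular complex Gaussians with mean spectrum G), so
    ll = sum_f n * (-logdet G_f - tr(G_f^-1 W_f)) + const(W, n).
    """
    Ginv = np.linalg.inv(G)
    ld = np.linalg.slogdet(G)[1].real
    tr = np.einsum("fij,fji->f", Ginv, W).real
    return float(n * np.sum(-ld - tr)), Ginv


def fit_vl_wishart(
    y_csd: np.ndarray,
    dof: int,
    forward_csd: Callable[[np.ndarray], np.ndarray],
    mu0: np.ndarray,
    var0: np.ndarray,
    options: FitOptions | None = None,
    jacobian_csd: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float, list, bool]:
    """Variational Laplace under the complex-Wishart spectral likelihood.

    ``forward_csd`` maps free parameters to the predicted (F, m, m) spectral
    stack.  Fisher scoring with Levenberg-Marquardt damping maximizes
    F = ll(theta) - KL complexity; the observation noise level needs no
    hyperparameters because the Wishart degrees of freedom (number of
    averaged epochs) set it.
    """
    opt = options or FitOptions()
    P0 = np.diag(1.0 / var0)
    sign0, ld0 = np.linalg.slogdet(P0)
    const = _complex_wishart_const(y_csd, dof)
    theta = mu0.copy()

    def laplace_F(ll: float, e: np.ndarray, H: np.ndarray) -> float:
        signH, ldH = np.linalg.slogdet(H)
        return ll + const - 0.5 * float(e @ (P0 @ e)) + 0.5 * (ld0 - ldH)

    def forward_with_jac(th: np.ndarray):
        if jacobian_csd is not None:
            return jacobian_csd(th)
        G = forward_csd(th)
        p = th.size
        D = np.empty((p,) + G.shape, dtype=complex)
        for k in range(p):
            tp = th.copy()
            tm = th.copy()
            tp[k] += opt.fd_step
            tm[k] -= opt.fd_step
            D[k] = (forward_csd(tp) - forward_csd(tm)) / (2 * opt.fd_step)
        return G, D

    def derivatives(G: np.ndarray, Ginv: np.ndarray, D: np.ndarray):
        A = Ginv @ (y_csd - G) @ Ginv  # (F, m, m)
        grad = dof * np.einsum("fab,kfba->k", A, D).real
        M = np.einsum("fab,kfbc->kfac", Ginv, D)
        H_f = dof * np.einsum("kfab,lfba->kl", M, M).real
        return grad, H_f

    G, D = forward_with_jac(theta)
    ll, Ginv = _wishart_loglik(y_csd, G, dof)
    grad, H_f = derivatives(G, Ginv, D)
    H = H_f + P0
    F_best = laplace_F(ll, theta - mu0, H)
    trace = [F_best]
    best = (theta.copy(), grad - P0 @ (theta - mu0), H)
    nu = opt.lm_init
    converged = False
    n_accepted = 0

    for _it in range(opt.max_iter):
        theta_b, grad_b, H_b = best
        cand = None
        for _try in range(opt.max_rejects):
            Hd = H_b + nu * np.diag(np.diag(H_b))
            dtheta = np.linalg.solve(Hd, grad_b)
            try:
                G_c, D_c = forward_with_jac(theta_b + dtheta)
                cand = theta_b + dtheta
                break
            except (UnstableModelError, FloatingPointError, RuntimeError):
                nu *= 8
        if cand is None:
            converged = n_accepted > 0
            break
        ll_c, Ginv_c = _wishart_loglik(y_csd, G_c, dof)
        grad_c, Hf_c = derivatives(G_c, Ginv_c, D_c)
        H_c = Hf_c + P0
        F_c = laplace_F(ll_c, cand - mu0, H_c)
        if F_c > F_best - 1e-12:
            dF = F_c - F_best
            F_best = max(F_c, F_best)
            best = (cand.copy(), grad_c - P0 @ (cand - mu0), H_c)
            trace.append(F_best)
            n_accepted += 1
            nu = max(nu / 2, 1e-8)
            if dF < opt.tol:
                converged = True
                break
        else:
            nu *= 8
            if nu > 1e7:
                converged = n_accepted > 0
                break

    theta, _, H = best
    Sigma = np.linalg.inv(H)
    return theta, Sigma, F_best, trace, converged


def _importance_refine(
    theta: np.ndarray,
    Sigma: np.ndarray,
    forward_csd: Callable[[np.ndarray], np.ndarray],
    y_csd: np.ndarray,
    dof: int,
    mu0: np.ndarray,
    var0: np.ndarray,
    n_draws: int,
    inflate: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Moment-match the exact posterior by importance re-weighting."""
    rng = np.random.default_rng(seed)
    Lc = np.linalg.cholesky(Sigma * inflate + 1e-12 * np.eye(theta.size))
    zs = rng.standard_normal((n_draws, theta.size))
    ths = theta + zs @ Lc.T
    logq = -0.5 * np.einsum("ij,ij->i", zs, zs)
    lw = np.full(n_draws, -np.inf)
    for i in range(n_draws):
        try:
            G = forward_csd(ths[i])
        except (UnstableModelError, FloatingPointError, RuntimeError):
            continue
        ll, _ = _wishart_loglik(y_csd, G, dof)
        lp = -0.5 * float(np.sum((ths[i] - mu0) ** 2 / var0))
        lw[i] = ll + lp - logq[i]
    lw -= lw.max()
    w = np.exp(lw)
    # truncate the largest weights (Ionides 2008) to bound estimator variance
    w = np.minimum(w, w.mean() * np.sqrt(n_draws))
    w /= w.sum()
    ess = float(1.0 / np.sum(w**2))
    if ess < 10:  # too few effective draws to trust the correction
        return theta, Sigma, ess, ths, w
    # refine the mean only: the first-order correction is robust at modest
    # effective sample sizes, whereas re-weighted covariances degenerate in
    # this many dimensions and can report wildly overconfident precisions
    m = w @ ths
    return m, Sigma, ess, ths, w


def _averaged_fisher_cov(
    ths: np.ndarray,
    w: np.ndarray,
    fisher_fn: Callable[[np.ndarray], np.ndarray],
    P0: np.ndarray,
    n_points: int = 8,
) -> np.ndarray | None:
    """Posterior covariance from weight-averaged expected information.

    The local curvature of this likelihood varies by orders of magnitude
    along narrow ridges, so the Fisher information at the mode alone can be
    wildly overconfident; averaging it over highly weighted posterior draws
    restores an honest scale.
    """
    order = np.argsort(w)[::-1][:n_points]
    acc = np.zeros_like(P0)
    tot = 0.0
    for i in order:
        if w[i] <= 0:
            continue
        try:
            acc += w[i] * fisher_fn(ths[i])
            tot += w[i]
        except (UnstableModelError, FloatingPointError, RuntimeError):
            continue
    if tot <= 0:
        return None
    return np.linalg.inv(acc / tot + P0)


def fit_vl(
    data: CSDData,
    priors: PriorSpec,
    spec: NetworkSpec,
    lead: LeadField,
    constants: dict | None = None,
    options: FitOptions | None = None,
    likelihood: str = "auto",
) -> Posterior:
    """Fit the spectral model to one subject's observed cross-spectra.

    With ``likelihood="wishart"`` (the default whenever the data's metadata
    records the number of averaged epochs) the observed spectral matrices
    are scored by the complex-Wishart density whose degrees of freedom equal
    that epoch count -- the exact sampling distribution of an epoch-averaged
    cross-spectrum of Gaussian data.  ``likelihood="gaussian"`` falls back
    to independent Gaussian features (real/imaginary blocks) with noise
    precisions estimated as hyperparameters.
    """
    if priors.mean.size != DCMParams.n_params():
        raise ValueError("prior dimension does not match the parameter vector")
    if likelihood == "auto":
        likelihood = "wishart" if data.meta.get("n_epochs") else "gaussian"
    free = priors.free
    mu0 = priors.mean[free]
    var0 = priors.variance[free]

    if likelihood == "wishart":
        dof = int(data.meta["n_epochs"])
        if dof < data.n_channels:
            raise ValueError("n_epochs must be >= channel count for Wishart scoring")

        def forward_csd(theta_free: np.ndarray) -> np.ndarray:
            full = priors.mean.copy()
            full[free] = theta_free
            params = DCMParams.from_vector(full)
            return predict_csd(params, spec, lead, data.freqs, constants).csd

        # analytic derivatives cover the default free set (couplings via the
        # rank-one Jacobian perturbation, amplitudes via the component
        # decomposition); finite differences handle anything else
        from .model import predict_csd_jacobian

        free_idx = np.where(free)[0]
        opt0 = options or FitOptions()

        def jacobian_csd(theta_free: np.ndarray):
            full = priors.mean.copy()
            full[free] = theta_free
            params = DCMParams.from_vector(full)
            G, Dmap = predict_csd_jacobian(params, spec, lead, data.freqs, constants)
            p = theta_free.size
            D = np.empty((p,) + G.shape, dtype=complex)
            for pos, gi in enumerate(free_idx):
                if gi in Dmap:
                    D[pos] = Dmap[gi]
                else:
                    tp = theta_free.copy()
                    tm = theta_free.copy()
                    tp[pos] += opt0.fd_step
                    tm[pos] -= opt0.fd_step
                    D[pos] = (forward_csd(tp) - forward_csd(tm)) / (2 * opt0.fd_step)
            return G, D

        def fisher_fn(theta_free: np.ndarray) -> np.ndarray:
            G, D = jacobian_csd(theta_free)
            Ginv = np.linalg.inv(G)
            M = np.einsum("fab,kfbc->kfac", Ginv, D)
            return dof * np.einsum("kfab,lfba->kl", M, M).real

        theta, Sigma, F, trace, converged = fit_vl_wishart(
            data.csd, dof, forward_csd, mu0, var0, options=options,
            jacobian_csd=jacobian_csd,
        )
        hyper = {"wishart_dof": float(dof)}
        opt = options or FitOptions()
        if opt.refine > 0:
            theta, Sigma, ess, ths, w = _importance_refine(
                theta,
                Sigma,
                forward_csd,
                data.csd,
                dof,
                mu0,
                var0,
                opt.refine,
                opt.refine_inflate,
                opt.refine_seed,
            )
            hyper["refine_ess"] = ess
            if ess >= 10:
                P0 = np.diag(1.0 / var0)
                S_avg = _averaged_fisher_cov(ths, w, fisher_fn, P0)
                if S_avg is not None:
                    Sigma = S_avg
    elif likelihood == "gaussian":
        y, blocks = featurize_csd(data)
        scale = _feature_weights(y, data.n_freqs)
        forward = _make_forward(
            priors, spec, lead, data.freqs, constants, scale, data.n_channels
        )
        theta, Sigma, F, trace, lam, converged = fit_vl_features(
            y * scale,
            blocks,
            forward,
            mu0,
            var0,
            priors.hyper_mean,
            priors.hyper_var,
            options=options,
        )
        hyper = {f"lambda_{b}": float(lam[b]) for b in range(lam.size)}
    else:
        raise ValueError("likelihood must be 'auto', 'wishart' or 'gaussian'")

    n = priors.mean.size
    mean = priors.mean.copy()
    mean[free] = theta
    cov = np.zeros((n, n))
    cov[np.ix_(np.where(free)[0], np.where(free)[0])] = Sigma
    return Posterior(
        mean=mean,
        covariance=cov,
        free_energy=F,
        trace=trace,
        hyper=hyper,
        converged=converged,
    )
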