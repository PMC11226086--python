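"""Biophysical generative model: neural mass dynamics to predicted cross-spectra.

Each source is a convolution-based neural mass (Jansen-Rit kinetics) with
three populations -- granular spiny stellate cells, pyramidal output cells
and inhibitory interneurons -- coupled through excitatory (He, tau_e) and
inhibitory (Hi, tau_i) synaptic kernels and a centred sigmoid firing
function.  Sources are coupled by typed extrinsic connections: forward
connections drive the stellate population, backward connections the
pyramidal cells and inhibitory interneurons, lateral connections all three.

The predicted cross-spectral density is obtained by linearizing the
dynamics about their fixed point and propagating per-source innovations
spectra through the resulting transfer functions and the lead field:

    G(f) = g^2 L T(f) Gu(f) T(f)^H L^T + Gn(f)

with Gu diagonal (white + 1/f^beta mixture per source) and Gn the channel
noise (channel-specific diagonal + common rank-one term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .csd import CSDData, LeadField
from .network import NetworkSpec
from .params import DCMParams, INTRINSIC_FIELDS, load_constants

N_STATES_PER_SOURCE = 8
# state columns: 0 v_stellate, 1 v_pyr_exc, 2 v_pyr_inh, 3 i_stellate,
#                4 i_pyr_exc, 5 i_pyr_inh, 6 v_iin, 7 i_iin


class UnstableModelError(RuntimeError):
    """Raised when the linearized dynamics have a non-decaying mode."""


@dataclass
class CompiledModel:
    """Parameters resolved against the constants table, ready for evaluation."""

    He: np.ndarray  # (4,) mV
    Hi: np.ndarray
    tau_e: np.ndarray  # (4,) s
    tau_i: np.ndarray
    g: np.ndarray  # (4, 4) intrinsic gains g1..g4 per source
    slope_scale: float
    AF: np.ndarray  # (4, 4) forward weights, [target, source]
    AB: np.ndarray
    AL: np.ndarray
    sig_e0: float
    sig_r: float
    sig_v0: float
    innov_amp: np.ndarray  # (4,) spectral amplitudes
    innov_beta: np.ndarray
    innov_white_frac: float
    innov_f_clamp: float
    noise_specific_amp: float
    noise_specific_beta: float
    noise_common_amp: float
    noise_common_beta: float
    noise_white_frac: float
    noise_f_clamp: float
    lead_gain: float

    # -- sigmoid -----------------------------------------------------------

    def sigmoid(self, v: np.ndarray) -> np.ndarray:
        r = self.sig_r * self.slope_scale
        return 2.0 * self.sig_e0 / (1.0 + np.exp(r * (self.sig_v0 - v))) - (
            2.0 * self.sig_e0 / (1.0 + np.exp(r * self.sig_v0))
        )

    def dsigmoid(self, v: np.ndarray) -> np.ndarray:
        r = self.sig_r * self.slope_scale
        e = np.exp(r * (self.sig_v0 - v))
        return 2.0 * self.sig_e0 * r * e / (1.0 + e) ** 2

    # -- dynamics ----------------------------------------------------------

    def f(self, x: np.ndarray, u: np.ndarray | float = 0.0) -> np.ndarray:
        """State derivative; ``x`` is (4, 8), ``u`` per-source drive (4,)."""
        x = x.reshape(4, N_STATES_PER_SOURCE)
        vp = x[:, 1] - x[:, 2]
        sv = self.sigmoid(vp)
        s1 = self.sigmoid(x[:, 0])
        s7 = self.sigmoid(x[:, 6])
        in_st = self.g[:, 0] * sv + (self.AF + self.AL) @ sv + u
        in_pe = self.g[:, 1] * s1 + (self.AB + self.AL) @ sv
        in_ii = self.g[:, 2] * sv + (self.AB + self.AL) @ sv
        in_pi = self.g[:, 3] * s7

        ke = self.He / self.tau_e
        ki = self.Hi / self.tau_i
        dx = np.empty_like(x)
        dx[:, 0] = x[:, 3]
        dx[:, 1] = x[:, 4]
        dx[:, 2] = x[:, 5]
        dx[:, 6] = x[:, 7]
        dx[:, 3] = ke * in_st - 2.0 * x[:, 3] / self.tau_e - x[:, 0] / self.tau_e**2
        dx[:, 4] = ke * in_pe - 2.0 * x[:, 4] / self.tau_e - x[:, 1] / self.tau_e**2
        dx[:, 5] = ki * in_pi - 2.0 * x[:, 5] / self.tau_i - x[:, 2] / self.tau_i**2
        dx[:, 7] = ke * in_ii - 2.0 * x[:, 7] / self.tau_e - x[:, 6] / self.tau_e**2
        return dx

    def pyramidal_potential(self, x: np.ndarray) -> np.ndarray:
        x = x.reshape(4, N_STATES_PER_SOURCE)
        return x[:, 1] - x[:, 2]

    # -- spectra -----------------------------------------------------------

    def _shape(self, f: np.ndarray, beta: np.ndarray | float, wf: float, fc: float) -> np.ndarray:
        fcl = np.maximum(f, fc)
        return wf + (1.0 - wf) * fcl ** -np.atleast_1d(beta)[..., None]

    def innovations_spectrum(self, freqs: np.ndarray) -> np.ndarray:
        """One-sided PSD of the per-source neuronal innovations, (4, F)."""
        shape = self._shape(freqs, self.innov_beta, self.innov_white_frac, self.innov_f_clamp)
        return self.innov_amp[:, None] * shape

    def channel_noise(self, freqs: np.ndarray, n_channels: int) -> np.ndarray:
        """One-sided PSD of the observation noise, (F, m, m)."""
        spec = self.noise_specific_amp * self._shape(
            freqs, self.noise_specific_beta, self.noise_white_frac, self.noise_f_clamp
        )[0]
        comm = self.noise_common_amp * self._shape(
            freqs, self.noise_common_beta, self.noise_white_frac, self.noise_f_clamp
        )[0]
        eye = np.eye(n_channels)
        ones = np.ones((n_channels, n_channels))
        return spec[:, None, None] * eye + comm[:, None, None] * ones


def compile_model(
    params: DCMParams, spec: NetworkSpec, constants: dict | None = None
) -> CompiledModel:
    """Resolve log-scaling parameters against the constants table."""
    params.check_finite()
    c = constants or load_constants()
    syn = c["synaptic"]
    gains = c["intrinsic_gains"]
    sig = c["sigmoid"]
    cpm = c["coupling_prior_means"]
    innov = c["innovations"]
    noise = c["channel_noise"]

    sc = np.exp(params.intrinsic)  # (4, 8) multiplicative scalings
    He = syn["He"] * sc[:, 0]
    Hi = syn["Hi"] * sc[:, 1]
    tau_e = syn["tau_e"] * sc[:, 2]
    tau_i = syn["tau_i"] * sc[:, 3]
    g = np.array([gains["g1"], gains["g2"], gains["g3"], gains["g4"]]) * sc[:, 4:8]

    AF = np.zeros((4, 4))
    AB = np.zeros((4, 4))
    AL = np.zeros((4, 4))
    mats = {"forward": AF, "backward": AB, "lateral": AL}
    for k, e in enumerate(spec.edges):
        t = spec.node_index(e.target)
        s = spec.node_index(e.source)
        mats[e.type][t, s] = cpm[e.type] * np.exp(params.a[k])

    return CompiledModel(
        He=He,
        Hi=Hi,
        tau_e=tau_e,
        tau_i=tau_i,
        g=g,
        slope_scale=float(np.exp(params.sigmoid_slope)),
        AF=AF,
        AB=AB,
        AL=AL,
        sig_e0=sig["e0"],
        sig_r=sig["r"],
        sig_v0=sig["v0"],
        innov_amp=innov["amp"] * np.exp(params.innov_amp),
        innov_beta=innov["beta"] * np.exp(params.innov_beta),
        innov_white_frac=innov["white_frac"],
        innov_f_clamp=innov["f_clamp"],
        noise_specific_amp=noise["specific_amp"] * np.exp(params.noise_specific_amp),
        noise_specific_beta=noise["beta"] * np.exp(params.noise_specific_beta),
        noise_common_amp=noise["common_amp"] * np.exp(params.noise_common_amp),
        noise_common_beta=noise["beta"] * np.exp(params.noise_common_beta),
        noise_white_frac=noise["white_frac"],
        noise_f_clamp=noise["f_clamp"],
        lead_gain=float(np.exp(params.lead_gain)),
    )


# ---------------------------------------------------------------------------
# operations


def equilibrium(
    params: DCMParams,
    spec: NetworkSpec,
    constants: dict | None = None,
) -> np.ndarray:
    """Fixed point of the deterministic dynamics (flattened state vector).

    With the centred sigmoid and no baseline drive the origin is the
    operating point; it is located by damped root finding so that perturbed
    constants remain supported.
    """
    model = compile_model(params, spec, constants)
    return _equilibrium_impl(model)


def _equilibrium_impl(model: CompiledModel) -> np.ndarray:
    def fun(xf: np.ndarray) -> np.ndarray:
        return model.f(xf.reshape(4, N_STATES_PER_SOURCE)).ravel()

    x0 = np.zeros(4 * N_STATES_PER_SOURCE)
    # with the centred sigmoid and no drive the origin is exact; only fall
    # back to root finding when a perturbed constants table moves it
    if np.abs(fun(x0)).max() < 1e-12:
        return x0
    sol = optimize.root(fun, x0, method="hybr", tol=1e-12)
    resid = np.abs(fun(sol.x)).max()
    if resid > 1e-8:
        raise RuntimeError(
            f"equilibrium search did not converge (worst residual {resid:g})"
        )
    return sol.x


def jacobian(
    params: DCMParams,
    spec: NetworkSpec,
    x_star: np.ndarray,
    constants: dict | None = None,
) -> np.ndarray:
    """Analytic Jacobian of the dynamics at ``x_star`` (32 x 32)."""
    model = compile_model(params, spec, constants)
    return _jacobian_impl(model, x_star)


def _jacobian_impl(model: CompiledModel, x_star: np.ndarray) -> np.ndarray:
    x = np.asarray(x_star, dtype=float).reshape(4, N_STATES_PER_SOURCE)
    vp = x[:, 1] - x[:, 2]
    dsv = model.dsigmoid(vp)  # (4,)
    ds1 = model.dsigmoid(x[:, 0])
    ds7 = model.dsigmoid(x[:, 6])

    n = 4 * N_STATES_PER_SOURCE
    J = np.zeros((n, n))

    def idx(src: int, state: int) -> int:
        return src * N_STATES_PER_SOURCE + state

    ke = model.He / model.tau_e
    ki = model.Hi / model.tau_i
    W_st = np.diag(model.g[:, 0]) + model.AF + model.AL
    W_pe = model.AB + model.AL
    W_ii = np.diag(model.g[:, 2]) + model.AB + model.AL

    for i in range(4):
        # velocity rows
        for v_state, c_state in ((0, 3), (1, 4), (2, 5), (6, 7)):
            J[idx(i, v_state), idx(i, c_state)] = 1.0
        # stellate current
        r = idx(i, 3)
        J[r, idx(i, 3)] = -2.0 / model.tau_e[i]
        J[r, idx(i, 0)] = -1.0 / model.tau_e[i] ** 2
        for j in range(4):
            w = ke[i] * W_st[i, j] * dsv[j]
            J[r, idx(j, 1)] += w
            J[r, idx(j, 2)] -= w
        # pyramidal excitatory current
        r = idx(i, 4)
        J[r, idx(i, 4)] = -2.0 / model.tau_e[i]
        J[r, idx(i, 1)] += -1.0 / model.tau_e[i] ** 2
        J[r, idx(i, 0)] += ke[i] * model.g[i, 1] * ds1[i]
        for j in range(4):
            w = ke[i] * W_pe[i, j] * dsv[j]
            J[r, idx(j, 1)] += w
            J[r, idx(j, 2)] -= w
        # pyramidal inhibitory current
        r = idx(i, 5)
        J[r, idx(i, 5)] = -2.0 / model.tau_i[i]
        J[r, idx(i, 2)] = -1.0 / model.tau_i[i] ** 2
        J[r, idx(i, 6)] = ki[i] * model.g[i, 3] * ds7[i]
        # inhibitory interneuron current
        r = idx(i, 7)
        J[r, idx(i, 7)] = -2.0 / model.tau_e[i]
        J[r, idx(i, 6)] += -1.0 / model.tau_e[i] ** 2
        for j in range(4):
            w = ke[i] * W_ii[i, j] * dsv[j]
            J[r, idx(j, 1)] += w
            J[r, idx(j, 2)] -= w
    return J


def stability_margin(J: np.ndarray) -> float:
    """Largest real part over the eigenvalues (negative means stable)."""
    return float(np.linalg.eigvals(J).real.max())


try:  # numba-accelerated triangular substitutions (numpy fallback below)
    from numba import njit as _njit

    @_njit(cache=False)
    def _subst_upper(T, Bh, iw, Y):
        F, n, r = Y.shape
        for f in range(F):
            for i in range(n - 1, -1, -1):
                d = iw[f] - T[i, i]
                for c in range(r):
                    acc = Bh[i, c]
                    for k in range(i + 1, n):
                        acc += T[i, k] * Y[f, k, c]
                    Y[f, i, c] = acc / d

    @_njit(cache=False)
    def _subst_lower(T, Bh, iw, Y):
        F, n, r = Y.shape
        for f in range(F):
            for i in range(n):
                d = iw[f] - T[i, i]
                for c in range(r):
                    acc = Bh[i, c]
                    for k in range(i):
                        acc += T[k, i] * Y[f, k, c]
                    Y[f, i, c] = acc / d

    _HAVE_NUMBA_SUBST = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA_SUBST = False


class _SchurResolvent:
    """Resolvent solves (i*w*I - J)^-1 B across a frequency grid.

    Uses one unitary complex Schur factorization J = Q T Q^H and vectorized
    triangular substitution per frequency.  The Jacobian's eigenvector basis
    is nearly defective (clustered modes of four similar sources), so an
    eigendecomposition would lose about seven digits; the Schur route is
    backward stable.
    """

    def __init__(self, J: np.ndarray, freqs: np.ndarray):
        from scipy.linalg import schur

        self.T, self.Q = schur(J.astype(complex), output="complex")
        self.iw = 2j * np.pi * np.asarray(freqs, dtype=float)
        self.margin = float(self.T.diagonal().real.max())
        self.n = J.shape[0]

    def solve(self, B: np.ndarray) -> np.ndarray:
        """(i w I - J)^-1 B for each frequency; B is (n, r) -> (F, n, r)."""
        T, Q, iw = self.T, self.Q, self.iw
        n = self.n
        Bh = np.ascontiguousarray(Q.conj().T @ B.astype(complex))  # (n, r)
        Y = np.empty((iw.size, n, B.shape[1]), dtype=complex)
        if _HAVE_NUMBA_SUBST:
            _subst_upper(self.T, Bh, iw, Y)
        else:  # pragma: no cover
            for i in range(n - 1, -1, -1):
                rhs = Bh[i][None, :] + np.einsum(
                    "k,fkr->fr", T[i, i + 1 :], Y[:, i + 1 :, :]
                )
                Y[:, i, :] = rhs / (iw - T[i, i])[:, None]
        return Q @ Y

    def solve_transposed(self, B: np.ndarray) -> np.ndarray:
        """(i w I - J^T)^-1 B per frequency (for left multiplications)."""
        T, Q, iw = self.T, self.Q, self.iw
        n = self.n
        # J^T = conj(Q) T^T Q^T, so i*w*I - J^T = conj(Q) (i*w*I - T^T) Q^T
        Bh = np.ascontiguousarray(Q.T @ B.astype(complex))
        Y = np.empty((iw.size, n, B.shape[1]), dtype=complex)
        if _HAVE_NUMBA_SUBST:
            _subst_lower(self.T, Bh, iw, Y)
        else:  # pragma: no cover
            for i in range(n):
                rhs = Bh[i][None, :] + np.einsum("k,fkr->fr", T[:i, i], Y[:, :i, :])
                Y[:, i, :] = rhs / (iw - T[i, i])[:, None]
        return Q.conj() @ Y


def _in_out_operators(model: CompiledModel) -> tuple[np.ndarray, np.ndarray]:
    n = 4 * N_STATES_PER_SOURCE
    C_in = np.zeros((n, 4))
    C_out = np.zeros((4, n))
    for i in range(4):
        C_in[i * N_STATES_PER_SOURCE + 3, i] = model.He[i] / model.tau_e[i]
        C_out[i, i * N_STATES_PER_SOURCE + 1] = 1.0
        C_out[i, i * N_STATES_PER_SOURCE + 2] = -1.0
    return C_in, C_out


def transfer_functions(
    params: DCMParams,
    spec: NetworkSpec,
    freqs: np.ndarray,
    constants: dict | None = None,
    check_stability: bool = True,
) -> np.ndarray:
    """Source-to-source transfer matrices T(f), shape (F, 4, 4).

    T(f) = C_out (2*pi*i*f - J)^-1 C_in, evaluated through an eigenvalue
    decomposition of the Jacobian at the fixed point; innovations enter at
    the stellate population and the pyramidal potential is read out.
    """
    model = compile_model(params, spec, constants)
    return _transfer_impl(model, np.asarray(freqs, dtype=float), check_stability)


def _transfer_impl(
    model: CompiledModel, freqs: np.ndarray, check_stability: bool = True
) -> np.ndarray:
    x_star = _equilibrium_impl(model)
    J = _jacobian_impl(model, x_star)
    res = _SchurResolvent(J, freqs)
    if check_stability and res.margin >= 0:
        raise UnstableModelError(
            f"linearized dynamics unstable (max Re eigenvalue {res.margin:g})"
        )
    C_in, C_out = _in_out_operators(model)
    bad = np.abs(res.iw[:, None] - res.T.diagonal()[None, :]).min(axis=1) < 1e-12
    if bad.any():
        raise RuntimeError(
            f"singular resolvent at {np.asarray(freqs)[bad][0]:g} Hz"
        )
    T = C_out @ res.solve(C_in)  # (F, 4, 4)
    return T


def predict_csd_components(
    params: DCMParams,
    spec: NetworkSpec,
    lead: LeadField,
    freqs: np.ndarray,
    constants: dict | None = None,
) -> dict:
    """Additive decomposition of the predicted CSD.

    Returns ``signal`` (4, F, m, m): the contribution of each source's
    innovations after propagation and lead-field mixing; ``noise_specific``
    and ``noise_common`` (F, m, m).  Their total equals
    :func:`predict_csd`.  Because each component scales linearly with one
    amplitude constant, derivatives of the CSD with respect to the
    log-scaling amplitude parameters are the components themselves.
    """
    freqs = np.asarray(freqs, dtype=float)
    model = compile_model(params, spec, constants)
    T = _transfer_impl(model, freqs)
    gu = model.innovations_spectrum(freqs)  # (4, F)
    L = model.lead_gain * lead.matrix
    H = np.einsum("ms,fst->fmt", L, T)  # (F, m, 4)
    sig = np.einsum("fmi,if,fni->ifmn", H, gu, H.conj())
    m = lead.n_channels
    spec_amp = model.noise_specific_amp * model._shape(
        freqs, model.noise_specific_beta, model.noise_white_frac, model.noise_f_clamp
    )[0]
    comm_amp = model.noise_common_amp * model._shape(
        freqs, model.noise_common_beta, model.noise_white_frac, model.noise_f_clamp
    )[0]
    return {
        "signal": sig,
        "noise_specific": spec_amp[:, None, None] * np.eye(m),
        "noise_common": comm_amp[:, None, None] * np.ones((m, m)),
    }


def predict_csd_jacobian(
    params: DCMParams,
    spec: NetworkSpec,
    lead: LeadField,
    freqs: np.ndarray,
    constants: dict | None = None,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Predicted CSD together with analytic derivatives.

    Returns ``(G, D)`` where ``D`` maps global parameter-vector indices to
    dG/dtheta arrays (F, m, m).  Covered parameters: the 12 extrinsic
    couplings (through the rank-one perturbation each edge makes to the
    Jacobian of the dynamics), the per-source innovations amplitudes, the
    lead-field gain and the channel-noise amplitudes (each scaling one
    additive CSD component).  Exact at the linearization point -- no finite
    differencing.
    """
    freqs = np.asarray(freqs, dtype=float)
    model = compile_model(params, spec, constants)
    x_star = _equilibrium_impl(model)
    J = _jacobian_impl(model, x_star)
    res = _SchurResolvent(J, freqs)
    if res.margin >= 0:
        raise UnstableModelError(
            f"linearized dynamics unstable (max Re eigenvalue {res.margin:g})"
        )
    C_in, C_out = _in_out_operators(model)
    n = J.shape[0]

    # stack the input operator and all edge row-patterns as joint RHS
    state_rows = {"forward": (3,), "backward": (4, 7), "lateral": (3, 4, 7)}
    Umat = np.zeros((n, len(spec.edges)))
    for k, e in enumerate(spec.edges):
        t = spec.node_index(e.target)
        for st in state_rows[e.type]:
            Umat[t * N_STATES_PER_SOURCE + st, k] = 1.0
    X = res.solve(np.hstack([C_in, Umat]))
    T = C_out @ X[:, :, :4]  # (F, 4, 4)
    RU = C_out @ X[:, :, 4:]  # (F, 4, n_edges): C_out R u_k

    # column patterns: v_s = e_(s, v_exc) - e_(s, v_inh) per source
    Vmat = np.zeros((n, 4))
    for s in range(4):
        Vmat[s * N_STATES_PER_SOURCE + 1, s] = 1.0
        Vmat[s * N_STATES_PER_SOURCE + 2, s] = -1.0
    Y = res.solve_transposed(Vmat)
    VRC = np.einsum("fns,ni->fsi", Y, C_in)  # (F, 4 sources, 4): v_s^T R C_in

    gu = model.innovations_spectrum(freqs)  # (4, F)
    L = model.lead_gain * lead.matrix
    H = np.einsum("ms,fst->fmt", L, T)  # (F, m, 4)
    sig = np.einsum("fmi,if,fni->ifmn", H, gu, H.conj())  # per-source signal
    m = lead.n_channels
    spec_noise = model.noise_specific_amp * model._shape(
        freqs, model.noise_specific_beta, model.noise_white_frac, model.noise_f_clamp
    )[0][:, None, None] * np.eye(m)
    comm_noise = model.noise_common_amp * model._shape(
        freqs, model.noise_common_beta, model.noise_white_frac, model.noise_f_clamp
    )[0][:, None, None] * np.ones((m, m))
    G = sig.sum(axis=0) + spec_noise + comm_noise

    n_lab = DCMParams.vector_labels()
    D: dict[int, np.ndarray] = {}

    # couplings: dJ = scale * u v^T (rank one), so dT_f is an outer product
    xs = x_star.reshape(4, N_STATES_PER_SOURCE)
    dsv = model.dsigmoid(xs[:, 1] - xs[:, 2])
    ke = model.He / model.tau_e
    cpm = (constants or load_constants())["coupling_prior_means"]
    tgt = np.array([spec.node_index(e.target) for e in spec.edges])
    src = np.array([spec.node_index(e.source) for e in spec.edges])
    base_w = np.array([cpm[e.type] for e in spec.edges])
    scales = ke[tgt] * base_w * np.exp(params.a) * dsv[src]
    # (E, F, 4, 4) outer products, then one batched chain to channel space
    dT = (
        scales[:, None, None, None]
        * RU.transpose(2, 0, 1)[:, :, :, None]
        * VRC[:, src].transpose(1, 0, 2)[:, :, None, :]
    )
    dH = np.einsum("ms,kfst->kfmt", L, dT)  # (E, F, m, 4)
    dSig = np.einsum("kfmi,if,fni->kfmn", dH, gu, H.conj())
    dSig = dSig + dSig.conj().transpose(0, 1, 3, 2)
    for k in range(len(spec.edges)):
        D[k] = dSig[k]

    base = 12 + 4 * len(INTRINSIC_FIELDS) + 1
    for i in range(4):
        D[base + i] = sig[i]  # innovations amplitude log-scalings
    obs0 = base + 8
    D[obs0] = 2.0 * sig.sum(axis=0)  # lead gain
    D[obs0 + 1] = comm_noise  # common channel-noise amplitude
    D[obs0 + 3] = spec_noise  # specific channel-noise amplitude
    return G, D


def predict_csd(
    params: DCMParams,
    spec: NetworkSpec,
    lead: LeadField,
    freqs: np.ndarray,
    constants: dict | None = None,
) -> CSDData:
    """Predicted channel cross-spectral density (one-sided, units^2/Hz)."""
    freqs = np.asarray(freqs, dtype=float)
    model = compile_model(params, spec, constants)
    T = _transfer_impl(model, freqs)
    gu = model.innovations_spectrum(freqs)  # (4, F)
    L = model.lead_gain * lead.matrix
    H = np.einsum("ms,fst->fmt", L, T)  # (F, m, 4)
    G = np.einsum("fmi,if,fni->fmn", H, gu, H.conj())
    G = G + model.channel_noise(freqs, lead.n_channels)
    G = 0.5 * (G + G.conj().transpose(0, 2, 1))
    out = CSDData(
        freqs=freqs,
        csd=G,
        meta={
            "space": "channels",
            "labels": list(lead.labels or []),
            "source": "model",
        },
    )
    return out
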