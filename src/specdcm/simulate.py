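"""Stochastic time-domain simulation of the neural mass network.

Serves as the independent oracle for the linearized spectral predictions:
the full nonlinear dynamics are integrated by Euler-Maruyama under coloured
innovations whose one-sided spectrum matches the generative model's
``Gu(f)``, observed through the lead field plus channel noise matching
``Gn(f)``.  Coloured processes are synthesized by FFT shaping of white
Gaussian noise, so an identical seed yields a bitwise-identical recording.
"""

from __future__ import annotations

import numpy as np

from .csd import LeadField, Recording
from .model import N_STATES_PER_SOURCE, CompiledModel, compile_model
from .network import NetworkSpec
from .params import DCMParams

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=False)
def _integrate_loop(
    x: np.ndarray,  # (4, 8) initial state, modified in place
    u: np.ndarray,  # (4, n_steps) innovations
    dt: float,
    decim: int,
    W_st: np.ndarray,  # (4, 4) weights onto stellate from S(v_pyr)
    W_pe: np.ndarray,
    W_ii: np.ndarray,
    g2: np.ndarray,
    g4: np.ndarray,
    He: np.ndarray,
    Hi: np.ndarray,
    te: np.ndarray,
    ti: np.ndarray,
    e0: float,
    r: float,
    v0: float,
    heun: bool,
    v_out: np.ndarray,  # (4, n_out)
) -> int:
    n_steps = u.shape[1]
    n_out = v_out.shape[1]
    s0 = 2.0 * e0 / (1.0 + np.exp(r * v0))
    dx = np.empty((4, 8))
    xp = np.empty((4, 8))
    dx2 = np.empty((4, 8))

    def _f(xs, us, out):
        sv = np.empty(4)
        s1 = np.empty(4)
        s7 = np.empty(4)
        for i in range(4):
            vp = xs[i, 1] - xs[i, 2]
            sv[i] = 2.0 * e0 / (1.0 + np.exp(r * (v0 - vp))) - s0
            s1[i] = 2.0 * e0 / (1.0 + np.exp(r * (v0 - xs[i, 0]))) - s0
            s7[i] = 2.0 * e0 / (1.0 + np.exp(r * (v0 - xs[i, 6]))) - s0
        for i in range(4):
            in_st = us[i]
            in_pe = g2[i] * s1[i]
            in_ii = 0.0
            for j in range(4):
                in_st += W_st[i, j] * sv[j]
                in_pe += W_pe[i, j] * sv[j]
                in_ii += W_ii[i, j] * sv[j]
            ke = He[i] / te[i]
            ki = Hi[i] / ti[i]
            out[i, 0] = xs[i, 3]
            out[i, 1] = xs[i, 4]
            out[i, 2] = xs[i, 5]
            out[i, 6] = xs[i, 7]
            out[i, 3] = ke * in_st - 2.0 * xs[i, 3] / te[i] - xs[i, 0] / te[i] ** 2
            out[i, 4] = ke * in_pe - 2.0 * xs[i, 4] / te[i] - xs[i, 1] / te[i] ** 2
            out[i, 5] = ki * g4[i] * s7[i] - 2.0 * xs[i, 5] / ti[i] - xs[i, 2] / ti[i] ** 2
            out[i, 7] = ke * in_ii - 2.0 * xs[i, 7] / te[i] - xs[i, 6] / te[i] ** 2

    j = 0
    for t in range(n_steps):
        if t % decim == 0 and j < n_out:
            for i in range(4):
                v_out[i, j] = x[i, 1] - x[i, 2]
            j += 1
        _f(x, u[:, t], dx)
        if heun:
            for i in range(4):
                for k in range(8):
                    xp[i, k] = x[i, k] + dt * dx[i, k]
            tn = t + 1 if t + 1 < n_steps else t
            _f(xp, u[:, tn], dx2)
            for i in range(4):
                for k in range(8):
                    x[i, k] += 0.5 * dt * (dx[i, k] + dx2[i, k])
        else:
            for i in range(4):
                for k in range(8):
                    x[i, k] += dt * dx[i, k]
        bad = False
        for i in range(4):
            for k in range(8):
                if not np.isfinite(x[i, k]) or abs(x[i, k]) > 1e9:
                    bad = True
        if bad:
            return t
    return -1


def colored_noise(
    psd: "callable",
    n_samples: int,
    sfreq: float,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Gaussian series whose one-sided PSD follows ``psd(f)`` (units^2/Hz)."""
    z = rng.standard_normal((n_series, n_samples))
    Z = np.fft.rfft(z, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    amp = np.sqrt(np.maximum(psd(f), 0.0) * sfreq / 2.0)
    return np.fft.irfft(Z * amp, n=n_samples, axis=-1)


def _innovations(
    model: CompiledModel, n_steps: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    u = np.empty((4, n_steps))
    for i in range(4):
        amp, beta = model.innov_amp[i], model.innov_beta[i]

        def psd(f, amp=amp, beta=beta):
            fc = np.maximum(f, model.innov_f_clamp)
            return amp * (model.innov_white_frac + (1 - model.innov_white_frac) * fc**-beta)

        u[i] = colored_noise(psd, n_steps, fs, rng)[0]
    return u


def _channel_noise(
    model: CompiledModel, n_ch: int, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    def shape(f, amp, beta):
        fc = np.maximum(f, model.noise_f_clamp)
        return amp * (model.noise_white_frac + (1 - model.noise_white_frac) * fc**-beta)

    spec = colored_noise(
        lambda f: shape(f, model.noise_specific_amp, model.noise_specific_beta),
        n_samples,
        fs,
        rng,
        n_series=n_ch,
    )
    comm = colored_noise(
        lambda f: shape(f, model.noise_common_amp, model.noise_common_beta),
        n_samples,
        fs,
        rng,
    )
    return spec + comm


def simulate_timeseries(
    params: DCMParams,
    spec: NetworkSpec,
    lead: LeadField,
    duration: float,
    dt: float = 1e-3,
    seed: int = 0,
    constants: dict | None = None,
    sfreq_out: float = 250.0,
    innovation_scale: float = 1.0,
    noise_scale: float = 1.0,
    x0: np.ndarray | None = None,
    return_sources: bool = False,
    integrator: str = "heun",
):
    """Simulate an EEG-like recording of ``duration`` seconds.

    The integration step ``dt`` must be at most 2 ms and divide the output
    sampling interval.  ``innovation_scale`` / ``noise_scale`` multiply the
    stochastic drives (0 gives a deterministic, noise-free trajectory).
    The default one-step scheme is a stochastic Heun (second-order) update,
    which removes the resonance-damping bias a plain Euler-Maruyama step
    shows at these pole frequencies; ``integrator="euler"`` is available.
    """
    if duration < 10.0:
        raise ValueError("duration must be at least 10 s")
    if dt > 2e-3:
        raise ValueError("dt must be at most 2 ms")
    if integrator not in ("heun", "euler"):
        raise ValueError("integrator must be 'heun' or 'euler'")
    decim = int(round(1.0 / (sfreq_out * dt)))
    if abs(decim * sfreq_out * dt - 1.0) > 1e-9 or decim < 1:
        raise ValueError("1/dt must be an integer multiple of sfreq_out")

    model = compile_model(params, spec, constants)
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    fs_int = 1.0 / dt

    if innovation_scale != 0.0:
        u = innovation_scale * _innovations(model, n_steps, fs_int, rng)
    else:
        u = np.zeros((4, n_steps))

    x = (
        np.zeros((4, N_STATES_PER_SOURCE))
        if x0 is None
        else np.asarray(x0, dtype=float).reshape(4, N_STATES_PER_SOURCE).copy()
    )
    n_out = n_steps // decim
    v_src = np.empty((4, n_out))
    W_st = np.diag(model.g[:, 0]) + model.AF + model.AL
    W_pe = model.AB + model.AL
    W_ii = np.diag(model.g[:, 2]) + model.AB + model.AL
    t_bad = _integrate_loop(
        x,
        np.ascontiguousarray(u),
        dt,
        decim,
        np.ascontiguousarray(W_st),
        np.ascontiguousarray(W_pe),
        np.ascontiguousarray(W_ii),
        np.ascontiguousarray(model.g[:, 1]),
        np.ascontiguousarray(model.g[:, 3]),
        model.He,
        model.Hi,
        model.tau_e,
        model.tau_i,
        model.sig_e0,
        model.sig_r * model.slope_scale,
        model.sig_v0,
        integrator == "heun",
        v_src,
    )
    if t_bad >= 0:
        raise RuntimeError(
            f"trajectory diverged at t={t_bad * dt:.3f} s; use a smaller dt"
        )

    y = model.lead_gain * lead.matrix @ v_src
    if noise_scale != 0.0:
        y = y + noise_scale * _channel_noise(
            model, lead.n_channels, n_out, sfreq_out, rng
        )
    rec = Recording(y, sfreq_out, list(lead.labels or []))
    if return_sources:
        return rec, v_src
    return rec
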