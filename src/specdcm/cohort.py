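"""Synthetic cohorts and spectral estimation.

The cohort generator emulates the statistical structure of a resting-EEG
group study of disorders of consciousness: four groups (healthy controls,
unconscious patients with congruent hypometabolism, conscious MCS+ patients
and a behaviourally unresponsive holdout group whose physiology resembles
the conscious groups), a group effect expressed as a log-scaling shift of
chosen couplings, Gaussian between-subject random effects, and finite-epoch
observation noise on the cross-spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csd import CSDData, LeadField, Recording, synthetic_lead_field
from .model import UnstableModelError, predict_csd
from .network import NetworkSpec, default_dmn
from .params import DCMParams, default_freqs

# canonical group labels
CONTROL = "control"
UWS = "uws_petneg"
MCS = "mcs_plus"
HOLDOUT = "mcs_star"


# ---------------------------------------------------------------------------
# spectral estimation


def welch_csd(
    recording: Recording,
    epoch_len: float = 10.0,
    band: tuple[float, float] = (1.0, 30.0),
    overlap: float = 0.0,
    window: str = "hann",
    n_epochs: int | None = None,
) -> CSDData:
    """Cross-spectral density by epoch-averaged tapered cross-periodograms.

    The recording is cut into ``epoch_len``-second epochs (optionally
    overlapping), each epoch is demeaned and tapered, and the one-sided
    cross-periodograms are averaged and restricted to ``band``.  With
    ``n_epochs`` only the first so many epochs enter the average.
    """
    fs = recording.sfreq
    nper = int(round(epoch_len * fs))
    if recording.n_samples < 2 * nper:
        raise ValueError("recording must contain at least 2 epochs")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if band[0] <= 0 or band[1] > fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2:g}]")

    step = max(1, int(round(nper * (1 - overlap))))
    starts = np.arange(0, recording.n_samples - nper + 1, step)
    if n_epochs is not None:
        if n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        starts = starts[:n_epochs]

    if window == "hann":
        w = np.hanning(nper)
    elif window == "boxcar":
        w = np.ones(nper)
    else:
        raise ValueError(f"unknown window {window!r}")
    U = (w**2).sum()

    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    m = recording.n_channels
    acc = np.zeros((keep.sum(), m, m), dtype=complex)
    for s in starts:
        seg = recording.data[:, s : s + nper]
        seg = (seg - seg.mean(axis=1, keepdims=True)) * w
        X = np.fft.rfft(seg, axis=1)[:, keep]  # (m, F)
        acc += np.einsum("mf,nf->fmn", X, X.conj())
    csd = 2.0 * acc / (fs * U * len(starts))
    return CSDData(
        freqs=freqs[keep],
        csd=csd,
        meta={
            "n_epochs": int(len(starts)),
            "sfreq": fs,
            "space": "channels",
            "labels": list(recording.labels),
            "estimator": "welch",
        },
    )


def bin_average_csd(est: CSDData, target_freqs: np.ndarray) -> CSDData:
    """Average estimate bins into the cells of a coarser frequency grid.

    Each target grid point f collects the estimate bins within +-df/2 of f
    (df the target spacing).  Averaging adjacent near-independent Welch bins
    multiplies the effective number of averages while introducing negligible
    bias for spectra that are smooth on the df scale.
    """
    target_freqs = np.asarray(target_freqs, dtype=float)
    df = np.min(np.diff(target_freqs)) if target_freqs.size > 1 else 1.0
    out = np.empty((target_freqs.size, est.n_channels, est.n_channels), complex)
    n_used = np.zeros(target_freqs.size, int)
    for k, f in enumerate(target_freqs):
        sel = np.abs(est.freqs - f) <= df / 2 + 1e-9
        if not sel.any():
            raise ValueError(f"no estimate bins near {f:g} Hz")
        out[k] = est.csd[sel].mean(axis=0)
        n_used[k] = sel.sum()
    meta = dict(est.meta)
    meta["bin_averaged"] = int(n_used.mean())
    return CSDData(target_freqs, out, meta)


def sample_observed_csd(true_csd: CSDData, n_epochs: int, seed: int = 0) -> CSDData:
    """Finite-epoch sampling noise via a complex Wishart draw per frequency.

    The observed matrix at each frequency is (1/n) sum_k z_k z_k^H with
    z_k ~ CN(0, G(f)), so its mean is the true CSD and its fluctuations
    shrink as 1/sqrt(n_epochs), emulating an n-epoch Welch average.
    """
    m = true_csd.n_channels
    if n_epochs < m:
        raise ValueError(
            f"n_epochs ({n_epochs}) must be >= channel count ({m}) for a "
            "non-degenerate sample"
        )
    rng = np.random.default_rng(seed)
    F = true_csd.n_freqs
    # Cholesky of each (regularized) spectral matrix
    jitter = 1e-12 * np.trace(true_csd.csd, axis1=1, axis2=2).real.mean() / m
    chol = np.linalg.cholesky(true_csd.csd + jitter * np.eye(m))
    z = (
        rng.standard_normal((F, m, n_epochs)) + 1j * rng.standard_normal((F, m, n_epochs))
    ) / np.sqrt(2.0)
    zc = np.einsum("fmk,fkn->fmn", chol, z)
    W = np.einsum("fmn,fpn->fmp", zc, zc.conj()) / n_epochs
    W = 0.5 * (W + W.conj().transpose(0, 2, 1))
    meta = dict(true_csd.meta)
    meta.update({"n_epochs": int(n_epochs), "sampling": "complex-wishart"})
    return CSDData(true_csd.freqs.copy(), W, meta)


def project_modes(
    data: CSDData | Recording, n_modes: int
) -> tuple[CSDData, np.ndarray] | tuple[Recording, np.ndarray]:
    """Reduce channels to the leading principal spatial modes.

    The projection is the top eigenvectors of the frequency-averaged real
    cross-spectral matrix (or the sample covariance for a recording);
    returns the reduced data and the (n_modes x m) projection matrix for
    reproducibility.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if isinstance(data, Recording):
        if n_modes > data.n_channels:
            raise ValueError("n_modes exceeds channel count")
        centred = data.data - data.data.mean(axis=1, keepdims=True)
        C = centred @ centred.T / centred.shape[1]
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:n_modes]
        P = evecs[:, order].T
        signs = np.sign(P[np.arange(n_modes), np.abs(P).argmax(axis=1)])
        P = P * signs[:, None]
        return Recording(P @ data.data, data.sfreq,
                         [f"mode{i}" for i in range(n_modes)]), P
    m = data.n_channels
    if n_modes > m:
        raise ValueError("n_modes exceeds channel count")
    C = data.csd.real.mean(axis=0)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:n_modes]
    P = evecs[:, order].T  # (n_modes, m)
    # fix sign for determinism
    signs = np.sign(P[np.arange(n_modes), np.abs(P).argmax(axis=1)])
    P = P * signs[:, None]
    reduced = np.einsum("am,fmn,bn->fab", P, data.csd, P)
    meta = dict(data.meta)
    meta.update({"space": "modes", "labels": [f"mode{i}" for i in range(n_modes)]})
    return CSDData(data.freqs.copy(), reduced, meta), P


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the emulated study: 11 controls, 6 unconscious patients
    (UWS with negative PET), 12 MCS+ patients, and 5 behaviourally
    unresponsive holdout subjects drawn from the conscious parameter
    distribution; the group effect is a -0.6 log-scaling reduction of the
    backward mPFC->lLP coupling in the unconscious group; between-subject
    spread 0.1 per coupling; 60 ten-second epochs at 250 Hz.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {CONTROL: 11, UWS: 6, MCS: 12, HOLDOUT: 5}
    )
    group_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {UWS: {"mPFC->lLP": -0.6}}
    )
    sigma_between: float = 0.1
    n_epochs: int = 60
    epoch_len: float = 10.0
    sfreq: float = 250.0
    n_channels: int = 8
    lead_seed: int = 101
    observation: str = "wishart"  # "wishart" | "timeseries"

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")
        if self.sigma_between < 0:
            raise ValueError("sigma_between must be >= 0")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.observation not in ("wishart", "timeseries"):
            raise ValueError("observation must be 'wishart' or 'timeseries'")


@dataclass
class Subject:
    sid: str
    group: str
    true_params: DCMParams
    csd: CSDData


@dataclass
class SyntheticCohort:
    config: CohortConfig
    seed: int
    spec: NetworkSpec
    lead: LeadField
    subjects: list[Subject]

    @property
    def labels(self) -> list[str]:
        return [s.group for s in self.subjects]

    def by_group(self, *groups: str) -> list[Subject]:
        return [s for s in self.subjects if s.group in groups]


def _effect_vector(spec: NetworkSpec, effects: dict[str, float]) -> np.ndarray:
    v = np.zeros(spec.n_edges)
    for name, val in effects.items():
        source, target = name.split("->")
        v[spec.edge_index(source, target)] = val
    return v


def make_cohort(
    config: CohortConfig,
    seed: int = 0,
    spec: NetworkSpec | None = None,
    constants: dict | None = None,
) -> SyntheticCohort:
    """Generate a reproducible cohort under the configured study design.

    Each subject's true couplings are the group effect plus an independent
    N(0, sigma_between^2) draw per coupling (redrawn if the resulting model
    is unstable); the observed CSD is the model prediction corrupted by a
    complex-Wishart finite-epoch sample (or, on the slow path, a Welch
    estimate of a simulated recording of matching length).
    """
    spec = spec or default_dmn()
    lead = synthetic_lead_field(config.n_channels, seed=config.lead_seed)
    freqs = default_freqs(constants)
    rng = np.random.default_rng(seed)
    holdout_like = config.group_effects.get(CONTROL, {})

    subjects: list[Subject] = []
    for group, size in config.group_sizes.items():
        effects = (
            holdout_like if group == HOLDOUT else config.group_effects.get(group, {})
        )
        base = _effect_vector(spec, effects)
        for k in range(size):
            for _attempt in range(50):
                a = base + config.sigma_between * rng.standard_normal(spec.n_edges)
                params = DCMParams(a=a)
                try:
                    true_csd = predict_csd(params, spec, lead, freqs, constants)
                    break
                except UnstableModelError:
                    continue
            else:
                raise RuntimeError("could not draw a stable subject in 50 attempts")
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if config.observation == "wishart":
                observed = sample_observed_csd(true_csd, config.n_epochs, sub_seed)
            else:
                from .simulate import simulate_timeseries

                rec = simulate_timeseries(
                    params,
                    spec,
                    lead,
                    duration=config.n_epochs * config.epoch_len,
                    seed=sub_seed,
                    sfreq_out=config.sfreq,
                    constants=constants,
                )
                observed = welch_csd(
                    rec,
                    config.epoch_len,
                    band=(max(freqs[0] - 0.2, 0.2), freqs[-1] + 0.2),
                )
                observed = bin_average_csd(observed, freqs)
            observed.meta.update({"group": group, "subject": f"{group}_{k}"})
            subjects.append(Subject(f"{group}_{k}", group, params, observed))
    return SyntheticCohort(config, seed, spec, lead, subjects)
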