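"""Model constants and the subject-level parameter vector.

All estimable quantities are dimensionless log-scalings multiplying the
prior-mean constants shipped in ``constants/priors.yaml``: a value of 0 means
"at the prior mean", +0.69 roughly "doubled".  The fixed vectorization order
(couplings, intrinsic physiology, sigmoid slope, innovations, observation
parameters) is what the inversion, the group model and all serialization use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

N_SOURCES = 4
N_EDGES = 12
# per-source intrinsic entries, in order
INTRINSIC_FIELDS = ("He", "Hi", "tau_e", "tau_i", "g1", "g2", "g3", "g4")

_REQUIRED_SECTIONS = (
    "sigmoid",
    "synaptic",
    "intrinsic_gains",
    "coupling_prior_means",
    "innovations",
    "channel_noise",
    "prior_variances",
    "frequency_grid",
)


_DEFAULT_CONSTANTS: dict | None = None


def load_constants(path: str | Path | None = None) -> dict:
    """Load and schema-check the biophysical constants table.

    With no argument the constants file shipped with the package is used
    (parsed once and cached).
    """
    global _DEFAULT_CONSTANTS
    if path is None and _DEFAULT_CONSTANTS is not None:
        return _DEFAULT_CONSTANTS
    if path is None:
        text = (
            resources.files("specdcm") / "constants" / "priors.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    missing = [s for s in _REQUIRED_SECTIONS if s not in table]
    if missing:
        raise ValueError(f"constants file missing sections: {missing}")
    for sec in _REQUIRED_SECTIONS:
        for key, val in table[sec].items():
            if not np.isfinite(float(val)):
                raise ValueError(f"non-finite constant {sec}.{key}")
    if path is None:
        _DEFAULT_CONSTANTS = table
    return table


def default_freqs(constants: dict | None = None) -> np.ndarray:
    """Default analysis grid: 1-30 Hz at 0.25 Hz resolution (117 bins)."""
    c = (constants or load_constants())["frequency_grid"]
    n = int(round((c["f_max"] - c["f_min"]) / c["df"])) + 1
    return c["f_min"] + c["df"] * np.arange(n)


@dataclass
class DCMParams:
    """Log-scaling parameters for one subject.

    ``a`` follows the edge order of the :class:`~specdcm.network.NetworkSpec`
    in use.  ``intrinsic`` is (4 sources x 8): He, Hi, tau_e, tau_i, g1..g4.
    ``innov_amp`` / ``innov_beta`` scale the per-source innovations spectrum;
    the observation block holds the lead-field gain and channel-noise
    (common + specific) amplitude/exponent scalings.
    """

    a: np.ndarray = field(default_factory=lambda: np.zeros(N_EDGES))
    intrinsic: np.ndarray = field(
        default_factory=lambda: np.zeros((N_SOURCES, len(INTRINSIC_FIELDS)))
    )
    sigmoid_slope: float = 0.0
    innov_amp: np.ndarray = field(default_factory=lambda: np.zeros(N_SOURCES))
    innov_beta: np.ndarray = field(default_factory=lambda: np.zeros(N_SOURCES))
    lead_gain: float = 0.0
    noise_common_amp: float = 0.0
    noise_common_beta: float = 0.0
    noise_specific_amp: float = 0.0
    noise_specific_beta: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.intrinsic = np.asarray(self.intrinsic, dtype=float)
        self.innov_amp = np.asarray(self.innov_amp, dtype=float)
        self.innov_beta = np.asarray(self.innov_beta, dtype=float)
        if self.a.shape != (N_EDGES,):
            raise ValueError(f"a must have shape ({N_EDGES},)")
        if self.intrinsic.shape != (N_SOURCES, len(INTRINSIC_FIELDS)):
            raise ValueError("intrinsic must have shape (4, 8)")
        if self.innov_amp.shape != (N_SOURCES,):
            raise ValueError("innov_amp must have shape (4,)")
        if self.innov_beta.shape != (N_SOURCES,):
            raise ValueError("innov_beta must have shape (4,)")

    # -- vectorization -----------------------------------------------------

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical order; round-trips losslessly."""
        return np.concatenate(
            [
                self.a,
                self.intrinsic.ravel(),
                [self.sigmoid_slope],
                self.innov_amp,
                self.innov_beta,
                [
                    self.lead_gain,
                    self.noise_common_amp,
                    self.noise_common_beta,
                    self.noise_specific_amp,
                    self.noise_specific_beta,
                ],
            ]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "DCMParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (cls.n_params(),):
            raise ValueError(f"expected vector of length {cls.n_params()}")
        k = N_EDGES
        ni = N_SOURCES * len(INTRINSIC_FIELDS)
        a = v[:k]
        intrinsic = v[k : k + ni].reshape(N_SOURCES, len(INTRINSIC_FIELDS))
        k += ni
        slope = v[k]
        k += 1
        innov_amp = v[k : k + N_SOURCES]
        k += N_SOURCES
        innov_beta = v[k : k + N_SOURCES]
        k += N_SOURCES
        obs = v[k : k + 5]
        return cls(
            a=a,
            intrinsic=intrinsic,
            sigmoid_slope=slope,
            innov_amp=innov_amp,
            innov_beta=innov_beta,
            lead_gain=obs[0],
            noise_common_amp=obs[1],
            noise_common_beta=obs[2],
            noise_specific_amp=obs[3],
            noise_specific_beta=obs[4],
        )

    @staticmethod
    def n_params() -> int:
        return N_EDGES + N_SOURCES * len(INTRINSIC_FIELDS) + 1 + 2 * N_SOURCES + 5

    @staticmethod
    def vector_labels() -> list[str]:
        labels = [f"a{k}" for k in range(N_EDGES)]
        for s in range(N_SOURCES):
            labels += [f"{f}_s{s}" for f in INTRINSIC_FIELDS]
        labels += ["sigmoid_slope"]
        labels += [f"innov_amp_s{s}" for s in range(N_SOURCES)]
        labels += [f"innov_beta_s{s}" for s in range(N_SOURCES)]
        labels += [
            "lead_gain",
            "noise_common_amp",
            "noise_common_beta",
            "noise_specific_amp",
            "noise_specific_beta",
        ]
        return labels

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.to_vector())):
            raise ValueError("DCMParams contains non-finite entries")

    @property
    def coupling_slice(self) -> slice:
        return slice(0, N_EDGES)


def prior_variance_vector(constants: dict | None = None) -> np.ndarray:
    """Diagonal prior variances in vectorization order.

    Entries with zero variance are fixed at the prior mean during inversion;
    by default only extrinsic couplings, innovations amplitudes, the
    lead-field gain and the channel-noise amplitudes are free.
    """
    c = constants or load_constants()
    pv = c["prior_variances"]
    v = np.concatenate(
        [
            np.full(N_EDGES, pv["coupling"]),
            np.full(N_SOURCES * len(INTRINSIC_FIELDS), pv["intrinsic"]),
            [pv["sigmoid_slope"]],
            np.full(N_SOURCES, pv["innovations_amp"]),
            np.full(N_SOURCES, pv["innovations_beta"]),
            [
                pv["lead_gain"],
                pv["noise_amp"],
                pv["noise_beta"],
                pv["noise_amp"],
                pv["noise_beta"],
            ],
        ]
    )
    return v.astype(float)
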