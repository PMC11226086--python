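"""Containers for cross-spectral data and lead fields, with disk round-trip.

A :class:`CSDData` holds a strictly increasing frequency grid together with
one complex Hermitian positive-semidefinite matrix per frequency (channels,
spatial modes or sources) plus provenance metadata.  On disk it is a
directory with a ``meta.json`` file and an ``arrays.npz`` file storing the
frequency grid (F real) and the cross-spectra as separate real and imaginary
arrays (F x m x m each); the reader inverts the writer exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

HERMITIAN_TOL = 1e-10
PSD_TOL = -1e-10


@dataclass
class CSDData:
    freqs: np.ndarray
    csd: np.ndarray  # (F, m, m) complex
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float).ravel()
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.csd.ndim != 3 or self.csd.shape[0] != self.freqs.size:
            raise ValueError("csd must be (F, m, m) matching freqs")
        if self.csd.shape[1] != self.csd.shape[2]:
            raise ValueError("cross-spectral matrices must be square")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.csd.shape[1]

    @property
    def n_freqs(self) -> int:
        return self.freqs.size

    def validate(self, hermitian_tol: float = HERMITIAN_TOL, psd_tol: float = PSD_TOL) -> None:
        """Check Hermitian symmetry and positive semi-definiteness."""
        scale = max(np.abs(self.csd).max(), 1e-300)
        asym = np.abs(self.csd - self.csd.conj().transpose(0, 2, 1)).max()
        if asym > hermitian_tol * scale:
            raise ValueError(f"cross-spectra not Hermitian (max asymmetry {asym:g})")
        H = 0.5 * (self.csd + self.csd.conj().transpose(0, 2, 1))
        ev = np.linalg.eigvalsh(H)
        if ev.min() < psd_tol * scale:
            raise ValueError(f"cross-spectra not PSD (min eigenvalue {ev.min():g})")

    def copy(self) -> "CSDData":
        return CSDData(self.freqs.copy(), self.csd.copy(), dict(self.meta))

    # -- disk container ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "meta.json").write_text(json.dumps(self.meta, indent=2, default=str))
        np.savez(
            path / "arrays.npz",
            freqs=self.freqs,
            csd_real=self.csd.real,
            csd_imag=self.csd.imag,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CSDData":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        with np.load(path / "arrays.npz") as z:
            freqs = z["freqs"]
            csd = z["csd_real"] + 1j * z["csd_imag"]
        return cls(freqs=freqs, csd=csd, meta=meta)


@dataclass
class Recording:
    """A multichannel time series: (channels x samples) at a fixed rate."""

    data: np.ndarray
    sfreq: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.labels is None:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def rereference_common_average(self) -> "Recording":
        return Recording(
            self.data - self.data.mean(axis=0, keepdims=True),
            self.sfreq,
            list(self.labels),
        )


@dataclass
class LeadField:
    """Linear mapping from the 4 source outputs to m observation channels."""

    matrix: np.ndarray  # (m, 4)
    provenance: str = "supplied"  # "synthetic" | "supplied"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("lead field must be a 2-D matrix")
        m, n = self.matrix.shape
        if np.linalg.matrix_rank(self.matrix) < n:
            raise ValueError("lead field must have full column rank")
        if self.labels is None:
            self.labels = [f"ch{i}" for i in range(m)]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def synthetic_lead_field(n_channels: int = 8, n_sources: int = 4, seed: int = 0) -> LeadField:
    """Seeded random, well-conditioned lead field with unit column norms.

    Stands in for an anatomical head-model forward operator; columns are
    drawn Gaussian and redrawn until the condition number is below 20.
    """
    if n_channels < n_sources:
        raise ValueError("need at least as many channels as sources")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        L = rng.standard_normal((n_channels, n_sources))
        L /= np.linalg.norm(L, axis=0, keepdims=True)
        if np.linalg.cond(L) < 20:
            return LeadField(L, provenance="synthetic")
    raise RuntimeError("failed to draw a well-conditioned lead field")
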