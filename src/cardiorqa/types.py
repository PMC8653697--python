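"""Shared domain containers.

The package analyses single-lead ECG around four core objects: the sampled
voltage trace (:class:`ECGSignal`), the RR-interval series derived from it
(:class:`Tachogram`), the Gaussian-sum PQRST template parameters of one
simulated cardiac condition (:class:`ConditionParams`), and the phase-space
embedding parameters (:class:`EmbeddingParams`) that govern recurrence
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

WAVES = ("P", "Q", "R", "S", "T")

CONDITIONS = ("DET", "AF", "LQT", "NSE")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ConditionParams:
    """Gaussian PQRST template for one simulated cardiac condition.

    Each wave ``w`` contributes ``a_w * exp(-dtheta_w**2 / (2 b_w**2))`` to the
    beat template, with ``theta_w`` the wave centre on the beat cycle
    (degrees, R at 0) and ``b_w`` the angular width (radians).
    """

    name: str
    theta_deg: tuple[float, float, float, float, float]
    a: tuple[float, float, float, float, float]
    b: tuple[float, float, float, float, float]
    pq_noise: bool = False
    pq_noise_sd: float = 0.2
    trace_noise_fraction: float = 0.01

    def __post_init__(self) -> None:
        if any(bw <= 0 for bw in self.b):
            raise ValidationError("all wave widths b_w must be positive")
        if list(self.theta_deg) != sorted(self.theta_deg):
            raise ValidationError(
                "wave centres theta must be strictly increasing P->T"
            )

    def with_(self, **kwargs) -> "ConditionParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TachogramSpec:
    """Recipe for a synthetic RR series with an LF/HF-shaped spectrum.

    ``mean_hr`` / ``sd_hr`` are in beats/min; the two spectral bands are
    Gaussians centred at ``lf_center`` / ``hf_center`` Hz.  ``lf_hf_ratio``
    multiplies the LF Gaussian while the HF weight is fixed at 1, so ratio 0
    leaves only high-frequency (fast, decorrelated) modulation.  Rat band
    defaults: LF 0.35 Hz (width 0.1), HF 1.5 Hz (width 0.3).
    """

    mean_hr: float = 350.0
    sd_hr: float = 50.0
    lf_hf_ratio: float = 1.0
    lf_center: float = 0.35
    lf_width: float = 0.1
    hf_center: float = 1.5
    hf_width: float = 0.3
    n_beats: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_hr <= 0:
            raise ValidationError("mean_hr must be positive")
        if self.sd_hr < 0:
            raise ValidationError("sd_hr must be non-negative")
        if self.lf_hf_ratio < 0:
            raise ValidationError("lf_hf_ratio must be non-negative")
        for name in ("lf_center", "lf_width", "hf_center", "hf_width"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_beats < 2:
            raise ValidationError("n_beats must be at least 2")


@dataclass
class Tachogram:
    """Ordered RR-interval series in milliseconds."""

    rr_ms: np.ndarray
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.rr_ms.ndim != 1:
            raise ValidationError("rr_ms must be one-dimensional")
        if not np.all(np.isfinite(self.rr_ms)):
            raise ValidationError("rr_ms must be finite")
        if np.any(self.rr_ms <= 0):
            raise ValidationError("all RR intervals must be positive")

    def __len__(self) -> int:
        return self.rr_ms.size

    @property
    def hr_bpm(self) -> np.ndarray:
        """Instantaneous heart rate, 60000 / RR."""
        return 60000.0 / self.rr_ms


@dataclass
class ECGSignal:
    """Uniformly sampled single-lead voltage trace."""

    fs: float
    samples: np.ndarray
    condition_label: Optional[str] = None
    r_indices: Optional[np.ndarray] = None  # ground truth when synthesized

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError("sampling rate fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise ValidationError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class EmbeddingParams:
    """Phase-space reconstruction parameters (delay, dimension, threshold)."""

    tau: int
    m: int
    epsilon_fraction: float = 0.09

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValidationError("tau must be >= 1")
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if not 0 < self.epsilon_fraction < 1:
            raise ValidationError("epsilon_fraction must lie in (0, 1)")


@dataclass
class PoincareSummary:
    """First-return-map ellipse descriptors (ms)."""

    sd1: float
    sd2: float
    centroid: tuple[float, float]
    lag: int = 1
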