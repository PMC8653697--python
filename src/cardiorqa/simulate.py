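"""Synthetic rat ECG generator.

Builds RR tachograms from a bimodal LF/HF power spectrum and renders ECG
traces by sequencing Gaussian-sum PQRST templates, one beat per RR interval.
Four conditions are modelled: a clean deterministic trace (DET), an atrial
fibrillation-like morphology (AF: suppressed P wave plus white noise on the
PQ segment), long-QT (LQT: widened T wave), and a noise-dominated control
(NSE: DET buried in full-amplitude Gaussian noise).  The default heart-rate
statistics (350 +/- 50 bpm) are typical of awake rats.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    CONDITIONS,
    ConditionParams,
    ECGSignal,
    Tachogram,
    TachogramSpec,
    ValidationError,
)

__all__ = [
    "condition_params",
    "build_tachogram",
    "add_tachogram_noise",
    "synthesize_ecg",
    "simulate_recording",
    "NOISE_LEVELS",
    "LF_HF_RATIOS",
    "RR_FLOOR_MS",
]

#: Tachogram white-noise grid (fraction of peak-to-peak RR range).
NOISE_LEVELS = (0.0, 0.33, 0.66, 0.99)
#: LF/HF modulation grid.
LF_HF_RATIOS = (0.0, 0.5, 1.0, 1.5)
#: Hard positivity floor for RR intervals after noising (ms); far below any
#: physiologic rat RR so it only guards against sign flips.
RR_FLOOR_MS = 40.0

_DET = ConditionParams(
    name="DET",
    theta_deg=(-70.0, -15.0, 0.0, 15.0, 100.0),
    a=(1.2, -5.0, 30.0, -7.5, 0.75),
    b=(0.25, 0.1, 0.1, 0.1, 0.4),
)

_REGISTRY: dict[str, ConditionParams] = {
    "DET": _DET,
    "LQT": _DET.with_(name="LQT", b=(0.25, 0.1, 0.1, 0.1, 0.6)),
    "AF": _DET.with_(
        name="AF",
        a=(0.2, -5.0, 30.0, -7.5, 0.75),
        b=(0.125, 0.1, 0.1, 0.1, 0.4),
        pq_noise=True,
    ),
    "NSE": _DET.with_(name="NSE", trace_noise_fraction=1.0),
}


def condition_params(name: str) -> ConditionParams:
    """Return the PQRST template parameters for one of DET/AF/LQT/NSE.

    NSE shares the DET template and differs only in its trace-noise fraction
    (1.00 instead of the default 0.01).
    """
    key = str(name).upper()
    if key not in _REGISTRY:
        raise ValidationError(
            f"unknown condition {name!r}; expected one of {', '.join(CONDITIONS)}"
        )
    return _REGISTRY[key]


def build_tachogram(spec: TachogramSpec) -> Tachogram:
    """Generate an RR series whose spectrum follows the LF/HF recipe.

    The power spectrum ``S(f) = r * G(lf_center, lf_width) + G(hf_center,
    hf_width)`` is sampled on the beat-frequency grid, random phases are
    drawn (seeded), and an inverse real FFT yields a fluctuation series.
    That series is affinely rescaled so the instantaneous heart rate has
    exactly ``mean_hr`` and ``sd_hr`` (sample convention), then converted to
    RR in ms.  HR excursions that would produce non-positive RR are clipped
    and reported via a warning.
    """
    n = spec.n_beats
    rng = np.random.default_rng(spec.seed)

    if spec.sd_hr == 0:
        rr = np.full(n, 60000.0 / spec.mean_hr)
        return Tachogram(rr_ms=rr, origin="synthetic")

    # The tachogram is a beat-indexed series; map physical frequencies (Hz)
    # onto its spectrum using the mean beat rate as the sampling rate.
    fs_beats = spec.mean_hr / 60.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_beats)
    spectrum = spec.lf_hf_ratio * np.exp(
        -0.5 * ((freqs - spec.lf_center) / spec.lf_width) ** 2
    ) + np.exp(-0.5 * ((freqs - spec.hf_center) / spec.hf_width) ** 2)
    spectrum[0] = 0.0  # no DC: the mean is set by the rescale below

    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    coeffs = np.sqrt(spectrum) * np.exp(1j * phases)
    if n % 2 == 0:
        coeffs[-1] = np.sqrt(spectrum[-1])  # Nyquist bin must be real
    x = np.fft.irfft(coeffs, n=n)

    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError(
            "spectral synthesis produced a constant series; widen the bands"
        )
    hr = spec.mean_hr + spec.sd_hr * (x - x.mean()) / sd

    hr_floor = 60000.0 / (RR_FLOOR_MS * 100.0)  # 15 bpm: RR capped at 4 s
    if np.any(hr < hr_floor):
        warnings.warn(
            "sd_hr produced non-physiologic HR excursions; clipping applied",
            stacklevel=2,
        )
        hr = np.maximum(hr, hr_floor)
    rr = 60000.0 / hr
    rr = np.maximum(rr, RR_FLOOR_MS)
    return Tachogram(rr_ms=rr, origin="synthetic")


def add_tachogram_noise(
    t: Tachogram,
    level: float,
    seed: int = 0,
    rr_floor_ms: float = RR_FLOOR_MS,
) -> Tachogram:
    """Add zero-mean white Gaussian noise to an RR series.

    The noise SD is ``level`` times the peak-to-peak range of the clean
    tachogram (the grid used throughout is 0, 0.33, 0.66, 0.99).  Output RR
    values are floored at ``rr_floor_ms`` to preserve positivity.
    """
    if level < 0:
        raise ValidationError("noise level must be non-negative")
    if rr_floor_ms <= 0:
        raise ValidationError("rr_floor_ms must be positive")
    rr = t.rr_ms
    if level == 0:
        return Tachogram(rr_ms=rr.copy(), origin=t.origin)
    span = float(np.ptp(rr))
    if span == 0:
        warnings.warn(
            "constant tachogram: peak-to-peak range is 0; "
            "falling back to SD = level * mean(rr) * 0.01",
            stacklevel=2,
        )
        sd = level * float(rr.mean()) * 0.01
    else:
        sd = level * span
    rng = np.random.default_rng(seed)
    noised = rr + rng.normal(0.0, sd, size=rr.size)
    return Tachogram(rr_ms=np.maximum(noised, rr_floor_ms), origin=t.origin)


def _beat_template(params: ConditionParams, n_samples: int) -> np.ndarray:
    """Render one beat on theta in [-pi, pi) with the R peak at theta = 0."""
    theta = -np.pi + 2.0 * np.pi * np.arange(n_samples) / n_samples
    beat = np.zeros(n_samples)
    for theta_w, a_w, b_w in zip(params.theta_deg, params.a, params.b):
        d = theta - np.deg2rad(theta_w)
        d = np.mod(d + np.pi, 2.0 * np.pi) - np.pi  # wrapped phase distance
        beat += a_w * np.exp(-(d**2) / (2.0 * b_w**2))
    return beat


# PQ segment on the beat cycle (degrees): from just before the P centre to
# just before the Q wave; used for the AF white-noise overlay.
_PQ_WINDOW_DEG = (-90.0, -20.0)


def synthesize_ecg(
    params: ConditionParams,
    t: Tachogram,
    fs: float = 1000.0,
    seed: int = 0,
) -> ECGSignal:
    """Concatenate Gaussian-sum PQRST beats following a tachogram.

    Each RR interval is rendered as one beat cycle theta in [-pi, pi)
    stretched to RR_k milliseconds, with voltage ``sum_w a_w *
    exp(-dtheta_w^2 / (2 b_w^2))``.  After concatenation, zero-mean Gaussian
    trace noise with SD ``trace_noise_fraction * max|signal|`` is added
    (1% by default; 100% for NSE).  For AF, white noise is additionally laid
    over the PQ segment of every beat.  Ground-truth R-peak sample indices
    are attached to the returned signal.
    """
    if fs < 250:
        raise ValidationError("fs must be at least 250 Hz")
    rng = np.random.default_rng(seed)

    # Cumulative-boundary rounding keeps total duration faithful to the
    # tachogram instead of accumulating per-beat rounding error.
    edges_ms = np.concatenate([[0.0], np.cumsum(t.rr_ms)])
    edges = np.round(edges_ms * fs / 1000.0).astype(int)
    lengths = np.diff(edges)
    if np.any(lengths < 8):
        warnings.warn(
            "some RR intervals are shorter than the template support at this "
            "fs; beats were compressed",
            stacklevel=2,
        )
    lengths = np.maximum(lengths, 2)

    pieces: list[np.ndarray] = []
    r_indices = np.empty(lengths.size, dtype=int)
    offset = 0
    for k, n_k in enumerate(lengths):
        beat = _beat_template(params, n_k)
        if params.pq_noise:
            theta_deg = -180.0 + 360.0 * np.arange(n_k) / n_k
            mask = (theta_deg >= _PQ_WINDOW_DEG[0]) & (
                theta_deg <= _PQ_WINDOW_DEG[1]
            )
            beat[mask] += rng.normal(0.0, params.pq_noise_sd, size=mask.sum())
        pieces.append(beat)
        r_indices[k] = offset + n_k // 2  # theta closest to 0
        offset += n_k

    signal = np.concatenate(pieces)
    peak = float(np.max(np.abs(signal)))
    if params.trace_noise_fraction > 0 and peak > 0:
        signal = signal + rng.normal(
            0.0, params.trace_noise_fraction * peak, size=signal.size
        )
    return ECGSignal(
        fs=fs,
        samples=signal,
        condition_label=params.name,
        r_indices=r_indices,
    )


def simulate_recording(
    condition: str,
    lf_hf_ratio: float = 1.0,
    noise_level: float = 0.0,
    n_beats: int = 2048,
    fs: float = 1000.0,
    seed: int = 0,
    mean_hr: float = 350.0,
    sd_hr: float = 50.0,
) -> tuple[ECGSignal, Tachogram]:
    """One-call pipeline: tachogram -> tachogram noise -> ECG trace.

    Independent sub-streams for the three stochastic stages are spawned from
    ``seed`` so the full recording is reproducible bit-for-bit.
    """
    s_tacho, s_noise, s_ecg = np.random.SeedSequence(seed).spawn(3)
    spec = TachogramSpec(
        mean_hr=mean_hr,
        sd_hr=sd_hr,
        lf_hf_ratio=lf_hf_ratio,
        n_beats=n_beats,
        seed=s_tacho.generate_state(1)[0] % (2**31),
    )
    tacho = build_tachogram(spec)
    noised = add_tachogram_noise(
        tacho, noise_level, seed=s_noise.generate_state(1)[0] % (2**31)
    )
    params = condition_params(condition)
    ecg = synthesize_ecg(
        params, noised, fs=fs, seed=s_ecg.generate_state(1)[0] % (2**31)
    )
    return ecg, noised
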