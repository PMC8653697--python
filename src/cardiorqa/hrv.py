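"""Time-domain heart-rate variability and Poincare-map descriptors.

SDNN captures overall (long-period) variability of the RR series, RMSSD the
beat-to-beat (short-period, vagally mediated) variability.  The Poincare
first-return map scatters RR_t against RR_{t+lag}; SD1 is the dispersion
perpendicular to the line of identity and SD2 the dispersion along it.

All statistics use the sample (n-1) convention, so the classical identities
SD1 = RMSSD/sqrt(2) and SD1^2 + SD2^2 = 2*SDNN^2 hold to O(1/n) rather than
exactly.  No NN (ectopy) filtering is applied by default; pass a filter
callable to preprocess the tachogram if needed.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .types import PoincareSummary, Tachogram, ValidationError

__all__ = ["sdnn", "rmssd", "poincare", "hrv_summary"]

ArtifactFilter = Callable[[np.ndarray], np.ndarray]


def _intervals(t: Tachogram, nn_filter: Optional[ArtifactFilter]) -> np.ndarray:
    rr = t.rr_ms
    if nn_filter is not None:
        rr = np.asarray(nn_filter(rr), dtype=float)
    if rr.size < 2:
        raise ValidationError("need at least 2 RR intervals")
    return rr


def sdnn(t: Tachogram, nn_filter: Optional[ArtifactFilter] = None) -> float:
    """Sample standard deviation (ddof=1) of the RR intervals, in ms."""
    rr = _intervals(t, nn_filter)
    return float(np.std(rr, ddof=1))


def rmssd(t: Tachogram, nn_filter: Optional[ArtifactFilter] = None) -> float:
    """Root mean square of successive RR differences, in ms."""
    rr = _intervals(t, nn_filter)
    return float(np.sqrt(np.mean(np.diff(rr) ** 2)))


def poincare(
    t: Tachogram,
    lag: int = 1,
    nn_filter: Optional[ArtifactFilter] = None,
) -> PoincareSummary:
    """SD1/SD2 ellipse descriptors of the lagged return map.

    With x = RR[:-lag] and y = RR[lag:]: SD1 is the sample SD of
    (x - y)/sqrt(2), SD2 the sample SD of (x + y)/sqrt(2); the centroid is
    (mean x, mean y).
    """
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    rr = _intervals(t, nn_filter)
    if rr.size < lag + 2:
        raise ValidationError(f"need at least lag+2 = {lag + 2} intervals")
    x = rr[:-lag]
    y = rr[lag:]
    sd1 = float(np.std((x - y) / np.sqrt(2.0), ddof=1))
    sd2 = float(np.std((x + y) / np.sqrt(2.0), ddof=1))
    return PoincareSummary(
        sd1=sd1, sd2=sd2, centroid=(float(x.mean()), float(y.mean())), lag=lag
    )


def hrv_summary(t: Tachogram, lag: int = 1) -> dict[str, float]:
    """SDNN, RMSSD, SD1 and SD2 in one call (the CLI's one-row output)."""
    pm = poincare(t, lag=lag)
    return {
        "sdnn_ms": sdnn(t),
        "rmssd_ms": rmssd(t),
        "sd1_ms": pm.sd1,
        "sd2_ms": pm.sd2,
    }
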