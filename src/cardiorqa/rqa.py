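"""Recurrence quantification analysis.

The pipeline is: delay selection by the first drop of average mutual
information below AMI(0)/e (Sturges-binned histograms), embedding-dimension
selection by the Kennel false-nearest-neighbour criterion (< 0.1), Takens
delay embedding, a max-diameter-normalized Euclidean distance matrix,
thresholding at a fraction epsilon of the diameter (9% by default), and ten
recurrence factors computed from the diagonal- and vertical-line structure
of the resulting binary plot:

========  =====================================================
RecR      recurrence rate (density of off-LOI recurrences)
DTM       determinism: fraction of recurrence points on
          diagonals of length >= l_min
<D>       mean diagonal line length (d >= l_min)
Dmax      maximum diagonal line length (d >= l_min)
ENTR      Shannon entropy of the diagonal length distribution
LAM       laminarity: fraction of points on verticals >= l_min
TT        trapping time: mean vertical line length (v >= l_min)
Vmax      maximum vertical line length
T1        mean vertical return time, sojourn points included
T2        mean vertical return time between run onsets
========  =====================================================

Diagonal statistics exclude a Theiler band of width 1 around the line of
identity so that trivial self-recurrence does not inflate determinism.
Factors with no qualifying structure are reported as 0 and flagged.  This
module is RNG-free: all stochasticity lives upstream in the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .types import ECGSignal, EmbeddingParams, ValidationError

__all__ = [
    "average_mutual_information",
    "select_tau",
    "false_nearest_neighbors",
    "select_m",
    "embed",
    "distance_matrix",
    "recurrence_plot",
    "rqa_factors",
    "select_embedding",
    "factor_table",
    "RecurrencePlot",
    "RQAFactorVector",
    "FACTOR_NAMES",
]

FACTOR_NAMES = (
    "recr",
    "dtm",
    "mean_diag",
    "dmax",
    "entr",
    "lam",
    "tt",
    "vmax",
    "t1",
    "t2",
)


# ---------------------------------------------------------------------------
# parameter selection


def _sturges_bins(n: int) -> int:
    return int(np.ceil(1.0 + np.log2(n)))


def average_mutual_information(x: np.ndarray, max_lag: int) -> np.ndarray:
    """AMI(tau) in nats for tau = 0..max_lag from Sturges-binned histograms.

    The joint histogram of (x_t, x_{t+tau}) uses the same bin edges on both
    axes, so AMI(0) equals the Shannon entropy of the binned series.  A
    constant series has zero entropy and returns an all-zero curve.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= max_lag + 1:
        raise ValidationError("series must be longer than max_lag + 1")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return np.zeros(max_lag + 1)
    edges = np.linspace(lo, hi, _sturges_bins(n) + 1)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = x[: n - lag]
        b = x[lag:]
        joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        mask = p > 0
        ami[lag] = float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    return ami


def select_tau(ami: np.ndarray) -> int:
    """Smallest tau >= 1 with AMI(tau) <= AMI(0)/e; argmin fallback.

    If the curve never drops below the 1/e threshold (e.g. a monotone ramp
    binned coarsely), the lag minimising AMI is returned with a warning.
    """
    ami = np.asarray(ami, dtype=float)
    if ami.size == 0:
        raise ValidationError("AMI curve is empty")
    if ami.size == 1:
        return 1
    threshold = ami[0] / np.e
    below = np.flatnonzero(ami[1:] <= threshold)
    if below.size:
        return int(below[0] + 1)
    warnings.warn(
        "AMI never dropped below AMI(0)/e; falling back to argmin",
        stacklevel=2,
    )
    return int(np.argmin(ami[1:]) + 1)


def false_nearest_neighbors(
    x: np.ndarray,
    tau: int,
    m_max: int = 8,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
) -> np.ndarray:
    """Kennel false-nearest-neighbour fraction for m = 1..m_max.

    A neighbour pair at dimension m is false when the extra coordinate
    revealed at m+1 either stretches the pair by more than ``r_tol`` relative
    to its m-dimensional distance, or moves it beyond ``a_tol`` attractor
    sizes (SD of the series).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m_max * tau + 1:
        raise ValidationError("series too short to embed at m_max")
    sd = float(x.std())
    if sd == 0:
        warnings.warn("constant series: FNN fractions are all 0", stacklevel=2)
        return np.zeros(m_max)
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        pts = embed(x, tau, m)
        # only points whose (m+1)-th coordinate exists can be tested
        n_test = n - m * tau
        pts = pts[:n_test]
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=2)
        d_m = dist[:, 1]
        nb = idx[:, 1]
        extra = np.abs(x[np.arange(n_test) + m * tau] - x[nb + m * tau])
        # pairs at (numerically) zero distance carry no stretch information
        # (exactly periodic data); exclude them from the criterion
        valid = d_m > 1e-10 * sd
        if not np.any(valid):
            fractions[m - 1] = 0.0
            continue
        stretch = extra[valid] / d_m[valid]
        d_m1 = np.sqrt(d_m[valid] ** 2 + extra[valid] ** 2)
        false = (stretch > r_tol) | (d_m1 / sd > a_tol)
        fractions[m - 1] = float(false.mean())
    return fractions


def select_m(fnn: np.ndarray, threshold: float = 0.1) -> int:
    """First embedding dimension whose FNN fraction drops below 0.1.

    Falls back to the largest tested dimension (with a warning) when no
    dimension qualifies.
    """
    fnn = np.asarray(fnn, dtype=float)
    if fnn.size == 0:
        raise ValidationError("FNN curve is empty")
    below = np.flatnonzero(fnn < threshold)
    if below.size:
        return int(below[0] + 1)
    warnings.warn(
        f"no dimension reached FNN < {threshold}; using m_max = {fnn.size}",
        stacklevel=2,
    )
    return int(fnn.size)


# ---------------------------------------------------------------------------
# embedding and recurrence plot


def embed(x: np.ndarray, tau: int, m: int) -> np.ndarray:
    """Takens delay embedding: point i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(x, dtype=float)
    if tau < 1 or m < 1:
        raise ValidationError("tau and m must be >= 1")
    n_points = x.size - (m - 1) * tau
    if n_points < 1:
        raise ValidationError("series too short for this (tau, m)")
    return np.stack([x[j * tau : j * tau + n_points] for j in range(m)], axis=1)


def distance_matrix(ps: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances normalized by the max phase-space diameter.

    The result lies in [0, 1] with zero diagonal; an all-identical point
    cloud has zero diameter and yields the zero matrix (with a warning).
    """
    ps = np.atleast_2d(np.asarray(ps, dtype=float))
    d = squareform(pdist(ps))
    diameter = d.max() if d.size else 0.0
    if diameter == 0:
        warnings.warn("degenerate phase space: max diameter is 0", stacklevel=2)
        return d
    return d / diameter


def _run_lengths(col: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    padded = np.concatenate(([0], col.astype(np.int8), [0]))
    changes = np.diff(padded)
    starts = np.flatnonzero(changes == 1)
    ends = np.flatnonzero(changes == -1)
    return ends - starts


def _run_length_hist(segments: list[np.ndarray], max_len: int) -> np.ndarray:
    """Histogram of maximal-run lengths pooled over many boolean segments.

    Segments are concatenated with zero separators so a single run-length
    encoding pass covers all of them.
    """
    hist = np.zeros(max_len + 1, dtype=np.int64)
    if not segments:
        return hist
    parts: list[np.ndarray] = [np.zeros(1, dtype=np.int8)]
    sep = np.zeros(1, dtype=np.int8)
    for seg in segments:
        parts.append(seg.astype(np.int8))
        parts.append(sep)
    flat = np.concatenate(parts)
    changes = np.diff(flat)
    lengths = np.flatnonzero(changes == -1) - np.flatnonzero(changes == 1)
    if lengths.size:
        hist[: lengths.max() + 1] = np.bincount(lengths)
    return hist


@dataclass
class RecurrencePlot:
    """Binary recurrence matrix with its line-length histograms.

    ``diag_hist[L]`` counts maximal diagonal runs of length exactly L over
    all diagonals with offset |i-j| >= theiler_window; ``vert_hist[L]``
    counts maximal vertical runs over all columns (LOI included, as is
    standard for laminarity statistics).
    """

    matrix: np.ndarray
    theiler_window: int = 1
    l_min: int = 3
    diag_hist: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    vert_hist: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValidationError("recurrence matrix must be square")
        if self.matrix.shape[0] == 0:
            raise ValidationError("recurrence matrix is empty")
        n = self.matrix.shape[0]
        if self.diag_hist is None or self.vert_hist is None:
            diags = [
                np.diagonal(self.matrix, offset)
                for offset in range(-(n - 1), n)
                if abs(offset) >= self.theiler_window
            ]
            self.diag_hist = _run_length_hist(diags, n)
            self.vert_hist = _run_length_hist(
                [self.matrix[:, j] for j in range(n)], n
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def recurrence_plot(
    dm: np.ndarray,
    epsilon_fraction: float = 0.09,
    theiler_window: int = 1,
    l_min: int = 3,
) -> RecurrencePlot:
    """Threshold a normalized distance matrix into a recurrence plot.

    Entry (i, j) is recurrent when dm(i, j) < epsilon_fraction.  The stored
    matrix keeps the line of identity; the Theiler band only affects the
    diagonal-line histogram.
    """
    dm = np.asarray(dm, dtype=float)
    if not 0 < epsilon_fraction <= 1:
        raise ValidationError("epsilon_fraction must lie in (0, 1]")
    return RecurrencePlot(
        matrix=dm < epsilon_fraction,
        theiler_window=theiler_window,
        l_min=l_min,
    )


# ---------------------------------------------------------------------------
# factors


@dataclass
class RQAFactorVector:
    """The ten recurrence factors for one epoch, in fixed order.

    ``undefined`` names the factors for which no qualifying line structure
    existed; those entries are 0 by convention.
    """

    recr: float
    dtm: float
    mean_diag: float
    dmax: int
    entr: float
    lam: float
    tt: float
    vmax: int
    t1: float
    t2: float
    undefined: frozenset[str] = frozenset()

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FACTOR_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FACTOR_NAMES}


def rqa_factors(rp: RecurrencePlot) -> RQAFactorVector:
    """Compute the ten recurrence factors from a recurrence plot.

    Diagonal factors use the Theiler-excluded diagonal histogram; DTM and
    LAM are normalized over all recurrence points (any line length >= 1) of
    their respective histograms.  Return times T1/T2 pool the gaps between
    successive recurrence indices down every column, T2 after collapsing
    each run of consecutive recurrences to its onset (sojourn removal).
    """
    m = rp.matrix
    n = rp.n
    l_min = rp.l_min
    undefined: set[str] = set()

    off_diag = int(m.sum()) - int(np.trace(m))
    recr = off_diag / (n * n - n) if n > 1 else 0.0

    d_hist = rp.diag_hist
    lengths = np.arange(d_hist.size)
    d_points_all = float((lengths * d_hist).sum())
    d_points_long = float((lengths[l_min:] * d_hist[l_min:]).sum())
    d_count_long = float(d_hist[l_min:].sum())
    if d_points_all > 0:
        dtm = d_points_long / d_points_all
    else:
        dtm = 0.0
        undefined.add("dtm")
    if d_count_long > 0:
        mean_diag = d_points_long / d_count_long
        dmax = int(np.flatnonzero(d_hist[l_min:])[-1] + l_min)
        p = d_hist[l_min:][d_hist[l_min:] > 0] / d_count_long
        entr = float(-(p * np.log(p)).sum())
    else:
        mean_diag, dmax, entr = 0.0, 0, 0.0
        undefined.update({"mean_diag", "dmax", "entr"})

    v_hist = rp.vert_hist
    v_lengths = np.arange(v_hist.size)
    v_points_all = float((v_lengths * v_hist).sum())
    v_points_long = float((v_lengths[l_min:] * v_hist[l_min:]).sum())
    v_count_long = float(v_hist[l_min:].sum())
    if v_points_all > 0:
        lam = v_points_long / v_points_all
        vmax = int(np.flatnonzero(v_hist)[-1])
    else:
        lam, vmax = 0.0, 0
        undefined.update({"lam", "vmax"})
    if v_count_long > 0:
        tt = v_points_long / v_count_long
    else:
        tt = 0.0
        undefined.add("tt")

    t1_sum = 0.0
    t1_n = 0
    t2_sum = 0.0
    t2_n = 0
    for j in range(n):
        idx = np.flatnonzero(m[:, j])
        if idx.size >= 2:
            gaps = np.diff(idx)
            t1_sum += float(gaps.sum())
            t1_n += gaps.size
            onsets = idx[np.concatenate(([True], gaps > 1))]
            if onsets.size >= 2:
                g2 = np.diff(onsets)
                t2_sum += float(g2.sum())
                t2_n += g2.size
    if t1_n > 0:
        t1 = t1_sum / t1_n
    else:
        t1 = 0.0
        undefined.add("t1")
    if t2_n > 0:
        t2 = t2_sum / t2_n
    else:
        t2 = 0.0
        undefined.add("t2")

    return RQAFactorVector(
        recr=recr,
        dtm=dtm,
        mean_diag=mean_diag,
        dmax=dmax,
        entr=entr,
        lam=lam,
        tt=tt,
        vmax=vmax,
        t1=t1,
        t2=t2,
        undefined=frozenset(undefined),
    )


# ---------------------------------------------------------------------------
# per-recording pipeline


def select_embedding(
    x: np.ndarray,
    fs: float,
    window_s: float = 20.0,
    n_windows: int = 10,
    max_lag: int = 50,
    m_max: int = 8,
    epsilon_fraction: float = 0.09,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
) -> EmbeddingParams:
    """Per-recording (tau, m) selection aggregated over epoch windows.

    tau is the median first-1/e-crossing of the AMI curve over up to
    ``n_windows`` consecutive windows of ``window_s`` seconds; m is the
    first dimension whose FNN fraction, averaged over the same windows at
    the selected tau, drops below 0.1.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * fs))
    w = min(w, x.size)
    if w < max_lag + 2:
        raise ValidationError("window too short for the AMI max_lag")
    n_fit = min(n_windows, x.size // w)
    windows = [x[k * w : (k + 1) * w] for k in range(max(n_fit, 1))]

    taus = [select_tau(average_mutual_information(win, max_lag)) for win in windows]
    tau = int(np.median(taus))

    fnn_curves = []
    for win in windows:
        if win.size > m_max * tau + 1:
            fnn_curves.append(
                false_nearest_neighbors(win, tau, m_max, r_tol, a_tol)
            )
    if not fnn_curves:
        raise ValidationError("windows too short for FNN at the selected tau")
    m = select_m(np.mean(fnn_curves, axis=0))
    return EmbeddingParams(tau=tau, m=m, epsilon_fraction=epsilon_fraction)


def factor_table(
    ecg: ECGSignal,
    epoch_s: float = 20.0,
    n_epochs: int = 15,
    embedding: EmbeddingParams | None = None,
    theiler_window: int = 1,
    l_min: int = 3,
    m_max: int = 8,
    max_lag: int = 50,
) -> pd.DataFrame:
    """Per-epoch table of the ten recurrence factors for one recording.

    The trace is cut into up to ``n_epochs`` consecutive epochs of
    ``epoch_s`` seconds.  Unless an embedding is supplied, (tau, m) are
    selected once per recording from the epoch windows and shared by all
    epochs; epsilon is applied per epoch after per-epoch distance-matrix
    normalization.  Columns: the ten factors, tau, m, epsilon, and a flag
    marking epochs with any undefined factor.
    """
    x = ecg.samples
    w = int(round(epoch_s * ecg.fs))
    n_avail = x.size // w
    if n_avail == 0:
        raise ValidationError("recording shorter than one epoch")
    n_use = min(n_epochs, n_avail)

    if embedding is None:
        embedding = select_embedding(
            x, ecg.fs, window_s=epoch_s, n_windows=n_use,
            max_lag=max_lag, m_max=m_max,
        )

    rows = []
    for k in range(n_use):
        seg = x[k * w : (k + 1) * w]
        ps = embed(seg, embedding.tau, embedding.m)
        rp = recurrence_plot(
            distance_matrix(ps),
            epsilon_fraction=embedding.epsilon_fraction,
            theiler_window=theiler_window,
            l_min=l_min,
        )
        fv = rqa_factors(rp)
        row = fv.as_dict()
        row["tau"] = embedding.tau
        row["m"] = embedding.m
        row["epsilon"] = embedding.epsilon_fraction
        row["epoch"] = k
        row["any_undefined"] = bool(fv.undefined)
        rows.append(row)
    return pd.DataFrame(rows).set_index("epoch")
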