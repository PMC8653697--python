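"""Cohort-level analysis of recurrence-factor matrices.

A factor matrix stacks the per-epoch 10-entry recurrence vectors of many
recordings (rows = epochs, columns = factors).  This module fits a
standardized PCA on such a matrix, projects new recordings into the fitted
space without refitting, measures Euclidean distances between condition
centroids in the PC1-PC2 plane, builds a hierarchical clustergram, and runs
the nonparametric group statistics (Kolmogorov-Smirnov normality screen,
Kruskal-Wallis with Tukey-Kramer follow-up on rank means, Mann-Whitney for
two groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .rqa import FACTOR_NAMES
from .types import ValidationError

__all__ = [
    "PCAModel",
    "pca_fit",
    "pca_project",
    "centroid_distances",
    "clustergram",
    "group_tests",
    "build_factor_matrix",
    "simulate_grid_factor_matrix",
]


def build_factor_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack labelled per-epoch factor tables into one cohort matrix.

    ``tables`` maps a recording label (e.g. "DET/noise0/lfhf0.5") to the
    output of :func:`cardiorqa.rqa.factor_table`.  Only the ten factor
    columns are kept; the label is stored in a ``label`` column.  Epochs
    flagged with undefined factors keep their 0-imputed values (the flag
    column itself never enters PCA).
    """
    frames = []
    for label, table in tables.items():
        sub = table.loc[:, list(FACTOR_NAMES)].copy()
        sub["label"] = label
        frames.append(sub)
    if not frames:
        raise ValidationError("no factor tables supplied")
    return pd.concat(frames, ignore_index=True)


def simulate_grid_factor_matrix(
    seed: int = 0,
    conditions: tuple[str, ...] = ("DET", "AF", "LQT", "NSE"),
    noise_levels: tuple[float, ...] | None = None,
    lf_hf_ratios: tuple[float, ...] | None = None,
    n_epochs: int = 20,
    epoch_s: float = 4.0,
    fs: float = 250.0,
    n_beats: int | None = None,
) -> pd.DataFrame:
    """Per-epoch recurrence factors for the full simulated condition grid.

    Simulates every (condition, tachogram-noise, LF/HF) cell of the default
    4x4x4 grid with seeds spawned from ``seed``, segments each recording
    into ``n_epochs`` epochs, and returns one row per epoch: the ten
    factors plus ``condition``, ``noise_level``, ``lf_hf_ratio`` metadata
    columns and a ``label`` column (the condition name, the PCA grouping
    the protocol uses).
    """
    from . import rqa as _rqa
    from . import simulate as _simulate

    noise_levels = noise_levels or _simulate.NOISE_LEVELS
    lf_hf_ratios = lf_hf_ratios or _simulate.LF_HF_RATIOS
    if n_beats is None:
        # enough beats at the rat mean rate to fill the requested epochs
        n_beats = int(np.ceil((n_epochs + 1) * epoch_s * 350.0 / 60.0))

    combos = [
        (c, nz, r) for c in conditions for nz in noise_levels for r in lf_hf_ratios
    ]
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(len(combos))
    ]
    frames = []
    for (cond, noise, ratio), sub_seed in zip(combos, seeds):
        ecg, _ = _simulate.simulate_recording(
            cond,
            lf_hf_ratio=ratio,
            noise_level=noise,
            n_beats=n_beats,
            fs=fs,
            seed=sub_seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # FNN fallback on noise-only cells
            table = _rqa.factor_table(ecg, epoch_s=epoch_s, n_epochs=n_epochs)
        sub = table.loc[:, list(FACTOR_NAMES)].reset_index(drop=True)
        sub["condition"] = cond
        sub["noise_level"] = noise
        sub["lf_hf_ratio"] = ratio
        sub["label"] = cond
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


@dataclass
class PCAModel:
    """Standardized PCA: z-scoring parameters plus orthonormal loadings."""

    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (n_kept_columns, n_components)
    explained_variance_ratio: np.ndarray
    dropped_columns: tuple[str, ...] = ()


def pca_fit(fm: pd.DataFrame, standardize: bool = True) -> PCAModel:
    """Fit PCA on the factor columns of a cohort matrix.

    Columns are z-scored (sample SD) before eigendecomposition of the
    covariance, so explained-variance fractions are fractions of the total
    standardized variance.  Zero-variance columns are dropped with a
    warning.  Component signs follow a deterministic convention: the largest
    |loading| entry of each component is made positive.
    """
    cols = [c for c in fm.columns if c != "label"]
    X = fm.loc[:, cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 rows to fit PCA")
    if not np.all(np.isfinite(X)):
        raise ValidationError("factor matrix contains non-finite values")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = tuple(np.asarray(cols)[~keep])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    kept_cols = tuple(np.asarray(cols)[keep])
    X = X[:, keep]
    means = means[keep]
    sds = sds[keep]
    if standardize:
        Z = (X - means) / sds
    else:
        Z = X - means
        sds = np.ones_like(sds)

    cov = np.cov(Z, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, k]))
        if evecs[pivot, k] < 0:
            evecs[:, k] = -evecs[:, k]
    total = evals.sum()
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    return PCAModel(
        columns=kept_cols,
        means=means,
        sds=sds,
        loadings=evecs,
        explained_variance_ratio=ratio,
        dropped_columns=dropped,
    )


def pca_project(model: PCAModel, rows: pd.DataFrame) -> np.ndarray:
    """Project new rows with the fitted standardization and loadings.

    The row columns must contain every fitted column; no refit happens, so
    projecting points far from the training cloud is legitimate (that is
    the point of the protocol).
    """
    missing = [c for c in model.columns if c not in rows.columns]
    if missing:
        raise ValidationError(f"rows are missing fitted columns: {missing}")
    X = rows.loc[:, list(model.columns)].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds
    return Z @ model.loadings


def centroid_distances(
    scores: np.ndarray,
    labels: np.ndarray | list[str],
    reference_label: str,
    n_components: int = 2,
) -> pd.DataFrame:
    """Per-label centroids in the leading PC plane and their distance to a reference.

    Returns one row per label with centroid coordinates and the Euclidean
    distance from that centroid to the reference label's centroid (default:
    in the PC1-PC2 plane).
    """
    scores = np.asarray(scores, dtype=float)[:, :n_components]
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))  # stable order
    if reference_label not in uniq:
        raise ValidationError(f"reference label {reference_label!r} not present")
    cents = {lab: scores[labels == lab].mean(axis=0) for lab in uniq}
    ref = cents[reference_label]
    records = []
    for lab in uniq:
        c = cents[lab]
        records.append(
            {
                "label": lab,
                **{f"pc{k + 1}": c[k] for k in range(n_components)},
                "distance_to_reference": float(np.linalg.norm(c - ref)),
            }
        )
    return pd.DataFrame(records).set_index("label")


@dataclass
class Clustergram:
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    row_order: np.ndarray
    col_order: np.ndarray | None
    ordered: pd.DataFrame


def clustergram(fm: pd.DataFrame, standardize: bool = True) -> Clustergram:
    """Average-linkage Euclidean clustergram of a factor matrix.

    Rows and columns of the (z-scored) matrix are clustered independently;
    the returned frame is reordered by the deterministic scipy leaf order.
    """
    cols = [c for c in fm.columns if c != "label"]
    X = fm.loc[:, cols].to_numpy(dtype=float)
    if standardize and X.shape[0] > 1:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if X.shape[0] == 1:
        ordered = pd.DataFrame(X, columns=cols)
        return Clustergram(
            row_linkage=np.empty((0, 4)),
            col_linkage=None,
            row_order=np.array([0]),
            col_order=None,
            ordered=ordered,
        )
    row_link = hierarchy.linkage(X, method="average", metric="euclidean")
    row_order = hierarchy.leaves_list(row_link)
    col_link = None
    col_order = None
    if X.shape[1] > 1:
        col_link = hierarchy.linkage(X.T, method="average", metric="euclidean")
        col_order = hierarchy.leaves_list(col_link)
    ordered = pd.DataFrame(X, columns=cols).iloc[row_order]
    if col_order is not None:
        ordered = ordered.iloc[:, col_order]
    return Clustergram(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=row_order,
        col_order=col_order,
        ordered=ordered,
    )


def _tukey_kramer_ranks(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparison of mean ranks after Kruskal-Wallis.

    All observations are ranked jointly (ties averaged); each pair of groups
    is compared through the studentized-range distribution of the mean-rank
    difference, SE = sqrt(N(N+1)/12 * (1/n_i + 1/n_j)).  This mirrors the
    usual stats-toolbox follow-up and is an approximation, not an exact
    rank test.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    sizes = [groups[g].size for g in names]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = dict(zip(names, [r.mean() for r in np.split(ranks, splits)]))
    n_total = pooled.size
    k = len(names)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = names[i], names[j]
            diff = mean_ranks[gi] - mean_ranks[gj]
            se = np.sqrt(
                n_total * (n_total + 1) / 12.0
                * (1.0 / groups[gi].size + 1.0 / groups[gj].size)
            )
            q = np.sqrt(2.0) * abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, np.inf))
            rows.append(
                {
                    "group_a": gi,
                    "group_b": gj,
                    "mean_rank_diff": diff,
                    "p_value": min(max(p, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupTestReport:
    normality: pd.DataFrame
    omnibus: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05


def group_tests(samples: dict[str, np.ndarray], alpha: float = 0.05) -> GroupTestReport:
    """Nonparametric comparison of named groups.

    Each group is first screened for normality with a Kolmogorov-Smirnov
    test against a normal with the sample's own mean/SD.  Two groups are
    compared with Mann-Whitney U (exact when sample sizes permit); more
    than two with Kruskal-Wallis followed by Tukey-Kramer on rank means.
    Groups with fewer than 2 observations are excluded with a warning.
    """
    groups = {}
    for name, values in samples.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {name!r} has <2 observations; excluded", stacklevel=2)
            continue
        groups[name] = arr
    if len(groups) < 2:
        raise ValidationError("need at least 2 usable groups")

    norm_rows = []
    for name, arr in groups.items():
        sd = arr.std(ddof=1)
        if sd == 0:
            stat, p = np.nan, 0.0
        else:
            stat, p = stats.kstest((arr - arr.mean()) / sd, "norm")
        norm_rows.append(
            {"group": name, "ks_stat": stat, "p_value": p, "normal": p >= alpha}
        )
    normality = pd.DataFrame(norm_rows).set_index("group")

    if len(groups) == 2:
        (na, a), (nb, b) = groups.items()
        method = "exact" if (a.size <= 25 and b.size <= 25) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        omnibus = {
            "test": "mann-whitney",
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "significant": bool(res.pvalue < alpha),
            "groups": (na, nb),
        }
        posthoc = None
    else:
        res = stats.kruskal(*groups.values())
        omnibus = {
            "test": "kruskal-wallis",
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "significant": bool(res.pvalue < alpha),
            "groups": tuple(groups),
        }
        posthoc = _tukey_kramer_ranks(groups)
        posthoc["significant"] = posthoc["p_value"] < alpha
    return GroupTestReport(
        normality=normality, omnibus=omnibus, posthoc=posthoc, alpha=alpha
    )
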