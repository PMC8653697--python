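"""Brute-force recurrence-factor oracle.

Computes all ten recurrence factors from a binary matrix with naive pure
Python scans: every diagonal and vertical maximal run is enumerated cell by
cell, and return times are read directly off each column's recurrence set.
Intentionally independent of the vectorized implementation it checks.
"""

from __future__ import annotations

import math


def _scan_runs(cells: list[int]) -> list[int]:
    runs = []
    current = 0
    for c in cells:
        if c:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def oracle_factors(
    matrix, theiler_window: int = 1, l_min: int = 3
) -> dict[str, float]:
    m = [[int(bool(v)) for v in row] for row in matrix]
    n = len(m)

    off_diag = sum(m[i][j] for i in range(n) for j in range(n) if i != j)
    recr = off_diag / (n * n - n) if n > 1 else 0.0

    diag_runs: list[int] = []
    for off in range(-(n - 1), n):
        if abs(off) < theiler_window:
            continue
        cells = [
            m[i][i + off]
            for i in range(n)
            if 0 <= i + off < n
        ]
        diag_runs.extend(_scan_runs(cells))

    vert_runs: list[int] = []
    for j in range(n):
        vert_runs.extend(_scan_runs([m[i][j] for i in range(n)]))

    d_all = sum(diag_runs)
    long_d = [d for d in diag_runs if d >= l_min]
    dtm = sum(long_d) / d_all if d_all else 0.0
    mean_diag = sum(long_d) / len(long_d) if long_d else 0.0
    dmax = max(long_d) if long_d else 0
    entr = 0.0
    if long_d:
        total = len(long_d)
        counts: dict[int, int] = {}
        for d in long_d:
            counts[d] = counts.get(d, 0) + 1
        entr = -sum(
            (c / total) * math.log(c / total) for c in counts.values()
        )

    v_all = sum(vert_runs)
    long_v = [v for v in vert_runs if v >= l_min]
    lam = sum(long_v) / v_all if v_all else 0.0
    tt = sum(long_v) / len(long_v) if long_v else 0.0
    vmax = max(vert_runs) if vert_runs else 0

    t1_gaps: list[int] = []
    t2_gaps: list[int] = []
    for j in range(n):
        idx = [i for i in range(n) if m[i][j]]
        for a, b in zip(idx, idx[1:]):
            t1_gaps.append(b - a)
        onsets = [i for i in idx if i - 1 not in idx]
        for a, b in zip(onsets, onsets[1:]):
            t2_gaps.append(b - a)
    t1 = sum(t1_gaps) / len(t1_gaps) if t1_gaps else 0.0
    t2 = sum(t2_gaps) / len(t2_gaps) if t2_gaps else 0.0

    return {
        "recr": recr,
        "dtm": dtm,
        "mean_diag": mean_diag,
        "dmax": dmax,
        "entr": entr,
        "lam": lam,
        "tt": tt,
        "vmax": vmax,
        "t1": t1,
        "t2": t2,
    }
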