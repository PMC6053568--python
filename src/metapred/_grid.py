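"""Internal dense-array view of long-format time series.

Runs (or experimental rounds) sharing the same sampling grid are stacked into
batches of shape (runs, times, patches) so that aggregation, transition
building and bootstrap resampling are single vectorised array operations.
Only used internally; the public API speaks DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GridBatch:
    run_ids: np.ndarray  # (B,)
    times: np.ndarray  # (T,) shared sampling times
    H: np.ndarray  # (B, T, N)
    P: np.ndarray  # (B, T, N)


def grid_from_frame(ts: pd.DataFrame):
    """Split a validated long-format frame into dense batches.

    Returns (patches, batches); every run must observe every patch at every
    one of its sampling times (a complete grid per run).
    """
    patches = np.sort(ts["patch_id"].unique())
    n = patches.size
    pos = {p: i for i, p in enumerate(patches)}
    by_times: dict[tuple, list] = {}
    for run_id, g in ts.groupby("run_id", sort=True):
        times = np.sort(g["time"].unique())
        t_pos = {t: i for i, t in enumerate(times)}
        if len(g) != times.size * n:
            raise ValueError(
                f"run {run_id}: incomplete grid "
                f"({len(g)} rows, expected {times.size * n})"
            )
        h = np.zeros((times.size, n), dtype=np.int64)
        p = np.zeros((times.size, n), dtype=np.int64)
        ti = g["time"].map(t_pos).to_numpy()
        pi = g["patch_id"].map(pos).to_numpy()
        h[ti, pi] = g["H"].to_numpy()
        p[ti, pi] = g["P"].to_numpy()
        by_times.setdefault(tuple(times), []).append((run_id, h, p))
    batches = []
    for times, entries in by_times.items():
        batches.append(
            GridBatch(
                run_ids=np.array([e[0] for e in entries]),
                times=np.asarray(times),
                H=np.stack([e[1] for e in entries]),
                P=np.stack([e[2] for e in entries]),
            )
        )
    return patches, batches


def grid_to_frame(patches: np.ndarray, batches) -> pd.DataFrame:
    """Inverse of :func:`grid_from_frame` (row order: run, time, patch)."""
    parts = []
    for b in batches:
        n_b, n_t, n_p = b.H.shape
        parts.append(
            pd.DataFrame(
                {
                    "run_id": np.repeat(b.run_ids, n_t * n_p),
                    "patch_id": np.tile(patches, n_b * n_t),
                    "time": np.tile(np.repeat(b.times, n_p), n_b),
                    "H": b.H.ravel(),
                    "P": b.P.ravel(),
                }
            )
        )
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["run_id", "time", "patch_id"], ignore_index=True)


def transition_xy(H, P):
    """Log-ratio responses and mean-density predictors for one batch.

    Returns (y_td, x_td, y_bu, x_bu, keep) with shape (B, T-1, G); ``keep``
    masks out cells where both species are absent at both ends.
    """
    h0, h1 = H[:, :-1], H[:, 1:]
    p0, p1 = P[:, :-1], P[:, 1:]
    y_td = np.log(h0 + 1.0) - np.log(h1 + 1.0)
    x_td = (p0 + p1) / 2.0
    y_bu = np.log(p1 + 1.0) - np.log(p0 + 1.0)
    x_bu = (h0 + h1) / 2.0
    keep = ~((h0 == 0) & (h1 == 0) & (p0 == 0) & (p1 == 0))
    return y_td, x_td, y_bu, x_bu, keep


def slope_sums(x: np.ndarray, y: np.ndarray) -> float:
    """OLS slope via centred sums; NaN when degenerate (n < 3 or var(x) = 0)."""
    n = x.size
    if n < 3:
        return np.nan
    xm = x.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx <= 0.0:
        return np.nan
    return float(((x - xm) * (y - y.mean())).sum() / sxx)
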