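"""Patch-resampling bootstrap null model for the interaction statistics.

The null hypothesis is that any association between the two species' patch
series is a scale-irrelevant artefact of shared temporal structure (trends,
synchronized fluctuations, experimental procedure).  Each bootstrap iteration
rebuilds the dataset by drawing, independently for every (patch, time) cell
and separately for the two species, a donor patch uniformly with replacement
from all patches at the same time within the same round/run.  This preserves
the time-specific cross-patch distribution -- and hence any common trend --
while destroying within-patch associations between and within species.

Resampling happens at patch scale and is then aggregated, so one iteration
yields mutually consistent null statistics across spatial scales.  Summaries
are the null median, the 2.5/97.5 percentile interval and a two-tailed mid-p
value for the observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._grid import grid_from_frame, grid_to_frame, GridBatch, slope_sums, transition_xy
from .analysis import build_transitions, top_down_effect, bottom_up_effect, aggregate_to_scale
from .habitat import SpatialLayout, partition_matrix

__all__ = [
    "NullDistribution",
    "resample_once",
    "null_distribution",
    "null_summary",
    "pvalue",
]

_METRICS = ("R_TD", "R_BU")


@dataclass
class NullDistribution:
    """Bootstrap null of one interaction statistic at one scale."""

    scale: int
    metric: str
    n_iter: int
    seed: object
    samples: np.ndarray  # NaN entries mark degenerate iterations
    observed: float
    median: float
    ci_low: float
    ci_high: float
    p_value: float
    n_degenerate: int
    valid: bool

    def summary(self) -> dict:
        return {
            "scale": self.scale,
            "metric": self.metric,
            "observed": self.observed,
            "median": self.median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_iter": self.n_iter,
            "n_degenerate": self.n_degenerate,
            "valid": self.valid,
        }


def _resample_batch(batch: GridBatch, rng: np.random.Generator, mode: str) -> GridBatch:
    b, t, n = batch.H.shape
    if mode == "cell":
        donors_h = rng.integers(0, n, size=(b, t, n))
        donors_p = rng.integers(0, n, size=(b, t, n))
    elif mode == "series":
        # one donor per (run, patch), reused along its whole series
        donors_h = np.broadcast_to(rng.integers(0, n, size=(b, 1, n)), (b, t, n))
        donors_p = np.broadcast_to(rng.integers(0, n, size=(b, 1, n)), (b, t, n))
    else:
        raise ValueError(f"unknown resampling mode {mode!r}; expected 'cell' or 'series'")
    return GridBatch(
        run_ids=batch.run_ids,
        times=batch.times,
        H=np.take_along_axis(batch.H, donors_h, axis=2),
        P=np.take_along_axis(batch.P, donors_p, axis=2),
    )


def resample_once(ts: pd.DataFrame, rng: np.random.Generator, mode: str = "cell") -> pd.DataFrame:
    """One bootstrap resample of a patch-scale time series.

    For every patch i and time t the herbivore count is replaced by the count
    of a donor patch k drawn uniformly with replacement from all patches at
    the same time (within the same run/round); predators use an independent
    draw.  ``mode='series'`` draws one donor per patch for its whole series
    instead (a sensitivity-analysis variant).
    """
    patches, batches = grid_from_frame(ts)
    return grid_to_frame(patches, [_resample_batch(b, rng, mode) for b in batches])


def pvalue(samples, observed: float) -> float:
    """Two-tailed mid-p of ``observed`` against bootstrap ``samples``.

    p = 2 * min(r, 1 - r) with r = (#{null <= observed} + 0.5) / (B + 1),
    clipped to at most 1.  The attainable floor is 1 / (B + 1).
    """
    s = np.asarray(samples, dtype=float)
    s = s[~np.isnan(s)]
    b = s.size
    if b < 100:
        raise ValueError(f"need at least 100 null samples, got {b}")
    r = (np.count_nonzero(s <= observed) + 0.5) / (b + 1)
    return float(min(2.0 * min(r, 1.0 - r), 1.0))


def _observed_statistics(ts, layout, scales) -> dict:
    out = {}
    for scale in scales:
        tt = build_transitions(aggregate_to_scale(ts, layout, scale))
        out[(scale, "R_TD")] = top_down_effect(tt, scale)
        out[(scale, "R_BU")] = bottom_up_effect(tt, scale)
    return out


def null_summary(
    ts: pd.DataFrame,
    layout: SpatialLayout,
    scales,
    metrics=_METRICS,
    n_iter: int = 10_000,
    seed=None,
    mode: str = "cell",
) -> list[NullDistribution]:
    """Bootstrap nulls for several (scale, metric) pairs from shared resamples.

    Each iteration resamples the patch-scale data once and evaluates every
    requested scale and metric on that single resample, so nulls are
    consistent across scales.  Iterations use per-iteration RNG substreams
    derived from ``seed``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    scales = tuple(int(s) for s in scales)
    for m in metrics:
        if m not in _METRICS:
            raise ValueError(f"unknown metric {m!r}; expected subset of {_METRICS}")
    _, batches = grid_from_frame(ts)
    mats = {scale: partition_matrix(layout, scale) for scale in scales}
    observed = _observed_statistics(ts, layout, scales)

    samples = {key: np.full(n_iter, np.nan) for key in observed if key[1] in metrics}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for it, child in enumerate(ss.spawn(n_iter)):
        rng = np.random.default_rng(child)
        res = [_resample_batch(b, rng, mode) for b in batches]
        for scale in scales:
            m = mats[scale]
            xs_td, ys_td, xs_bu, ys_bu = [], [], [], []
            for rb in res:
                hg = rb.H if scale == 1 else rb.H @ m
                pg = rb.P if scale == 1 else rb.P @ m
                y_td, x_td, y_bu, x_bu, keep = transition_xy(hg, pg)
                k = keep.ravel()
                xs_td.append(x_td.ravel()[k])
                ys_td.append(y_td.ravel()[k])
                xs_bu.append(x_bu.ravel()[k])
                ys_bu.append(y_bu.ravel()[k])
            if "R_TD" in metrics:
                samples[(scale, "R_TD")][it] = slope_sums(
                    np.concatenate(xs_td), np.concatenate(ys_td)
                )
            if "R_BU" in metrics:
                samples[(scale, "R_BU")][it] = slope_sums(
                    np.concatenate(xs_bu), np.concatenate(ys_bu)
                )

    out = []
    for (scale, metric), vals in samples.items():
        est = observed[(scale, metric)]
        finite = vals[~np.isnan(vals)]
        n_degen = int(n_iter - finite.size)
        valid = est.defined and n_degen <= n_iter // 2 and finite.size >= 100
        if finite.size:
            median = float(np.median(finite))
            ci_low, ci_high = (float(q) for q in np.percentile(finite, [2.5, 97.5]))
        else:
            median = ci_low = ci_high = np.nan
        p = pvalue(finite, est.slope) if valid else np.nan
        out.append(
            NullDistribution(
                scale=scale,
                metric=metric,
                n_iter=n_iter,
                seed=seed,
                samples=vals,
                observed=est.slope,
                median=median,
                ci_low=ci_low,
                ci_high=ci_high,
                p_value=p,
                n_degenerate=n_degen,
                valid=valid,
            )
        )
    return out


def null_distribution(
    ts: pd.DataFrame,
    layout: SpatialLayout,
    scale: int,
    metric: str,
    n_iter: int = 10_000,
    seed=None,
    mode: str = "cell",
) -> NullDistribution:
    """Bootstrap null of one statistic at one scale (see :func:`null_summary`)."""
    (dist,) = null_summary(
        ts, layout, scales=(scale,), metrics=(metric,), n_iter=n_iter, seed=seed, mode=mode
    )
    return dist
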