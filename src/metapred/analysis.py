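"""Scale aggregation, interaction-strength regressions and field metrics.

Interaction strength is measured as the ordinary-least-squares slope of a
log-response-ratio on the mean density of the other species, pooled over all
groups and rounds at a given spatial scale:

* top-down (R_TD): per-interval prey decrease
  ``log(H_t + 1) - log(H_{t+1} + 1)`` against mean predator abundance
  ``(P_t + P_{t+1})/2`` -- the per-capita (per-predator) effect on prey;
* bottom-up (R_BU): per-interval predator increase
  ``log(P_{t+1} + 1) - log(P_t + 1)`` against mean prey abundance.

Natural logarithms with +1 offsets keep zero counts finite.  Transition pairs
where both species are absent at both ends carry no information and are
removed.  Transitions never span round/run boundaries.  Because the slope
notation "R" is ambiguous between a regression coefficient and a correlation,
the Pearson r is reported alongside the slope; the slope is the primary
statistic.

Field metrics summarise metacommunity structure: patch occupancy (fraction of
patches where a species is present, averaged over sampling dates) and the
colonization rate (per interval, newly occupied patches over patches that
started the interval empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._grid import grid_from_frame, transition_xy
from .habitat import SpatialLayout, scale_partition

__all__ = [
    "InteractionEstimate",
    "SummaryStat",
    "FieldMetrics",
    "aggregate_to_scale",
    "build_transitions",
    "top_down_effect",
    "bottom_up_effect",
    "interaction_estimates",
    "occupancy",
    "colonization_rate",
    "field_metrics",
]

SPECIES_COLUMNS = {"H": "H", "herbivore": "H", "aphid": "H",
                   "P": "P", "predator": "P", "ladybeetle": "P"}


@dataclass(frozen=True)
class InteractionEstimate:
    """Pooled OLS estimate of an interaction statistic at one scale.

    ``defined`` is False (and slope/intercept/r are NaN) when there are fewer
    than 3 transition points or the predictor has zero variance.
    """

    metric: str  # "R_TD" or "R_BU"
    slope: float
    intercept: float
    n_points: int
    pearson_r: float
    defined: bool
    scale: int | None = None


@dataclass(frozen=True)
class SummaryStat:
    """Mean and standard error of a per-date (or per-interval) fraction."""

    mean: float
    se: float
    values: np.ndarray
    defined: bool = True


@dataclass(frozen=True)
class FieldMetrics:
    species: str
    occupancy_mean: float
    occupancy_se: float
    colonization_mean: float
    colonization_se: float


def aggregate_to_scale(ts: pd.DataFrame, layout: SpatialLayout, scale: int) -> pd.DataFrame:
    """Sum patch counts into group counts at the given scale.

    The output keeps the long-format schema; ``patch_id`` holds the group
    index.  ``scale=1`` returns the input partition unchanged.
    """
    patches = np.sort(ts["patch_id"].unique())
    if not np.isin(patches, layout.patch_ids).all():
        raise ValueError("time series contains patch ids not present in the layout")
    part = scale_partition(layout, scale)
    out = ts.loc[:, ["run_id", "patch_id", "time", "H", "P"]].copy()
    out["patch_id"] = part[out["patch_id"].to_numpy()]
    out = (
        out.groupby(["run_id", "patch_id", "time"], as_index=False, sort=True)[["H", "P"]]
        .sum()
        .loc[:, ["run_id", "patch_id", "time", "H", "P"]]
    )
    return out.sort_values(["run_id", "time", "patch_id"], ignore_index=True)


def build_transitions(agg: pd.DataFrame) -> pd.DataFrame:
    """One row per group per consecutive recorded-time pair within a run.

    Columns: run_id, group_id, t, H_t, H_t1, P_t, P_t1, y_td, x_td, y_bu,
    x_bu.  Rows with all four counts zero are removed.
    """
    patches, batches = grid_from_frame(agg)
    parts = []
    for b in batches:
        if b.times.size < 2:
            continue
        y_td, x_td, y_bu, x_bu, keep = transition_xy(b.H, b.P)
        n_b, n_t1, n_g = y_td.shape
        frame = pd.DataFrame(
            {
                "run_id": np.repeat(b.run_ids, n_t1 * n_g),
                "group_id": np.tile(patches, n_b * n_t1),
                "t": np.tile(np.repeat(b.times[:-1], n_g), n_b),
                "H_t": b.H[:, :-1].ravel(),
                "H_t1": b.H[:, 1:].ravel(),
                "P_t": b.P[:, :-1].ravel(),
                "P_t1": b.P[:, 1:].ravel(),
                "y_td": y_td.ravel(),
                "x_td": x_td.ravel(),
                "y_bu": y_bu.ravel(),
                "x_bu": x_bu.ravel(),
            }
        )
        parts.append(frame[keep.ravel()])
    if not parts:
        return pd.DataFrame(
            columns=["run_id", "group_id", "t", "H_t", "H_t1", "P_t", "P_t1",
                     "y_td", "x_td", "y_bu", "x_bu"]
        )
    return pd.concat(parts, ignore_index=True)


def _regress(x: np.ndarray, y: np.ndarray, metric: str, scale) -> InteractionEstimate:
    n = x.size
    if n < 3 or np.ptp(x) == 0:
        return InteractionEstimate(metric, np.nan, np.nan, n, np.nan, False, scale)
    res = stats.linregress(x, y)
    return InteractionEstimate(
        metric=metric,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=int(n),
        pearson_r=float(res.rvalue),
        defined=True,
        scale=scale,
    )


def top_down_effect(tt: pd.DataFrame, scale: int | None = None) -> InteractionEstimate:
    """R_TD: OLS slope of prey log-decrease on mean predator abundance."""
    return _regress(tt["x_td"].to_numpy(float), tt["y_td"].to_numpy(float), "R_TD", scale)


def bottom_up_effect(tt: pd.DataFrame, scale: int | None = None) -> InteractionEstimate:
    """R_BU: OLS slope of predator log-increase on mean prey abundance."""
    return _regress(tt["x_bu"].to_numpy(float), tt["y_bu"].to_numpy(float), "R_BU", scale)


def interaction_estimates(
    ts: pd.DataFrame,
    layout: SpatialLayout,
    scales=None,
    include_top_scale: bool = False,
) -> pd.DataFrame:
    """R_TD and R_BU at each requested scale, as a tidy table.

    By default all layout scales except the largest are analysed: at the full
    system size the bootstrap null is constrained to be nearly identical to
    the data, so the comparison is uninformative.
    """
    if scales is None:
        scales = layout.scales if include_top_scale else layout.scales[:-1]
    rows = []
    for scale in scales:
        tt = build_transitions(aggregate_to_scale(ts, layout, scale))
        for est in (top_down_effect(tt, scale), bottom_up_effect(tt, scale)):
            rows.append(
                {
                    "scale": scale,
                    "metric": est.metric,
                    "slope": est.slope,
                    "intercept": est.intercept,
                    "n_points": est.n_points,
                    "pearson_r": est.pearson_r,
                    "defined": est.defined,
                }
            )
    return pd.DataFrame(rows)


def _species_column(species: str) -> str:
    try:
        return SPECIES_COLUMNS[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; expected one of {sorted(SPECIES_COLUMNS)}"
        ) from None


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, se


def occupancy(ts: pd.DataFrame, species: str) -> SummaryStat:
    """Fraction of patches occupied per sampling date; mean and SE over dates."""
    col = _species_column(species)
    if ts.empty:
        raise ValueError("empty time series")
    frac = (
        ts.assign(present=ts[col] > 0)
        .groupby(["run_id", "time"], sort=True)["present"]
        .mean()
        .to_numpy()
    )
    mean, se = _mean_se(frac)
    return SummaryStat(mean=mean, se=se, values=frac)


def colonization_rate(ts: pd.DataFrame, species: str) -> SummaryStat:
    """Per-interval colonizations over initially empty patches.

    Intervals that start with no empty patch are skipped; if every interval
    is skipped the statistic is undefined (``defined=False``).
    """
    col = _species_column(species)
    _, batches = grid_from_frame(ts)
    rates = []
    for b in batches:
        counts = b.H if col == "H" else b.P
        if counts.shape[1] < 2:
            continue
        empty = counts[:, :-1] == 0  # (B, T-1, N)
        colonized = empty & (counts[:, 1:] > 0)
        n_empty = empty.sum(axis=2).ravel()
        n_col = colonized.sum(axis=2).ravel()
        ok = n_empty > 0
        rates.extend(n_col[ok] / n_empty[ok])
    if not rates:
        return SummaryStat(mean=np.nan, se=np.nan, values=np.array([]), defined=False)
    mean, se = _mean_se(np.asarray(rates))
    return SummaryStat(mean=mean, se=se, values=np.asarray(rates))


def field_metrics(ts: pd.DataFrame) -> pd.DataFrame:
    """Occupancy and colonization summaries for both species, as a table."""
    rows = []
    for species, name in (("H", "herbivore"), ("P", "predator")):
        occ = occupancy(ts, species)
        colz = colonization_rate(ts, species)
        rows.append(
            FieldMetrics(
                species=name,
                occupancy_mean=occ.mean,
                occupancy_se=occ.se,
                colonization_mean=colz.mean,
                colonization_se=colz.se,
            ).__dict__
        )
    return pd.DataFrame(rows)
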