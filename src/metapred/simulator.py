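"""Exact stochastic simulation of the metacommunity (Gillespie direct method).

Produces long-format per-patch time series (run_id, patch_id, time, H, P) for
single runs and run ensembles.  Runs can be instrumented (per-event tallies by
kind and patch) and can carry schedules of timed interventions -- e.g. holding
a patch at a fixed density, or supplementing predators daily -- executed at
their exact times between stochastic events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _gillespie as core
from .dynamics import SimulationParams, settlement_matrix
from .habitat import SpatialLayout

__all__ = [
    "EVENT_KINDS",
    "Intervention",
    "EventLog",
    "SimulationDiverged",
    "run_gillespie",
    "run_ensemble",
    "estimate_event_rate",
]

EVENT_KINDS = (
    "herbivore_birth",
    "herbivore_crowding_death",
    "herbivore_background_death",
    "predation",
    "predator_birth",
    "predator_background_death",
    "herbivore_emigration",
    "predator_emigration",
)

_INTERVENTION_KINDS = {
    "set_H": core.SCHED_SET_H,
    "set_P": core.SCHED_SET_P,
    "add_H": core.SCHED_ADD_H,
    "add_P": core.SCHED_ADD_P,
}


class SimulationDiverged(RuntimeError):
    """Total population exceeded the configured hard cap (parameter pathology)."""


@dataclass(frozen=True)
class Intervention:
    """A deterministic timed state change.

    kind is one of 'set_H', 'set_P' (clamp a patch to ``value``) or
    'add_H', 'add_P' (add ``value`` individuals).
    """

    time: float
    kind: str
    patch: int
    value: int

    def __post_init__(self) -> None:
        if self.kind not in _INTERVENTION_KINDS:
            raise ValueError(
                f"unknown intervention kind {self.kind!r}; "
                f"expected one of {sorted(_INTERVENTION_KINDS)}"
            )
        if self.time < 0:
            raise ValueError("intervention time must be non-negative")


@dataclass
class EventLog:
    """Per-event diagnostics from an instrumented run."""

    counts: np.ndarray  # (8, N) events by kind and patch
    duration: float  # simulated days
    sink_herbivores: int
    sink_predators: int

    def to_frame(self) -> pd.DataFrame:
        n = self.counts.shape[1]
        return pd.DataFrame(
            {
                "event": np.repeat(EVENT_KINDS, n),
                "patch_id": np.tile(np.arange(n), len(EVENT_KINDS)),
                "count": self.counts.ravel(),
            }
        )


def _build_schedule(params: SimulationParams, interventions):
    entries = []
    for order, iv in enumerate(interventions):
        if iv.time > params.t_end:
            raise ValueError(f"intervention at t={iv.time} exceeds t_end={params.t_end}")
        entries.append((float(iv.time), 0, order, _INTERVENTION_KINDS[iv.kind], iv.patch, iv.value))
    # interventions sort before records at equal times
    for order, t in enumerate(sorted(params.record_times)):
        entries.append((float(t), 1, order, core.SCHED_RECORD, 0, 0))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    times = np.array([e[0] for e in entries], dtype=np.float64)
    kinds = np.array([e[3] for e in entries], dtype=np.int64)
    patches = np.array([e[4] for e in entries], dtype=np.int64)
    values = np.array([e[5] for e in entries], dtype=np.int64)
    return times, kinds, patches, values


def _settle_cum(layout: SpatialLayout, params: SimulationParams) -> np.ndarray:
    if layout.n_patches == 1 and params.w_out == 0:
        if params.d_H_max > 0 or params.d_P_max > 0:
            raise ValueError(
                "single closed patch has no settlement destination; "
                "set d_H_max = d_P_max = 0 or w_out > 0"
            )
        return np.ones((1, 2))
    cum = np.cumsum(settlement_matrix(layout, params), axis=1)
    if params.w_out == 0:
        cum[:, -2] = 1.0  # sink never drawn in a closed system
    cum[:, -1] = 1.0
    return cum


def _seed_pair(seed):
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, core_ss = ss.spawn(2)
    core_seed = int(core_ss.generate_state(1)[0] & 0x7FFFFFFF)
    return np.random.default_rng(init_ss), core_seed


def run_gillespie(
    params: SimulationParams,
    layout: SpatialLayout,
    seed=None,
    init_H: np.ndarray | None = None,
    init_P: np.ndarray | None = None,
    interventions=(),
    instrument: bool = False,
    run_id: int = 0,
):
    """One exact SSA run; returns a long-format time-series DataFrame.

    Initial per-patch counts default to independent uniform integer draws on
    [0, H_init_max] and [0, P_init_max].  With ``instrument=True`` returns
    ``(frame, EventLog)``.
    """
    rng, core_seed = _seed_pair(seed)
    n = layout.n_patches
    h0 = (
        rng.integers(0, params.H_init_max + 1, n)
        if init_H is None
        else np.asarray(init_H, dtype=np.int64).copy()
    )
    p0 = (
        rng.integers(0, params.P_init_max + 1, n)
        if init_P is None
        else np.asarray(init_P, dtype=np.int64).copy()
    )
    if h0.shape != (n,) or p0.shape != (n,):
        raise ValueError("init_H/init_P must have one entry per patch")
    if np.any(h0 < 0) or np.any(p0 < 0):
        raise ValueError("initial counts must be non-negative")

    times, kinds, patches, values = _build_schedule(params, interventions)
    status, out_h, out_p, counts, sink_h, sink_p, t_final = core.simulate_core(
        h0.astype(np.int64), p0.astype(np.int64), _settle_cum(layout, params),
        times, kinds, patches, values,
        len(params.record_times),
        params.g_H, params.k_H, params.e_P, params.H_0, params.a_P,
        params.m_H, params.m_P,
        params.d_H_max, params.tau_H, params.s_H,
        params.d_P_max, params.tau_P, params.s_P,
        1 if params.predator_demography else 0,
        params.pop_cap, core_seed,
    )
    if status == core.STATUS_POP_CAP:
        raise SimulationDiverged(
            f"total population exceeded pop_cap={params.pop_cap} at t={t_final:.2f}; "
            "check parameter values"
        )

    rec_times = np.array(sorted(params.record_times))
    n_rec = rec_times.size
    frame = pd.DataFrame(
        {
            "run_id": np.full(n_rec * n, run_id, dtype=np.int64),
            "patch_id": np.tile(np.arange(n), n_rec),
            "time": np.repeat(rec_times, n),
            "H": out_h.ravel(),
            "P": out_p.ravel(),
        }
    )
    if instrument:
        return frame, EventLog(
            counts=counts, duration=t_final, sink_herbivores=sink_h, sink_predators=sink_p
        )
    return frame


def run_ensemble(
    params: SimulationParams,
    layout: SpatialLayout,
    n_runs: int | None = None,
    seed=None,
) -> pd.DataFrame:
    """Independent runs with random initial values, pooled and run-tagged.

    Per-run RNG substreams are derived deterministically from ``seed``, so the
    same seed reproduces the ensemble exactly.
    """
    n_runs = params.n_runs if n_runs is None else int(n_runs)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    frames = [
        run_gillespie(params, layout, seed=child, run_id=r)
        for r, child in enumerate(ss.spawn(n_runs))
    ]
    return pd.concat(frames, ignore_index=True)


def estimate_event_rate(log: EventLog, kind: str, patch: int | None = None) -> float:
    """Empirical events per day for one event kind from an instrumented run."""
    if log is None:
        raise ValueError("event log absent: run with instrument=True")
    try:
        idx = EVENT_KINDS.index(kind)
    except ValueError:
        raise ValueError(f"unknown event kind {kind!r}; expected one of {EVENT_KINDS}") from None
    if log.duration <= 0:
        raise ValueError("instrumented run has zero duration")
    total = log.counts[idx].sum() if patch is None else log.counts[idx, patch]
    return float(total) / log.duration
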