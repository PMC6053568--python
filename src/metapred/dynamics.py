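"""Per-patch event rates: local demography and density-dependent dispersal.

The local model is a discrete-state analogue of the classical
logistic-prey / type-II-predator difference equations,

    H_{t+1} = H_t + g_H H_t (k_H - H_t)/k_H - e_P H_t P_t/(H_t + H_0) - m_H H_t
    P_{t+1} = P_t + a_P e_P H_t P_t/(H_t + H_0) - m_P P_t

translated into non-negative Poisson event rates.  The logistic term is split
into a birth process (g_H * H) and a crowding-death process (g_H * H^2 / k_H)
so every rate stays non-negative even when H exceeds k_H.

Dispersal is informed emigration with indiscriminate settlement: aphids leave
crowded patches (emigration rises logistically once local density exceeds a
threshold), ladybeetles leave prey-poor patches (emigration falls with local
prey density -- a surrogate for area-restricted search), and emigrants of both
species settle on destination patches with probability decaying exponentially
with distance (a Hanski-style incidence kernel), regardless of what lives
there.  An optional external sink absorbs emigrants leaving the system.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .habitat import SpatialLayout

__all__ = [
    "SCENARIO_NO_PREDATOR_DEMOGRAPHY",
    "SCENARIO_WITH_PREDATOR_DEMOGRAPHY",
    "SimulationParams",
    "PatchEventRates",
    "functional_response",
    "local_event_rates",
    "herbivore_emigration_rate",
    "predator_emigration_rate",
    "settlement_distribution",
    "settlement_matrix",
    "expected_local_change",
]

SCENARIO_NO_PREDATOR_DEMOGRAPHY = "no_predator_demography"
SCENARIO_WITH_PREDATOR_DEMOGRAPHY = "with_predator_demography"
_SCENARIO_ALIASES = {
    "i": SCENARIO_NO_PREDATOR_DEMOGRAPHY,
    "ii": SCENARIO_WITH_PREDATOR_DEMOGRAPHY,
    SCENARIO_NO_PREDATOR_DEMOGRAPHY: SCENARIO_NO_PREDATOR_DEMOGRAPHY,
    SCENARIO_WITH_PREDATOR_DEMOGRAPHY: SCENARIO_WITH_PREDATOR_DEMOGRAPHY,
}


@dataclass
class SimulationParams:
    """All demographic, dispersal and run-schedule parameters.

    Rates are per day, abundances in individuals, distances in metres.

    Demography (per patch):

    g_H
        Herbivore intrinsic growth rate.
    k_H
        Herbivore carrying capacity.
    e_P
        Maximum per-predator predation rate (prey per predator per day).
    H_0
        Half-saturation prey density of the type-II functional response.
    a_P
        Predator assimilation rate (predator births per prey consumed);
        active only in scenario ``with_predator_demography``.
    m_H, m_P
        Background per-capita mortality rates (spatially and temporally
        constant).

    Dispersal:

    d_H_max, tau_H, s_H
        Herbivore per-capita emigration: logistic in local H with maximum
        d_H_max, midpoint tau_H (individuals) and steepness s_H.
    d_P_max, tau_P, s_P
        Predator per-capita emigration: reversed logistic in local H
        (predators linger where prey are abundant).
    alpha
        Settlement-kernel decay (per metre): weight exp(-alpha * distance).
    w_out
        External-sink weight; 0 closes the system, > 0 lets emigrants leave
        (the open-system variant).

    Schedule: ``t_end`` days per run, states recorded at ``record_times``,
    ``n_runs`` independent runs with uniform random initial counts on
    [0, H_init_max] and [0, P_init_max] per patch.  ``pop_cap`` aborts runs
    whose total population diverges.
    """

    g_H: float = 0.6
    k_H: float = 60.0
    e_P: float = 20.0
    H_0: float = 15.0
    a_P: float = 0.02
    m_H: float = 0.05
    m_P: float = 0.1
    d_H_max: float = 0.3
    tau_H: float = 30.0
    s_H: float = 0.3
    d_P_max: float = 3.0
    tau_P: float = 15.0
    s_P: float = 0.5
    alpha: float = 1.0
    w_out: float = 0.0
    scenario: str = SCENARIO_NO_PREDATOR_DEMOGRAPHY
    t_end: float = 100.0
    record_times: tuple[float, ...] = tuple(float(t) for t in range(91, 101))
    n_runs: int = 300
    H_init_max: int = 20
    P_init_max: int = 1
    pop_cap: int = 1_000_000

    def __post_init__(self) -> None:
        try:
            self.scenario = _SCENARIO_ALIASES[str(self.scenario)]
        except KeyError:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected "
                f"{SCENARIO_NO_PREDATOR_DEMOGRAPHY!r} (i) or "
                f"{SCENARIO_WITH_PREDATOR_DEMOGRAPHY!r} (ii)"
            ) from None
        for name in (
            "g_H", "k_H", "e_P", "H_0", "a_P", "m_H", "m_P",
            "d_H_max", "tau_H", "d_P_max", "tau_P", "alpha", "w_out",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_H <= 0 or self.H_0 <= 0:
            raise ValueError("k_H and H_0 must be positive")
        if not self.record_times:
            raise ValueError("record_times must not be empty")
        rt = tuple(float(t) for t in self.record_times)
        if any(t < 0 or t > self.t_end for t in rt):
            raise ValueError("record_times must lie within [0, t_end]")
        self.record_times = rt

    @property
    def predator_demography(self) -> bool:
        return self.scenario == SCENARIO_WITH_PREDATOR_DEMOGRAPHY

    def with_(self, **kwargs) -> "SimulationParams":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PatchEventRates:
    """Event rates (events per day) for one patch at a given state."""

    herbivore_birth: float
    herbivore_crowding_death: float
    herbivore_background_death: float
    predation: float
    predator_birth: float
    predator_background_death: float
    herbivore_emigration: float
    predator_emigration: float

    def total(self) -> float:
        return (
            self.herbivore_birth
            + self.herbivore_crowding_death
            + self.herbivore_background_death
            + self.predation
            + self.predator_birth
            + self.predator_background_death
            + self.herbivore_emigration
            + self.predator_emigration
        )


def _check_nonneg(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    return x


def functional_response(H, params: SimulationParams):
    """Type-II per-predator consumption rate e_P * H / (H + H_0).

    Monotone increasing in prey density H and saturating at e_P.
    """
    H = _check_nonneg(H, "H")
    out = params.e_P * H / (H + params.H_0)
    return float(out) if out.ndim == 0 else out


def herbivore_emigration_rate(H, params: SimulationParams):
    """Per-capita herbivore emigration d_H_max / (1 + exp(-s_H (H - tau_H))).

    Crowding-triggered: rises logistically around the threshold tau_H.
    """
    H = _check_nonneg(H, "H")
    with np.errstate(over="ignore"):  # exp overflow saturates the logistic at 0
        out = params.d_H_max / (1.0 + np.exp(-params.s_H * (H - params.tau_H)))
    return float(out) if out.ndim == 0 else out


def predator_emigration_rate(H, params: SimulationParams):
    """Per-capita predator emigration d_P_max / (1 + exp(+s_P (H - tau_P))).

    Non-increasing in local prey density: predators stay put where prey are
    abundant (the area-restricted-search surrogate).
    """
    H = _check_nonneg(H, "H")
    with np.errstate(over="ignore"):  # exp overflow saturates the logistic at 0
        out = params.d_P_max / (1.0 + np.exp(params.s_P * (H - params.tau_P)))
    return float(out) if out.ndim == 0 else out


def local_event_rates(H: float, P: float, params: SimulationParams) -> PatchEventRates:
    """Demographic and emigration event rates for one patch with state (H, P)."""
    h = float(_check_nonneg(H, "H"))
    p = float(_check_nonneg(P, "P"))
    fr = params.e_P * h / (h + params.H_0) if h > 0 else 0.0
    demog = params.predator_demography
    return PatchEventRates(
        herbivore_birth=params.g_H * h,
        herbivore_crowding_death=params.g_H * h * h / params.k_H,
        herbivore_background_death=params.m_H * h,
        predation=fr * p,
        predator_birth=params.a_P * fr * p if demog else 0.0,
        predator_background_death=params.m_P * p if demog else 0.0,
        herbivore_emigration=h * herbivore_emigration_rate(h, params),
        predator_emigration=p * predator_emigration_rate(h, params),
    )


def settlement_distribution(
    layout: SpatialLayout, source: int, params: SimulationParams
) -> np.ndarray:
    """Settlement probabilities for an emigrant from ``source``.

    Returns a vector of length N + 1: entries 0..N-1 are destination patches
    (weight exp(-alpha * distance), zero for the source itself), entry N is
    the external sink (weight w_out).  Settlement is indiscriminate: it does
    not depend on the dispersing species or on destination occupancy.
    """
    source = int(source)
    if not 0 <= source < layout.n_patches:
        raise ValueError(f"invalid source patch {source}")
    w = np.exp(-params.alpha * layout.dist[source])
    w[source] = 0.0
    w = np.append(w, params.w_out)
    total = w.sum()
    if total <= 0:
        raise ValueError("all settlement weights are zero (single closed patch?)")
    return w / total


def settlement_matrix(layout: SpatialLayout, params: SimulationParams) -> np.ndarray:
    """Row-stochastic settlement matrix, shape (N, N + 1); last column = sink."""
    n = layout.n_patches
    w = np.exp(-params.alpha * layout.dist)
    np.fill_diagonal(w, 0.0)
    w = np.concatenate([w, np.full((n, 1), params.w_out)], axis=1)
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("all settlement weights are zero for some patch")
    return w / totals[:, None]


def expected_local_change(H: float, P: float, params: SimulationParams):
    """Expected one-day change (dH, dP) from demographic events alone.

    Summing rate contributions (x +/-1 per event x 1 day) recovers the
    difference equations of the deterministic skeleton exactly; emigration is
    excluded (dispersal off).
    """
    r = local_event_rates(H, P, params)
    d_h = (
        r.herbivore_birth
        - r.herbivore_crowding_death
        - r.herbivore_background_death
        - r.predation
    )
    d_p = r.predator_birth - r.predator_background_death
    return d_h, d_p
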