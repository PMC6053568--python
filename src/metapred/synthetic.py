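"""Synthetic datasets with known, prescribed statistical structure.

These generators are deliberately *not* the mechanistic simulator: they plant
known regression-scale effects directly on the scales the analysis measures,
so every stage of the analysis chain (aggregation, transition building, OLS,
bootstrap null) has an exactly known target.  Three regimes are provided:

* experiment-like -- 81 patches observed daily for 34 days in 4 rounds, with
  predator restocking at round starts, daily predator supplementation at the
  array centre, a declining predator trend within rounds, and log-ratio
  responses that contain prescribed coefficients b_TD and b_BU;
* field-like -- 38 patches sampled every 3 days for 59 days (20 dates), with
  per-species presence/absence Markov chains so that occupancy and
  colonization probabilities are configurable (herbivores occupying and
  colonizing more than predators, as observed);
* exchangeable null -- patch series i.i.d. across patches from a common
  time-varying distribution with no cross-species coupling: the regime in
  which the patch-resampling bootstrap null is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "generate_experiment_like",
    "generate_field_like",
    "generate_exchangeable_null",
    "round_lengths",
]


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic generators.

    Experiment-like block: ``n_patches`` (a power of 3), ``n_rounds`` rounds
    jointly covering ``n_days`` daily samples; ``b_TD`` is the prescribed
    coefficient of mean predator abundance in the prey log-ratio response
    (negative values reproduce the sign convention under which predator
    suppression is reported as a negative slope), ``b_BU`` the prescribed
    coefficient of prey abundance in the predator log-ratio; multiplicative
    lognormal process noise has log-scale SD ``noise_sd``.  Predators decline
    by the factor ``predator_trend`` per day within a round and are restocked
    at round starts (``restock_count`` patches with one predator each, chosen
    at random); ``daily_center_additions`` predators are added to the central
    patches every day.

    Field-like block: per-species initial presence probability, per-interval
    colonization and extinction probabilities, and mean abundance when
    present.
    """

    # experiment-like
    n_patches: int = 81
    n_rounds: int = 4
    n_days: int = 34
    b_TD: float = -0.4
    b_BU: float = 0.005
    baseline_decline_H: float = 0.05
    predator_trend: float = 0.85
    noise_sd: float = 0.3
    gamma_H: float = 0.4  # Gompertz mean reversion of log prey abundance
    K_syn: float = 25.0  # prey abundance the reversion pulls towards
    gamma_P: float = 0.3  # reversion of log predator abundance towards 0
    coupling_cap_P: float = 2.5  # predator abundance saturating the b_TD term
    coupling_cap_H: float = 100.0  # prey abundance saturating the b_BU term
    restock_total_threshold: int = 1
    restock_count: int = 9
    daily_center_additions: int = 2
    init_H_mean: float = 15.0
    # field-like
    field_n_patches: int = 38
    field_n_dates: int = 20
    field_interval_days: int = 3
    herbivore_p_init: float = 0.7
    herbivore_p_col: float = 0.35
    herbivore_p_ext: float = 0.15
    herbivore_abundance: float = 20.0
    predator_p_init: float = 0.2
    predator_p_col: float = 0.07
    predator_p_ext: float = 0.5
    predator_abundance: float = 1.5
    # exchangeable null
    null_mean_H: float = 15.0
    null_mean_P: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        n, l = self.n_patches, 0
        while n % 3 == 0:
            n //= 3
            l += 1
        if n != 1:
            raise ValueError("n_patches must be a power of 3 (fractal compatibility)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 1 <= self.n_rounds <= self.n_days:
            raise ValueError("need 1 <= n_rounds <= n_days")
        for p in ("herbivore_p_init", "herbivore_p_col", "herbivore_p_ext",
                  "predator_p_init", "predator_p_col", "predator_p_ext"):
            if not 0 <= getattr(self, p) <= 1:
                raise ValueError(f"{p} must be a probability")


def round_lengths(n_days: int, n_rounds: int) -> list[int]:
    """Near-equal split of the study days over rounds (e.g. 34/4 -> 9,9,8,8)."""
    base, extra = divmod(n_days, n_rounds)
    return [base + (1 if r < extra else 0) for r in range(n_rounds)]


def _rng(cfg: SyntheticConfig, seed) -> np.random.Generator:
    return np.random.default_rng(cfg.seed if seed is None else seed)


def _to_frame(run_ids, times, patch_ids, H, P) -> pd.DataFrame:
    return pd.DataFrame(
        {"run_id": run_ids, "patch_id": patch_ids, "time": times, "H": H, "P": P}
    )


def generate_experiment_like(cfg: SyntheticConfig, seed=None) -> pd.DataFrame:
    """Daily 81-patch series over 4 restocked rounds with planted coefficients.

    Within a round, for each day-to-day step the predator count updates
    multiplicatively on the log(count + 1) scale with the declining trend,
    the planted bottom-up term ``b_BU * min(H_t, coupling_cap_H)``, a
    reversion term ``-gamma_P * log(P_t + 1)`` and lognormal noise, then the
    central supplementation is added; the prey log-decrease is
    ``baseline_decline_H + gamma_H * (log(H_t + 1) - log(K_syn + 1)) +
    b_TD * min(P_bar, coupling_cap_P)`` plus noise, with
    ``P_bar = (P_t + P_{t+1})/2`` -- the same predictor the top-down
    regression uses, so the planted coefficient is recovered directly.  The
    Gompertz reversion terms and the saturation of the coupling inputs keep
    the mutual positive feedback of a planted (b_TD < 0, b_BU > 0) pair from
    running away.  Counts are rounded and floored at zero; the +1 offsets
    used by the analysis keep zeros harmless.  Rounds restart with
    ``restock_count`` randomly chosen patches holding one predator each.
    """
    rng = _rng(cfg, seed)
    n = cfg.n_patches
    center = (max(n // 2 - 1, 0), n // 2)  # the two central patches
    lengths = round_lengths(cfg.n_days, cfg.n_rounds)
    h = rng.poisson(cfg.init_H_mean, n).astype(np.int64)

    rows_run, rows_time, rows_patch, rows_h, rows_p = [], [], [], [], []
    day = 0
    for rnd, length in enumerate(lengths):
        p = np.zeros(n, dtype=np.int64)
        stocked = rng.choice(n, size=min(cfg.restock_count, n), replace=False)
        p[stocked] = 1

        def record(rnd=rnd):
            rows_run.append(np.full(n, rnd))
            rows_time.append(np.full(n, day))
            rows_patch.append(np.arange(n))
            rows_h.append(h.copy())
            rows_p.append(p.copy())

        record()
        for _ in range(length - 1):
            log_p1 = (
                (1.0 - cfg.gamma_P) * np.log(p + 1.0)
                + np.log(cfg.predator_trend)
                + cfg.b_BU * np.minimum(h, cfg.coupling_cap_H)
                + rng.normal(0.0, cfg.noise_sd, n)
            )
            p1 = np.maximum(0, np.rint(np.exp(np.minimum(log_p1, 20.0)) - 1.0)).astype(np.int64)
            # daily supplementation, split between the two central patches
            p1[center[0]] += (cfg.daily_center_additions + 1) // 2
            p1[center[-1] if n > 1 else center[0]] += cfg.daily_center_additions // 2
            p_bar = (p + p1) / 2.0
            log_decrease = (
                cfg.baseline_decline_H
                + cfg.gamma_H * (np.log(h + 1.0) - np.log(cfg.K_syn + 1.0))
                + cfg.b_TD * np.minimum(p_bar, cfg.coupling_cap_P)
                + rng.normal(0.0, cfg.noise_sd, n)
            )
            log_h1 = np.minimum(np.log(h + 1.0) - log_decrease, 20.0)
            h = np.maximum(0, np.rint(np.exp(log_h1) - 1.0)).astype(np.int64)
            p = p1
            day += 1
            record()
        day += 1
    return _to_frame(
        np.concatenate(rows_run),
        np.concatenate(rows_time),
        np.concatenate(rows_patch),
        np.concatenate(rows_h),
        np.concatenate(rows_p),
    )


def generate_field_like(cfg: SyntheticConfig, seed=None) -> pd.DataFrame:
    """Field-survey-like series: 38 patches, 20 dates at 3-day intervals.

    Presence follows an independent two-state Markov chain per patch and
    species (colonization/extinction probabilities per interval); abundance
    when present is 1 + Poisson(mean - 1).
    """
    rng = _rng(cfg, seed)
    n, t = cfg.field_n_patches, cfg.field_n_dates
    times = np.arange(t) * cfg.field_interval_days

    def chain(p_init, p_col, p_ext, abundance):
        present = np.zeros((t, n), dtype=bool)
        present[0] = rng.random(n) < p_init
        for k in range(1, t):
            u = rng.random(n)
            present[k] = np.where(present[k - 1], u >= p_ext, u < p_col)
        counts = np.zeros((t, n), dtype=np.int64)
        mean = max(abundance - 1.0, 0.0)
        counts[present] = 1 + rng.poisson(mean, int(present.sum()))
        return counts

    h = chain(cfg.herbivore_p_init, cfg.herbivore_p_col, cfg.herbivore_p_ext,
              cfg.herbivore_abundance)
    p = chain(cfg.predator_p_init, cfg.predator_p_col, cfg.predator_p_ext,
              cfg.predator_abundance)
    return _to_frame(
        np.zeros(t * n, dtype=np.int64),
        np.repeat(times, n),
        np.tile(np.arange(n), t),
        h.ravel(),
        p.ravel(),
    )


def generate_exchangeable_null(cfg: SyntheticConfig, seed=None) -> pd.DataFrame:
    """Patch series i.i.d. across patches; no cross-species coupling.

    Herbivores are Poisson with a constant mean; predators are Poisson with a
    mean declining by ``predator_trend`` per day (a shared, scale-irrelevant
    trend).  Any within-patch association between the species is zero in
    expectation, so the bootstrap null is exact for these data.
    """
    rng = _rng(cfg, seed)
    n, t = cfg.n_patches, cfg.n_days
    lam_p = cfg.null_mean_P * cfg.predator_trend ** np.arange(t)
    h = rng.poisson(cfg.null_mean_H, (t, n))
    p = rng.poisson(np.repeat(lam_p, n).reshape(t, n))
    return _to_frame(
        np.zeros(t * n, dtype=np.int64),
        np.repeat(np.arange(t), n),
        np.tile(np.arange(n), t),
        h.astype(np.int64).ravel(),
        p.astype(np.int64).ravel(),
    )
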