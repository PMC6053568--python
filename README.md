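# metapred

Stochastic predator–prey metacommunity simulation and scale-dependent
interaction-strength analysis.

## The problem

How strongly a predator and its prey appear to interact depends on the
spatial scale at which you observe them.  A ladybeetle can devastate the
aphid colony on a single plant, yet fail to control aphids across a whole
stand, because aphids multiply on the plants the ladybeetles have not yet
found.  `metapred` is a toolkit for studying exactly this phenomenon in a
two-species herbivore–predator metacommunity: a spatially explicit stochastic
simulator generates patch-level population time series, and a statistical
pipeline measures interaction strength at a hierarchy of nested spatial
scales, testing it against a bootstrap null model that controls for shared
temporal trends.  It is aimed at community ecologists and modellers working
on metacommunity dynamics, biological control and the design of multi-scale
field experiments.

## Model

The habitat is a fractal array of `3^L` patches (triangles nested in
triangles), giving aggregation scales 1, 3, 9, …, `3^L`.  Local dynamics on
patch *i* follow a logistic prey / type-II predator skeleton,

    H_{t+1} = H_t + g_H H_t (k_H − H_t)/k_H − e_P H_t P_t/(H_t + H_0) − m_H H_t
    P_{t+1} = P_t + a_P e_P H_t P_t/(H_t + H_0) − m_P P_t

translated into Poisson event rates and simulated exactly with Gillespie's
algorithm (the logistic term is split into birth and crowding-death processes
so all rates stay non-negative).  Two scenarios: (i) no predator demography —
the predator population only redistributes, the within-season regime — and
(ii) full predator demography.  Dispersal is informed emigration with
indiscriminate settlement: herbivores leave crowded patches, predators leave
prey-poor patches (a surrogate for area-restricted search), and emigrants
settle with probability `∝ exp(−α·distance)` (an incidence-function kernel),
optionally losing individuals to an external sink.

Interaction strength at each scale is estimated from group-summed series as
pooled OLS slopes of log response ratios:

* **R_TD** (top-down): `log(H_t+1) − log(H_{t+1}+1)` regressed on
  `(P_t + P_{t+1})/2` — the per-predator effect on prey;
* **R_BU** (bottom-up): `log(P_{t+1}+1) − log(P_t+1)` regressed on
  `(H_t + H_{t+1})/2`.

Each estimate is compared against a patch-resampling bootstrap null: for
every (patch, time) cell, independently per species, the count is replaced by
that of a random donor patch at the same time.  The null preserves
time-specific cross-patch structure (trends, synchrony) while destroying
within-patch association, so `|observed − null median|` isolates the genuine
scale-dependent interaction.

## Worked example

`examples/scale_dependence.py` runs a 50-run scenario-(i) ensemble on the
81-patch array and prints:

```
metric scale   observed   null med    |dev|        p
R_BU       1    +0.0016    -0.0000   0.0016   0.0010
R_BU       3    +0.0004    -0.0000   0.0004   0.0010
R_BU       9    +0.0000    -0.0000   0.0000   0.1788
R_BU      27    +0.0000    -0.0000   0.0000   0.8302
R_TD       1    +0.1201    -0.0005   0.1207   0.0010
R_TD       3    +0.0445    -0.0004   0.0449   0.0010
R_TD       9    +0.0153    -0.0007   0.0161   0.0030
R_TD      27    -0.0000    -0.0003   0.0003   0.8821
```

Read `|dev|`, the deviation of the observed slope from the bootstrap null
median: both the top-down and the bottom-up interaction weaken monotonically
as the observation scale grows from 1 to 27 patches, and are statistically
significant (p at the bootstrap floor of ~0.001) only at the smallest scales.
Locally the predator suppresses the prey and tracks it; at larger scales both
signals dissolve, because the predator cannot colonize patches fast enough
and its total abundance barely responds to region-level prey abundance.

The other examples show habitat construction, ensemble simulation with exact
predator conservation, occupancy/colonization metrics for field-survey-like
data, and recovery of a planted interaction coefficient from synthetic data.

A thin CLI wraps the same library calls:

```
metapred simulate --scenario i --seed 7 --runs 50 --out sim.csv
metapred analyze  --input sim.csv --scales 1,3,9,27 --out estimates.csv
metapred null     --input sim.csv --n-iter 10000 --seed 1 --out null.csv
metapred fieldstats --input field.csv
metapred synth    --kind experiment --seed 3 --out synthetic.csv
```

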