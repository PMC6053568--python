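# Methods

## Model structure and assumptions

`metapred` simulates a two-species metacommunity — a fast-reproducing,
weakly mobile herbivore ("aphids") and a mobile predator ("ladybeetles") —
on a fractal array of host-plant patches.  The model is a continuous-time
Markov jump process; state is the integer pair (H, P) per patch.

**Habitat.**  `build_fractal_layout(levels, spacings)` places `3^L` patches
by recursive equilateral-triangle construction: each level-ℓ cluster is three
level-(ℓ−1) clusters at triangle vertices with centroid-to-centroid distance
`spacings[ℓ−1]`.  Patch indices follow the hierarchy path, so the level-ℓ
group of patch *i* is `i // 3^ℓ` and groups at successive scales are nested.
The default spacings (0.5, 1.5, 4.5, 13.5 m) are placeholders increasing
threefold per level — plausible for a potted-plant array but not measured
values; supply real spacings where they are known.  Geometry is planar; the
layout can be exported/imported as CSV.

**Local demography.**  The deterministic skeleton is logistic prey growth,
a type-II functional response `e_P·H/(H+H_0)` and density-independent
mortality.  Each term becomes a Poisson event: prey birth `g_H·H`, crowding
death `g_H·H²/k_H` (the split keeps rates non-negative even when H > k_H),
background deaths `m_H·H` and `m_P·P`, predation `e_P·H·P/(H+H_0)`, and — in
scenario (ii) only — predator birth `a_P·e_P·H·P/(H+H_0)`.  Predator
reproduction is an independent Poisson process at the assimilation-scaled
predation rate rather than a per-consumption coupling; this matches the
mean-field skeleton exactly (asserted by a test over a parameter grid) and
keeps the event set simple.  Mortalities are spatially and temporally
constant scalars.  Scenario (i) removes predator births and deaths entirely:
predator dynamics are pure movement, the regime relevant to within-season
data with no predator recruitment.

**Dispersal.**  Emigration is informed, settlement indiscriminate.
Per-capita herbivore emigration rises logistically with local crowding,
`d_H_max/(1+exp(−s_H(H−τ_H)))`; predator emigration falls with local prey
density, `d_P_max/(1+exp(+s_P(H−τ_P)))` — predators linger where prey are
abundant, a minimal surrogate for area-restricted search.  An emigrant from
patch *i* settles on patch *j* with probability ∝ `exp(−α·d_ij)` regardless
of species or destination state, or is absorbed by an external sink with
weight `w_out` (0 = closed system; set `w_out > 0` for the open variant in
which predators progressively leave).

**Simulation.**  Exact direct-method SSA, numba-compiled.  Per-patch total
rates are maintained incrementally (only the one or two patches touched by
an event are recomputed; the global total is refreshed periodically to shed
float drift).  Deterministic timed entries — state recording and
interventions such as clamping a patch's density or adding individuals — are
merged into the loop by truncating the exponential waiting time at the next
scheduled time, the standard treatment for time-inhomogeneous schedules;
interventions sort before recordings at equal times.  A hard total-population
cap (default 10⁶) aborts pathological parameterizations with
`SimulationDiverged` instead of looping forever.  Runs whose populations go
extinct are kept.  Ensembles draw initial counts uniformly on
`[0, H_init_max] × [0, P_init_max]` per patch and use per-run RNG substreams
derived from one seed, so every output is exactly reproducible.

## Default parameters

All rates per day, abundances in individuals, distances in metres.

| parameter | default | meaning |
|---|---|---|
| g_H | 0.6 | prey intrinsic growth |
| k_H | 60 | prey carrying capacity per patch |
| e_P | 20 | max per-predator consumption |
| H_0 | 15 | half-saturation prey density |
| a_P | 0.02 | predator births per prey consumed (scenario ii) |
| m_H, m_P | 0.05, 0.1 | background mortalities |
| d_H_max, τ_H, s_H | 0.3, 30, 0.3 | prey emigration logistic |
| d_P_max, τ_P, s_P | 3.0, 15, 0.5 | predator emigration logistic |
| α | 1.0 | settlement kernel decay |
| w_out | 0 | external sink weight |
| schedule | 100 d, record 91–100, 300 runs | ensemble defaults |

The demographic and dispersal values are the package's own calibration, not
field measurements.  They were chosen to place scenario (i) in the boom-bust
metacommunity regime: a visiting predator depletes a patch to roughly τ_P
within a few days and leaves before prey are extinct (predators emigrate
quickly below τ_P, d_P_max = 3/day), the remnant recovers in under a week
(g_H = 0.6), and settlement is strongly local (α = 1 against 0.5 m
nearest-neighbour spacing), so suppression is intense locally but cannot be
sustained regionally.  Outside this regime the multi-scale signal collapses:
with much stronger predation the prey go globally extinct; with much weaker
predation patches sit at a predator-conditional equilibrium, predators stop
moving, and all interaction signals vanish.  Both failure modes are easy to
reproduce by varying `e_P` and `τ_P`.

## Interaction-strength analysis

Series are summed over nested groups at each scale (`aggregate_to_scale`),
turned into per-group consecutive-time transitions within rounds/runs
(`build_transitions` — transitions never span a round boundary, since
restocking breaks dynamical continuity), and pooled into one OLS regression
per scale and metric.  Natural logs with +1 offsets keep zeros finite; pairs
with all four counts zero are uninformative and are removed.  "R" is read as
the regression slope (a per-capita effect); the Pearson correlation is
exposed alongside for completeness.  Estimates with fewer than 3 points or a
constant predictor are flagged undefined rather than raised.  The largest
(whole-system) scale is excluded from standard reports — there the null is
constrained to nearly reproduce the data — but remains computable via
`include_top_scale`.

Field metrics: occupancy is the per-date fraction of patches with count > 0
(mean ± SE over dates); the colonization rate is, per interval, the number
of newly occupied patches divided by the patches empty at the interval
start, skipping intervals with no empty patch (mean ± SE over intervals).

## Bootstrap null model

For each iteration, every (patch, time) cell receives the value of a donor
patch drawn uniformly with replacement from all patches at the same time,
within the same round/run, independently for the two species ("cell" mode;
a "series" mode drawing one donor per patch for its whole series is provided
for sensitivity analysis).  Resampling happens at patch scale and is then
aggregated, so a single iteration yields mutually consistent nulls across
scales.  Summaries: median, percentile 95% CI (2.5/97.5; BCa was judged
unnecessary for a null-reference band), and a two-tailed mid-p value
`p = 2·min(r, 1−r)` with `r = (#{null ≤ obs} + 0.5)/(B+1)`, floor `1/(B+1)`.
Iterations whose resampled statistic is degenerate are dropped; a
distribution with more than half degenerate iterations, or fewer than 100
valid samples, is flagged invalid.  The default 10,000 iterations match the
standard analysis; tests and the acceptance script use 1,000 for speed, which
widens the attainable p floor but leaves the 95% CI stable.

The null preserves time-specific cross-patch means in expectation (asserted
within 3 SE over 2,000 iterations), so scale-irrelevant structure — a
declining predator trend, synchronized fluctuations — is retained, and
inference is based on the deviation of the observed slope from the null
median rather than from zero.

## Synthetic data

The generators plant known statistical structure so the analysis chain has
exact targets; they are deliberately not the mechanistic simulator.

**Experiment-like** (81 patches × 34 daily samples in 4 rounds of 9/9/8/8
days): predators are restocked at round starts (9 random patches, 1 each),
supplemented daily at the two central patches, and decline multiplicatively
within rounds; prey update on the log(count+1) scale with a planted
coefficient `b_TD` on mean predator abundance — the same predictor the
top-down regression uses, so recovery is direct — and predators carry a
planted `b_BU` on prey abundance.  Restocking follows a fixed 4-round
schedule (the trigger it emulates — a predator total at or below
`restock_total_threshold` — would make the round count seed-dependent).
A planted pair (b_TD < 0, b_BU > 0) is a mutual positive feedback on the
linear abundance scale and diverges if left bare, so the updates include
Gompertz mean reversion (strengths `gamma_H`, `gamma_P`) and saturate the
coupling inputs (`coupling_cap_P`, `coupling_cap_H`).  The reversion acts as
an omitted variable in the top-down regression, attenuating the recovered
slope (defaults recover ≈ −0.06 for a planted −0.4, still decisively outside
the null CI); with reversion and feedback disabled (`gamma_H=0, b_BU=0`) the
planted coefficient is recovered to within ~2%.  The sign convention follows
the reporting convention in which suppression appears as a negative slope.

**Field-like** (38 patches × 20 dates, 3-day interval): per-species
presence/absence Markov chains with configurable initial, colonization and
extinction probabilities; abundance when present is 1 + Poisson.  Defaults
make the herbivore occupy (~0.7 vs ~0.13) and colonize (~0.3 vs ~0.07) far
more than the predator.

**Exchangeable null**: patch series i.i.d. across patches from a common
time-varying distribution (constant-mean Poisson prey; trend-declining
Poisson predators), no cross-species coupling — the regime where the
bootstrap null is exact, used for calibration (CI coverage ≈ 95%, verified
over 200 replicate datasets).

What the generators do not emulate: real aphid colony growth curves,
observation error, weather covariates, immigrant predators from outside the
two focal species, or within-day behaviour.  Passing tests therefore show
the statistical machinery is correct and calibrated under known structure,
not that the mechanistic model fits any particular field system.

## Numerical choices and limitations

* Event selection uses linear scans over patches and the 8 event kinds;
  cumulative settlement rows are sampled by binary search.  Ties and
  float-drift are handled by clamping to the last positive-rate entry and by
  periodic full recomputation of the total rate.
* `record_times` are truncation points of the waiting-time draw; recording
  is non-invasive.
* OLS uses `scipy.stats.linregress` in the public API and an identical
  centred-sums slope in the bootstrap hot loop (verified against each other
  and a closed-form oracle to 1e−10).
* Problem sizes in tests and the acceptance report (100-run ensembles, 1,000
  bootstrap iterations, 200 calibration replicates) are desk-scale choices
  that keep the full suite in a couple of minutes while leaving every
  statistical margin wide (3 SE, ≥ 90% coverage bands).
* Body size does not enter the model; state is individuals, not biomass.
  Optimal foraging, prey-taxis, destination choice by prey density and stage
  structure are deliberately out of scope.
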