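"""Measure how interaction strength changes with spatial scale.

Runs a scenario-(i) ensemble, estimates the top-down (R_TD) and bottom-up
(R_BU) regression slopes at the 1-, 3-, 9- and 27-patch scales, and compares
each against its patch-resampling bootstrap null.  The quantity to read is
|observed - null median|: the part of the slope not explained by shared
temporal structure.  It shrinks as the observation scale grows -- predators
suppress prey and track prey patch-by-patch, not region-by-region.
"""

from metapred import SimulationParams, build_fractal_layout, null_summary, run_ensemble

layout = build_fractal_layout(4)
params = SimulationParams(scenario="i")
ts = run_ensemble(params, layout, n_runs=50, seed=7)

dists = null_summary(ts, layout, scales=(1, 3, 9, 27), n_iter=1000, seed=8)
print(f"{'metric':6s} {'scale':>5s} {'observed':>10s} {'null med':>10s} "
      f"{'|dev|':>8s} {'p':>8s}")
for d in sorted(dists, key=lambda d: (d.metric, d.scale)):
    print(f"{d.metric:6s} {d.scale:5d} {d.observed:+10.4f} {d.median:+10.4f} "
          f"{abs(d.observed - d.median):8.4f} {d.p_value:8.4f}")
# p is a two-tailed bootstrap p-value (floor 1/(n_iter+1) ~ 0.001 here);
# significance at the small scales and its loss at larger ones is the
# scale-dependence signature.
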