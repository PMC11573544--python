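"""Run the base-case cost-effectiveness comparison.

Builds the full model with calibrated survival evidence, the published
unit costs and utilities, and prints discounted life years, QALYs and
costs per arm plus the incremental comparison against the willingness-to-
pay threshold of $38,223/QALY (3x China's 2022 per-capita GDP).
"""

from uccea.pipeline import RunConfig, build_base_case

cfg = RunConfig(run_psa=False, run_owsa=False, run_threshold=False)
model = build_base_case(cfg)

print(f"{'arm':<12s} {'LY':>7s} {'QALY':>7s} {'cost (US$)':>12s}")
for arm, o in model.outcomes.items():
    print(f"{arm:<12s} {o.ly:7.3f} {o.qaly:7.3f} {o.cost:12,.2f}")

r = model.base_result
print(f"\nincremental: {r.delta_ly:+.3f} LY, {r.delta_qaly:+.3f} QALY, "
      f"${r.delta_cost:+,.2f}")
print(f"ICER: ${r.icer_per_qaly:,.2f}/QALY (per LY ${r.icer_per_ly:,.2f})")
print(f"cost-effective at ${r.wtp:,.0f}/QALY: {r.cost_effective}")

# The combination gains QALYs at a cost far above the threshold, so it is
# not cost-effective at Chinese WTP levels.  (The absolute QALY gain here is
# smaller than the published 0.59 because the synthetic survival curves are
# calibrated only to medians and CI widths, not to the real trial's
# sustained hazard separation.)
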