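"""Fit all five parametric families to reconstructed IPD and select by AIC.

Prints the AIC table for one synthetic arm/endpoint, the selected family,
and its extrapolated median - the survival evidence that drives the
transition matrices of the decision model.
"""

import numpy as np

from uccea import (CHECKMATE_901, calibrate_family, emulate_digitized_curve,
                   fit_all, median_survival, reconstruct, select_by_aic)

cal = CHECKMATE_901[("gem_cis", "OS")]
params = calibrate_family(cal)
em = emulate_digitized_curve(cal.family, params, np.arange(0, 36.1, 1.0),
                             n0=300, risk_interval=3.0, seed=5, jitter_sd=0.002)
ipd = reconstruct(em.curve, em.risk)

fits = fit_all(ipd)
print(f"{'family':<12s} {'loglik':>10s} {'AIC':>10s}")
for f in sorted(fits, key=lambda f: f.aic):
    print(f"{f.family:<12s} {f.loglik:10.2f} {f.aic:10.2f}")

best = select_by_aic(fits)
print(f"\nselected: {best.family}, extrapolated median "
      f"{median_survival(best):.1f} months (generator: {cal.family}, "
      f"median {cal.median_months})")

# The generating family usually wins the AIC comparison; when a neighbour
# family wins (they can be nearly indistinguishable over 36 months of
# follow-up), its within-trial fit is equivalent and only the extrapolated
# tail differs - exactly the uncertainty the published analysis flags.
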