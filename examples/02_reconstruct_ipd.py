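"""Emulate a digitized KM plot and reconstruct pseudo-IPD from it.

A digitizer produces (time, survival) read points plus the numbers-at-risk
table printed under the figure.  The reconstruction solves, interval by
interval, for event and censoring counts consistent with both, yielding a
patient-level dataset whose KM estimate reproduces the published curve.
"""

import numpy as np

from uccea import calibrate_family, CHECKMATE_901, emulate_digitized_curve, reconstruct
from uccea.reconstruct import km_estimate, km_median

cal = CHECKMATE_901[("nivo_combo", "OS")]
params = calibrate_family(cal)
em = emulate_digitized_curve(cal.family, params, read_times=np.arange(0, 36.1, 1.0),
                             n0=300, risk_interval=3.0, seed=11, jitter_sd=0.0)

ipd = reconstruct(em.curve, em.risk)
s_rec = km_estimate(ipd, em.curve.times)
err = np.abs(s_rec - em.curve.survival)

print(f"records reconstructed : {len(ipd)} (= n at risk at t=0)")
print(f"events / censorings   : {ipd.n_events} / {len(ipd) - ipd.n_events}")
print(f"KM median, source IPD : {km_median(em.ipd):.2f} months")
print(f"KM median, pseudo-IPD : {km_median(ipd):.2f} months")
print(f"max |S_rec - S_read|  : {err.max():.4f}  (jitter-free input)")

# The worst absolute survival discrepancy at any read point is well below
# 0.02 - the information lost by digitization is only integer rounding.
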