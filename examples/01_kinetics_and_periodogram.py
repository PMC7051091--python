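"""Deterministic kinetics: the undulating mean trace and its periodogram.

Evaluates the cold-release mean kinetics M(t) at the ten fixation time
points (15..150 min), then runs the fluctuation statistics on the noiseless
trace: coefficient of variation, Fourier-amplitude periodogram, dominant
period with its sampling-interval uncertainty band, and the 15->30 min
fold change.
"""

import numpy as np

import nucleoflux as nf
from nucleoflux.stats import TimeCourse

cfg = nf.hela_config()
tps = np.asarray(cfg.timepoints)
trace = nf.noiseless_trace(cfg)

print("t (min):   ", "  ".join(f"{t:6.0f}" for t in tps))
print("B*M(t):    ", "  ".join(f"{v:6.1f}" for v in trace))

tc = TimeCourse(tps, trace, np.zeros(len(tps)), np.full(len(tps), 50))
pg = nf.periodogram(tc)
period = nf.dominant_period(pg)
low, high = nf.period_interval(period, tc.interval)

print(f"CV of the trace:        {nf.coefficient_of_variation(tc):.3f}")
print(f"dominant period:        {period:.0f} min")
print(f"uncertainty band:       {low:.0f}-{high:.0f} min (sampling interval {tc.interval:.0f} min)")
print(f"fold change 15->30 min: {nf.fold_change(tc, 15, 30):.2f}")
print()
print("The trace peaks at 30, 90 and 150 min and damps after two cycles.")
print("The recovered period sits within 5 min of the 60-min undulation (the")
print("recovery ramp skews the short-trace spectrum slightly low), and the")
print("+-15 min band is the resolution limit of the fixation interval.")
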