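"""Branching-process (BP) inversion with 50% confidence bands.

No labeling at all: the method inverts the counts of progenitors and
differentiated cells over time windows,

    pp - dd = (dP + Phi) / (dP + dD + Phi),   T = gamma * I / (dP + dD + Phi),

with I the progenitor exposure (integral of P) and Phi the integrated
death mass. Here we simulate a population whose mode of division drifts
from strongly self-renewing (ppdd = 0.4) down to homeostatic (ppdd = 0),
pool three replicate dishes, and recover the drift.
"""

import numpy as np
import pandas as pd

import cyclefate as cf

sched = cf.ScheduleSet(ppdd=cf.piecewise_linear([(0.0, 0.4), (48.0, 0.0)]))
frames = []
for seed in (10, 11, 12):
    cfg = cf.SimConfig(initial_count=500, t_end=48.0, seed=seed, schedules=sched)
    frames.append(cf.run(cfg).frame)
t = frames[0]["time_h"].to_numpy()
P = np.mean([f["P"] for f in frames], axis=0)
D = np.mean([f["D"] for f in frames], axis=0)
P_se = np.std([f["P"] for f in frames], axis=0, ddof=1) / np.sqrt(3)
D_se = np.std([f["D"] for f in frames], axis=0, ddof=1) / np.sqrt(3)

counts = cf.CountsTimeSeries(pd.DataFrame({"time_h": t, "P": P, "D": D}))
est = cf.bp_estimate(counts, gamma=1.0, apoptosis_rate=0.0, grid=np.linspace(0, 48, 9))
print(est.to_frame().round(2).to_string(index=False))

banded = cf.propagate_ci50(t, P, P_se, D, D_se, grid=np.linspace(0, 48, 9))
print("\nwith 50% confidence bands (sigmoid-fit route):")
print(banded.to_frame().round(2).to_string(index=False))
print("\nppdd falls along the programmed +0.4 -> 0.0 ramp while T stays near 20 h")
print("(slightly above in the fastest-growing windows, an age-structure effect).")
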