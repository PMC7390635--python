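"""Counterfactual factor decomposition of population expansion.

Which change matters most for expanding the cycling-progenitor pool —
a shorter cycle, a larger growth fraction, or more self-renewing
divisions? Starting from a baseline culture we substitute each factor
(alone or combined) from a stimulated condition and measure the % change
in cycling progenitors after 22 h.
"""

import cyclefate as cf

baseline = cf.ScheduleSet(
    T_mean=cf.constant(24.0), gamma=cf.constant(0.6), ppdd=cf.constant(0.1)
)
stimulated = cf.ScheduleSet(
    T_mean=cf.constant(14.0), gamma=cf.constant(0.9), ppdd=cf.constant(0.4)
)

table = cf.factor_decomposition(
    baseline, stimulated, horizon=22.0,
    factors=[("T",), ("gamma",), ("ppdd",), ("T", "ppdd"), ("T", "gamma", "ppdd")],
    n_sims=15, m=400, seed=0,
)
print(table.round(2).to_string(index=False))
print(
    "\npct_change: increase in cycling progenitors at 22 h relative to the\n"
    "all-baseline culture when the listed factors take their stimulated values."
)
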