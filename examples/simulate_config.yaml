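# Example configuration for `cyclefate simulate`:
# a culture whose self-renewal decays linearly while ~10% of progenitors
# rest in quiescence.
initial_count: 500
t_end: 48.0
seed: 1
schedules:
  T_mean: 20.0            # hours; constants or {breakpoints: [[t, v], ...]}
  ppdd:
    breakpoints: [[0.0, 0.4], [48.0, 0.0]]
  gamma: 0.9
  apoptosis_rate: 0.002   # per progenitor per hour
  cv: 0.3
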