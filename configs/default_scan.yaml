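# Default F26BP clamp scan: half-glycolytic / half-respiratory capacity,
# ATP demand at 20% of combined capacity, 25 logarithmic clamp levels
# spanning 1e-8..1e-4 M. Identical to the built-in defaults of
# `glycoreg simulate`.
total_capacity: 1.0e-3   # M/s
resp_fraction: 0.5
demand_fraction: 0.2
f26bp_lo: 1.0e-8         # M
f26bp_hi: 1.0e-4         # M
n_points: 25
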