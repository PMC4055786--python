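# Oral one-compartment PK: 100 mg daily for 3 doses, first-order absorption
# (ka = 0.1/h) and elimination (ke = 0.2/h).
seed: 1
solver:
  method: rk4
  start_time: -1
  stop_time: 100
  dt: 0.02
model:
  id: one_cpt_oral
  params: {ka: 0.1, ke: 0.2, V: 1.0}
regimens:
  - {amount: 100, first_time: 0, interval: 24, n_doses: 3, target: depot}
sweep:
  parameter: dose
  start: 100
  stop: 200
  steps: 11
  outputs: [conc]
  statistic: max
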