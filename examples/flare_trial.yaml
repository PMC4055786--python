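# Randomized-withdrawal flare trial: 18 patients per arm treated from day 0,
# one arm withdrawn to placebo at day 56, weekly visits with Bernoulli flare
# events driven by a Hill decline in drug concentration.
seed: 1
trial:
  kind: flare
  n_per_arm: 18
  tau: 56
  start_p2: 56
  start_time: -28
  stop_time: 224
  visit_freq: 7
  n_doses_p2: [3, 0]
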