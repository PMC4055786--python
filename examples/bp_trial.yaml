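# Blood-pressure success trial: 100 patients, 150 mg daily for 4 doses,
# success = blood-pressure reduction of at least 20 mmHg at 72 h (trough).
seed: 1
trial:
  kind: bp
  dose: 150
  n_doses: 4
  n_subjects: 100
  eval_time: 72
  pd_threshold: -20
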