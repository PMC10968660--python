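method: hs
iterations: 1000
synth:
  n_instances: 1000
  n_positive: 395
  n_features: 40
  n_informative: 6
  effect: 0.15
  missing_rate: 0.05
  seed: 42
classifiers: [nb, svm]
seeds: [0, 1, 2, 3, 4]
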