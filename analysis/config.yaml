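# Study-scale synthetic cohort: 73 subjects (59 IDH mutant / 14 wild-type),
# acquisition and class rCBV targets at the package defaults.
out_dir: scratch/pipeline
seed: 20260923
log_level: INFO
cohort:
  n_mutant: 59
  n_wildtype: 14
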