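{
  "name": "escherichia_coli",
  "stage": "storage",
  "raw_rate": 2.2e-10,
  "type_distribution": {
    "insertion": 0.05,
    "deletion": 0.05,
    "substitution": 0.9
  },
  "insertion_weights": {
    "A": 0.25,
    "C": 0.25,
    "G": 0.25,
    "T": 0.25
  },
  "deletion_weights": {
    "A": 0.25,
    "C": 0.25,
    "G": 0.25,
    "T": 0.25
  },
  "homopolymer_bias": 0.0,
  "substitution_rules": [],
  "positional_rules": [],
  "source": "Lee et al. (2012) PNAS 109:E2774; Sung et al. (2012) PNAS 109:18488 (editable per-generation rate)"
}
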