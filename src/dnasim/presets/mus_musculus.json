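{
  "name": "mus_musculus",
  "stage": "storage",
  "raw_rate": 5.4e-09,
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
  "source": "Drake et al. (1998) Genetics 148:1667; Sung et al. (2012) PNAS 109:18488 (editable per-generation rate)"
}
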