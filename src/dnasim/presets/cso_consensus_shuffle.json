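{
  "name": "cso_consensus_shuffle",
  "stage": "synthesis",
  "raw_rate": 0.00035,
  "type_distribution": {
    "insertion": 0.2,
    "deletion": 0.55,
    "substitution": 0.25
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
  "homopolymer_bias": 0.3,
  "substitution_rules": [],
  "positional_rules": [],
  "source": "Kosuri & Church (2014) Nat Methods 11:499-507 (editable representative rate)"
}
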