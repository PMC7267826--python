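{
  "name": "pfu",
  "stage": "pcr",
  "raw_rate": 1.6e-06,
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
  "source": "McInerney, Adams & Hadi (2014) Mol Biol Int 2014:287430 (editable representative per-cycle rate)"
}
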