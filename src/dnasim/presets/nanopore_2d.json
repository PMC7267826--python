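{
  "name": "nanopore_2d",
  "stage": "sequencing",
  "raw_rate": 0.07,
  "type_distribution": {
    "insertion": 0.2,
    "deletion": 0.4,
    "substitution": 0.4
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
  "homopolymer_bias": 0.5,
  "substitution_rules": [
    {
      "target": "TAG",
      "replacements": [
        {
          "sequence": "TGG",
          "weight": 1.0
        }
      ]
    },
    {
      "target": "TAC",
      "replacements": [
        {
          "sequence": "TGC",
          "weight": 1.0
        }
      ]
    }
  ],
  "positional_rules": [],
  "source": "Weirather et al. (2017) F1000Research 6:100 (editable representative rate)"
}
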