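{
  "name": "pacbio_subread",
  "stage": "sequencing",
  "raw_rate": 0.13,
  "type_distribution": {
    "insertion": 0.42,
    "deletion": 0.21,
    "substitution": 0.37
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
  "homopolymer_bias": 0.2,
  "substitution_rules": [
    {
      "target": "CG",
      "replacements": [
        {
          "sequence": "CA",
          "weight": 0.5
        },
        {
          "sequence": "TG",
          "weight": 0.5
        }
      ]
    }
  ],
  "positional_rules": [],
  "source": "Weirather et al. (2017) F1000Research 6:100 (editable representative rate)"
}
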