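{
  "name": "illumina_paired_end",
  "stage": "sequencing",
  "raw_rate": 0.0028,
  "type_distribution": {
    "insertion": 0.02,
    "deletion": 0.03,
    "substitution": 0.95
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
      "target": "GGG",
      "replacements": [
        {
          "sequence": "GGT",
          "weight": 1.0
        }
      ]
    }
  ],
  "positional_rules": [
    {
      "position": 35,
      "base": "T",
      "weight": 5.0
    }
  ],
  "source": "Schirmer et al. (2016) BMC Bioinformatics 17:125 (editable representative rate)"
}
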