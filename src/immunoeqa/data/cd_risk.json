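{
  "comment": "Default coeliac-disease HLA-DQ risk map. Ordered rules, first match wins; literature-informed gradient over DQ2.5 (DQA1*05 + DQB1*02) and DQ8 (DQB1*03:02) dose. Editable: schemes may override via panel configuration.",
  "rules": [
    {
      "label": "very_high",
      "requires": [
        {"locus": "HLA-DQB1", "prefix": "HLA-DQB1*02", "min_copies": 2},
        {"locus": "HLA-DQA1", "prefix": "HLA-DQA1*05", "min_copies": 1}
      ]
    },
    {
      "label": "very_high",
      "requires": [
        {"locus": "HLA-DQB1", "prefix": "HLA-DQB1*02", "min_copies": 1},
        {"locus": "HLA-DQA1", "prefix": "HLA-DQA1*05", "min_copies": 1},
        {"locus": "HLA-DQB1", "prefix": "HLA-DQB1*03:02", "min_copies": 1}
      ]
    },
    {
      "label": "high",
      "requires": [
        {"locus": "HLA-DQB1", "prefix": "HLA-DQB1*02", "min_copies": 1},
        {"locus": "HLA-DQA1", "prefix": "HLA-DQA1*05", "min_copies": 1}
      ]
    },
    {
      "label": "high",
      "requires": [
        {"locus": "HLA-DQB1", "prefix": "HLA-DQB1*03:02", "min_copies": 2}
      ]
    },
    {
      "label": "moderate",
      "requires": [
        {"locus": "HLA-DQB1", "prefix": "HLA-DQB1*03:02", "min_copies": 1}
      ]
    },
    {
      "label": "low",
      "requires": [
        {"locus": "HLA-DQB1", "prefix": "HLA-DQB1*02", "min_copies": 1}
      ]
    },
    {
      "label": "low",
      "requires": [
        {"locus": "HLA-DQA1", "prefix": "HLA-DQA1*05", "min_copies": 1}
      ]
    }
  ],
  "default": "very_low"
}
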