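{
  "bw_ratio": {
    "G00000": 0.00012870467361355493,
    "G00001": 0.10772464816244831,
    "G00002": 0.9231138244462523,
    "G00003": 0.04341895105067882,
    "G00004": 0.08527383103542958,
    "G00005": 0.03838656202061306,
    "G00006": 0.9747421853488508,
    "G00007": 0.14963169753533867,
    "G00008": 1.8690942179484098,
    "G00009": 0.07625478917253234,
    "G00010": 0.5976339133331834,
    "G00011": 0.13114372211815145
  },
  "ks_distance": {
    "G00000": 0.2333333333333333,
    "G00001": 0.7,
    "G00002": 0.6,
    "G00003": 0.4666666666666666,
    "G00004": 0.4,
    "G00005": 0.7333333333333334,
    "G00006": 0.25,
    "G00007": 0.5833333333333334,
    "G00008": 0.5666666666666667,
    "G00009": 0.6166666666666666,
    "G00010": 0.4,
    "G00011": 0.4833333333333334
  },
  "top_bw_gene": "G00008",
  "auc_top_bw_gene": 0.0,
  "survival_gene": "G00003",
  "logrank_chisq_survival_gene": 0.12175089789642367,
  "canonical_logrank_example": {
    "times_a": [
      1,
      2
    ],
    "events_a": [
      1,
      1
    ],
    "times_b": [
      3,
      4
    ],
    "events_b": [
      1,
      1
    ],
    "chisq": 2.8823529411764706
  },
  "truth": {
    "informative_genes": {
      "G00006": -1.775487292010956,
      "G00010": -1.384041041948975,
      "G00008": -1.2620466782768833
    },
    "shifted_genes": {
      "G00005": {
        "location_sd": 3.0,
        "scale": 1.0
      },
      "G00001": {
        "location_sd": 3.0,
        "scale": 1.0
      }
    },
    "survival_genes": {
      "G00007": 3.0,
      "G00003": 3.0
    },
    "response_probability": 0.4
  }
}
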