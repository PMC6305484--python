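{
  "cover_category_counts": {
    "exclusive": 16,
    "indifferent": 4,
    "preferring": 5
  },
  "n_species": 25,
  "n_stations": 81,
  "pe_vs_st_profile": "A_dominates",
  "permanova": {
    "cover_within_PE": {
      "R2": 0.841077176,
      "p": 0.0049751244
    },
    "cover_within_ST": {
      "R2": 0.401392841,
      "p": 0.0049751244
    },
    "substrate_overall": {
      "R2": 0.5331171572,
      "p": 0.0049751244
    },
    "substrate_within_B": {
      "R2": 0.7442406593,
      "p": 0.0049751244
    },
    "substrate_within_M": {
      "R2": 0.792868607,
      "p": 0.0049751244
    },
    "substrate_within_S": {
      "R2": 0.897731982,
      "p": 0.0149253731
    },
    "substrate_within_T": {
      "R2": 0.0671000257,
      "p": 0.1393034826
    }
  },
  "species_table_total_N": 14687,
  "stress": 0.0266157013,
  "substrate_category_counts": {
    "euryecious": 4,
    "pioneer": 5,
    "stenoecious": 16
  }
}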