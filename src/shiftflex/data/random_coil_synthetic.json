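{
  "provenance": "synthetic default: approximate IDP-like random-coil shifts and minimal nearest-neighbour corrections assembled for this package; replace with a measured table for production use",
  "shifts": {
    "ALA": {"CA": 52.6, "CB": 19.1, "C": 177.9, "N": 123.8, "H": 8.25, "HA": 4.33},
    "ARG": {"CA": 56.2, "CB": 30.7, "C": 176.5, "N": 121.5, "H": 8.26, "HA": 4.34},
    "ASN": {"CA": 53.3, "CB": 38.9, "C": 175.5, "N": 119.0, "H": 8.39, "HA": 4.73},
    "ASP": {"CA": 54.3, "CB": 41.2, "C": 176.4, "N": 120.5, "H": 8.33, "HA": 4.62},
    "CYS": {"CA": 58.5, "CB": 28.2, "C": 174.8, "N": 119.2, "H": 8.32, "HA": 4.54},
    "GLN": {"CA": 55.9, "CB": 29.5, "C": 176.1, "N": 120.4, "H": 8.31, "HA": 4.34},
    "GLU": {"CA": 56.6, "CB": 30.3, "C": 176.7, "N": 121.2, "H": 8.35, "HA": 4.33},
    "GLY": {"CA": 45.2, "C": 174.2, "N": 109.4, "H": 8.33, "HA": 3.96},
    "HIS": {"CA": 55.6, "CB": 29.6, "C": 174.9, "N": 119.5, "H": 8.40, "HA": 4.70},
    "ILE": {"CA": 61.3, "CB": 38.6, "C": 176.5, "N": 121.6, "H": 8.08, "HA": 4.16},
    "LEU": {"CA": 55.2, "CB": 42.3, "C": 177.5, "N": 122.4, "H": 8.14, "HA": 4.36},
    "LYS": {"CA": 56.3, "CB": 33.0, "C": 176.7, "N": 121.6, "H": 8.29, "HA": 4.32},
    "MET": {"CA": 55.6, "CB": 32.8, "C": 176.5, "N": 120.3, "H": 8.30, "HA": 4.47},
    "PHE": {"CA": 57.9, "CB": 39.8, "C": 175.9, "N": 120.7, "H": 8.17, "HA": 4.61},
    "PRO": {"CA": 63.3, "CB": 32.0, "C": 177.0, "N": 137.0, "HA": 4.41},
    "SER": {"CA": 58.3, "CB": 63.9, "C": 174.7, "N": 116.5, "H": 8.31, "HA": 4.46},
    "THR": {"CA": 61.8, "CB": 69.9, "C": 174.6, "N": 114.3, "H": 8.19, "HA": 4.42},
    "TRP": {"CA": 57.6, "CB": 29.6, "C": 176.2, "N": 121.4, "H": 8.09, "HA": 4.66},
    "TYR": {"CA": 57.8, "CB": 38.9, "C": 175.7, "N": 120.5, "H": 8.08, "HA": 4.56},
    "VAL": {"CA": 62.2, "CB": 32.7, "C": 176.1, "N": 121.0, "H": 8.14, "HA": 4.13}
  },
  "neighbor_corrections": {
    "+1": {
      "PRO": {"CA": -2.0, "C": -0.6, "N": -0.3, "H": -0.05, "HA": 0.1}
    },
    "-1": {
      "GLY": {"N": -0.5, "H": 0.05},
      "PRO": {"N": 0.9, "H": 0.1}
    },
    "+2": {},
    "-2": {}
  }
}
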