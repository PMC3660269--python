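{
  "comment": "Residue constant tables. hydropathy: Kyte-Doolittle (J Mol Biol 157:105, 1982). mass: average residue masses in Da (Expasy protparam constants); water: average mass of H2O added once per chain. pka: Bjellqvist/Expasy-style ionizable-group pKa values used for isoelectric-point estimation. abundance: UniProtKB/Swiss-Prot release-wide amino-acid composition (percent, renormalized at load). propensity: Chou-Fasman helix/sheet/turn conformational parameters used only by the toy secondary-structure stub.",
  "hydropathy": {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
  },
  "mass": {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "Q": 128.1307, "E": 129.1155, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326
  },
  "water_mass": 18.01524,
  "pka": {
    "n_terminus": 7.5,
    "c_terminus": 3.55,
    "positive_side_chains": {"K": 10.0, "R": 12.0, "H": 5.98},
    "negative_side_chains": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
  },
  "abundance_percent": {
    "A": 8.26, "R": 5.53, "N": 4.06, "D": 5.46, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.08, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87
  },
  "ambiguity": {
    "B": ["D", "N"],
    "Z": ["E", "Q"],
    "J": ["I", "L"],
    "X": ["A", "C", "D", "E", "F", "G", "H", "I", "K", "L",
          "M", "N", "P", "Q", "R", "S", "T", "V", "W", "Y"],
    "U": ["C"],
    "O": ["K"]
  },
  "ss_propensity": {
    "helix": {
      "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
      "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
      "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
      "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06
    },
    "sheet": {
      "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
      "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
      "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
      "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70
    },
    "coil": {
      "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19,
      "Q": 0.98, "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47,
      "L": 0.59, "K": 1.01, "M": 0.60, "F": 0.60, "P": 1.52,
      "S": 1.43, "T": 0.96, "W": 0.96, "Y": 1.14, "V": 0.50
    }
  }
}
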