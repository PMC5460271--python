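{
  "comment": "Van der Waals radii (per element, Angstrom) and per-residue-type theoretical maximum SASA (Angstrom^2, Tien et al. 2013 theoretical values) used for relative solvent accessibility.",
  "vdw_radii": {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "SE": 1.9,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "MG": 1.73,
    "CA": 2.0,
    "MN": 2.0,
    "FE": 2.0,
    "ZN": 1.39,
    "NA": 2.27,
    "K": 2.75
  },
  "max_sasa": {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0
  }
}
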