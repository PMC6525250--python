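{
  "comment": "Default SASA parameters: Chothia-style van-der-Waals radii (A) and Tien et al. 2013 theoretical Gly-X-Gly maximal ASA values (A^2) used to normalize relative ASA.",
  "probe_radius": 1.4,
  "sphere_points": 960,
  "radius_set": {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "H": 1.20,
    "D": 1.20
  },
  "max_asa_table": {
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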