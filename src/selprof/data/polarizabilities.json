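{
  "_comment": "Atomic (static dipole) polarizabilities in cubic Angstrom, CRC-style element values used for the additive apol descriptor. Hydrogens included.",
  "H": 0.666793,
  "B": 3.03,
  "C": 1.76,
  "N": 1.10,
  "O": 0.802,
  "F": 0.557,
  "Si": 5.38,
  "P": 3.63,
  "S": 2.90,
  "Cl": 2.18,
  "Br": 3.05,
  "I": 5.35
}
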