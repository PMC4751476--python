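# Ideal backbone covalent geometry (Engh & Huber-style literature values)
# used by the internal-coordinate chain builder.  Lengths angstrom,
# angles degrees.
bonds:
  N_CA: 1.458
  CA_C: 1.525
  C_N: 1.329
  C_O: 1.231
  CA_CB: 1.530
angles:
  N_CA_C: 111.2
  CA_C_N: 116.2
  C_N_CA: 121.7
  CA_C_O: 120.8
  N_CA_CB: 110.5
torsions:
  omega: 180.0          # trans peptide bond
  # improper C-N-CA-CB placing CB with L-amino-acid chirality
  cb_improper: -122.6
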