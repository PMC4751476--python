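# Karplus coefficients for the three-bond HN-Halpha scalar coupling,
#   J(phi) = A cos^2(phi - offset) + B cos(phi - offset) + C   [Hz]
# Empirical parameterization of Vuister & Bax (J. Am. Chem. Soc. 115,
# 7772-7777, 1993), fitted against staphylococcal nuclease couplings.
# The 60 degree phase offset is the standard convention relating the
# H-N-CA-HA torsion to the backbone phi dihedral.
vuister_bax_1993:
  A: 6.51
  B: -1.76
  C: 1.60
  offset_deg: 60.0
default: vuister_bax_1993
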