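# Parameters of the simplified one-or-two-bead-per-residue coarse-grained
# model used for rigid-body self-docking.  One backbone bead sits on the
# CA atom; one side-chain bead sits on the side-chain heavy-atom centroid
# (glycine has no side-chain bead).  Radii approximate the gyration radius
# of the grouped atoms; well depths are uniform and modest so that packing,
# not chemistry, dominates the landscape.  All values are editable data.
#
# Units: radius angstrom, epsilon kcal/mol, charge elementary.
backbone:
  radius: 2.3
  epsilon: 0.30
  charge: 0.0
sidechain:
  # radius per residue type; epsilon uniform; formal charges on the four
  # ionizable side chains (pH 7 states; His neutral)
  epsilon: 0.30
  radius:
    ALA: 1.8
    ARG: 3.2
    ASN: 2.5
    ASP: 2.4
    CYS: 2.2
    GLN: 2.8
    GLU: 2.7
    HIS: 2.8
    ILE: 2.7
    LEU: 2.7
    LYS: 3.0
    MET: 2.9
    PHE: 3.0
    PRO: 2.3
    SER: 2.0
    THR: 2.3
    TRP: 3.3
    TYR: 3.1
    VAL: 2.4
  charge:
    ASP: -1.0
    GLU: -1.0
    LYS: 1.0
    ARG: 1.0
# terminal backbone beads carry the zwitterion charges
terminal_charges:
  nterm: 1.0
  cterm: -1.0
# energy model
coulomb_constant: 332.0636     # kcal*angstrom/(mol*e^2)
dielectric_slope: 4.0          # eps(r) = slope * r  (distance-dependent)
cutoff: 12.0                   # angstrom; pairs beyond contribute zero
softcore_fraction: 0.6         # repulsion linearized below this fraction of sigma
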