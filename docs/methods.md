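# Methods

This document describes the models implemented in `paranuclei`, their
parameters and defaults, the numerical choices behind them, and their
limitations.

## Scientific context

Disordered amyloidogenic peptides such as Aβ42 populate broad
conformational ensembles. A conformational-selection model of early
oligomerisation proceeds in stages: (i) characterise the monomer
ensemble and validate it against NMR observables; (ii) reduce the
ensemble to representative conformers by clustering; (iii) rigidly
self-dock a representative conformer to enumerate dimer interfaces;
(iv) extract the screw (helical) geometry of each interface — repeated
application of any rigid transform generates a helix; (v) keep
interfaces whose helix is nearly flat and nearly cyclic with 5–6
protomers per turn; (vi) close those candidates into exact 5- or 6-fold
rings. `paranuclei` implements each stage with synthetic-data generators
so the whole pipeline is testable without molecular-dynamics input.

## Units

Coordinates are internally in Å throughout (PDB native). Reported
quantities follow field conventions: RMSD, radius of gyration, pitch,
ring metrics and contact cutoffs in nm; couplings in Hz; shifts in ppm;
energies in kcal/mol; angles in degrees.

## Ensemble observables

**Dihedrals.** φ(i) = C(i−1)–N(i)–CA(i)–C(i) and
ψ(i) = N(i)–CA(i)–C(i)–N(i+1), IUPAC sign convention, computed with the
projection ("praxeolitic") formulation; terminal residues missing a
flanking atom are NaN.

**³J(HN-Hα) couplings.** Karplus relation
J(φ) = A cos²(φ−60°) + B cos(φ−60°) + C with the Vuister & Bax
parameters A = 6.51, B = −1.76, C = 1.60 Hz (packaged in
`data/karplus.yaml`). The per-residue coupling is the ensemble mean over
frames with a defined φ. The analytic range of the curve (parabola in
u = cos(φ−60°) over u ∈ [−1, 1], including the interior vertex) bounds
every possible ensemble average and is exposed as
`KarplusParameters.analytic_range()`.

**Secondary chemical shifts.** Δδ = δ_coil − δ by default (the packaged
random-coil CA/CB references follow Wishart's tables,
`data/coil_shifts.tsv`; glycine has no CB). With this sign convention a
*positive* CA Δδ indicates extended/β character. The opposite
convention is available via `convention="obs_minus_coil"`. Agreement
between computed and experimental profiles is summarised by the Pearson
correlation over residues present in both tables (≥3 required).

**Secondary-structure propensities.** Per-frame classes are assigned
from backbone dihedrals by rectangular Ramachandran regions:

| class | region |
|---|---|
| H (helix, incl. 3₁₀/π) | φ ∈ (−100, −30), ψ ∈ (−80, −5) |
| E (extended/bridge) | φ ∈ [−180, −100], ψ ∈ (90, 180] ∪ [−180, −170] |
| T (turn) | φ ∈ (30, 90), ψ ∈ (−20, 80), or φ ∈ (−180, 0), ψ ∈ (−120, 60) outside H |

Everything else is coil. When an external per-frame assignment is
available (e.g. from a secondary-structure assignment program), its
letters can be supplied directly; the 7-class convention is grouped as
H/G/I→H, E/B→E, T→T, else coil. The rectangular regions are an
open-design operationalisation: class boundaries in φ/ψ space have no
universal definition, so the regions and the grouping rule are
documented here and fixed by tests.

**RMSD.** Minimum RMSD over rigid superpositions via the Kabsch/SVD
algorithm with the determinant-sign correction. All-pairs matrices use
the singular-value identity rmsd² = (‖A‖² + ‖B‖² − 2(σ₁+σ₂±σ₃))/n with
batched 3×3 SVDs, so thousand-frame matrices are tractable.

**Free-energy surface.** 2-D histogram over (RMSD to a reference
conformer, Rg), F = −kT ln N with k = 0.0019872 kcal/mol/K, default
T = 300 K, min-shifted to zero; empty bins are NaN.

**Clustering.** The gromos (neighbor-count, Daura) algorithm: count
neighbors within an RMSD cutoff (default 0.2 nm), take the frame with
most neighbors (ties → lowest frame index) as a cluster with its
neighbors, remove them, repeat. Clusters are ordered by decreasing size.

## Coarse-grained docking

**Bead model.** Two beads per residue: a backbone bead on CA and a
side-chain bead on the side-chain heavy-atom centroid (none for
glycine). Bead radii and ε are tabulated per residue type in
`data/cg_params.yaml`. Charges: −1 on Asp/Glu and +1 on Lys/Arg
side-chain beads; +1/−1 on the N-/C-terminal backbone beads. This is a
deliberately simple, fully documented substitute for published
CG docking force fields, sufficient for the geometric questions the
pipeline asks (interface enumeration and ranking), not for affinities.

**Energy.** Pairwise 12-6 Lennard-Jones with σ = sum of bead radii and
ε the geometric mean, continued linearly below 0.6σ so overlap stays
finite; Coulomb 332.0636·q₁q₂/(4r²) kcal/mol (distance-dependent
dielectric ε(r) = 4r, a standard implicit-solvent screening choice);
12 Å pair cutoff.

**Search.** Ligand centers are placed on a Fibonacci sphere of radius
1.2× the receptor's largest dimension (uniform angular coverage without
pole clustering), each with several spins about the radial axis. Because
start poses lie outside the energy cutoff, a deterministic approach step
(`slide_to_contact`) first translates the pose along the center line
until the closest bead pair sits 1 Å outside contact; local L-BFGS-B
minimisation over 3 translations + 3 axis-angle rotation increments
(composed onto the orientation, avoiding Euler singularities) then
relaxes the pose. The returned energy never exceeds the starting energy.
Poses are grouped by single-linkage clustering on ligand-bead RMSD
(receptor frame fixed, 2 Å default cutoff) and ranked by representative
energy. The whole pipeline is deterministic.

## Screw geometry

Any proper rigid motion is a screw: rotation by θ about an axis plus a
rise d along it (Chasles). The decomposition used: θ and the axis
direction from the rotation's axis-angle form; d = t·axis; a point on
the axis p = ½(t⊥ + cot(θ/2)·(axis × t⊥)) with t⊥ the translation
component normal to the axis. Conventions: θ ∈ (0°, 180°] with the axis
carrying the sense (handedness +1 for a right-handed screw); at
θ = 180° the axis sign is chosen so d ≥ 0; |θ| < 0.1° is flagged
degenerate (pure translation, no defined helix). Descriptors:
protomers per turn n = 360/θ, pitch P = n·d (reported in nm).

Repeating the interface transform k−1 times yields protomer k of a
helical N-mer; a steric catastrophe (inter-protomer CA pairs < 1 Å)
logs a warning but returns the assembly for inspection.

**Candidate filter.** A dimer interface is a ring candidate when
n ∈ [5, 6] (inclusive) and P < 2 nm (strict) — operationalising
"nearly cyclic with pentamer/hexamer symmetry" purely by these bounds.
A separate orientation screen asks whether a marker residue (default the
C-terminus) points inward: true iff its CA lies strictly closer to the
screw axis than the protomer's mean CA radial distance.

## Ring assembly

**Cyclization.** The candidate screw is projected onto the cyclic
manifold — rotation exactly 360/N about the screw axis, zero rise — and
the protomer is expressed in the axis frame. A seeded Metropolis search
(default ≤2° rotations about the protomer centroid, ≤0.5 Å in-plane
translations, temperature 0.6 kcal/mol, 300 steps) perturbs the protomer
pose, each trial replicated by exact N-fold symmetry, to lower the
coarse-grained energy of one protomer with the rest of the ring. Closure
is a hard constraint (exact by construction; the closure error of the
composed transform is at machine precision), and the best state seen is
returned, so the final energy never exceeds the projected start's.
N is limited to 3–24.

**Metrics.** The literature quotes ring diameters and heights without
operational definitions, so these are fixed here: outer diameter =
2 × max heavy-atom radial distance from the symmetry axis, height =
heavy-atom extent along the axis, pore diameter = 2 × min radial
distance, all in nm. Published values for comparable assemblies are
comparison points, not targets, since they depend on side chains beyond
CB and on relaxation not modelled here.

**Contacts.** Residue-level inter-protomer contact maps: entry (i, j)
true iff the minimum heavy-atom distance between residue i of one
protomer and j of the other is below 0.45 nm (strict; a common
heavy-atom contact convention — no published value constrains it).

**Stacking.** Ring-on-ring docking reuses the CG engine with ring 1
fixed. Each ranked pose is labelled by which face of each ring points at
the partner: the "N" face is the side of the ring plane enriched in a
named residue range (default residues 1–9, the N-terminal region),
classified by the mean axial offset of that range from the body mean.

## Synthetic generators

**Backbone builder.** NeRF (natural extension reference frame)
sequential placement of N, CA, C, O and CB (except Gly) from ideal bond
lengths/angles (`data/geometry.yaml`; ω fixed at 180°, CB placed by an
improper of −122.6°, validated against a reference residue template).
Measured dihedrals of the output match the inputs to well under 0.5°.

**Mixture ensembles.** Each frame draws a state by weight, jitters that
state's per-residue φ/ψ targets with Gaussian noise, builds the
backbone, and optionally adds Cartesian noise. Fixed seeds give
byte-identical output; frame labels record the generating state, so
recovery tests (cluster sizes vs configured weights, propensities vs
configured dihedral classes) have exact bookkeeping. The generator
emulates the *statistical shape* of a pooled multi-state ensemble —
distinct dihedral basins at known populations — not force-field physics,
solvent, or kinetics.

**Ground-truth dimers.** Protomer 2 is protomer 1 under a caller-chosen
screw; the generating parameters are returned for exact round-trip
assertions. With rotation 69.2308° about z and rise 2.1154 Å the
recovered descriptors are 5.2 protomers per turn and 1.1 nm pitch — a
nearly flat pentameric helix, the geometry that motivates ring closure
at N = 5.

## Numerical choices

- Kabsch superposition uses SVD with the det-sign fix; collinear point
  sets are rejected.
- Rotation handling goes through `scipy.spatial.transform.Rotation`
  (axis-angle composition, no gimbal issues).
- Minimisation: L-BFGS-B, gradient tolerance 1e-9, ≤400 iterations, with
  a never-uphill safeguard (the incoming pose is kept if the optimiser
  fails to improve it).
- The Metropolis schedule returns the best-so-far state, making the
  energy guarantee unconditional on acceptance statistics.
- Soft-core LJ keeps energies finite at bead overlap so minimisation
  from clashed starts is well-behaved.

## Limitations

- No all-atom relaxation or molecular-dynamics validation of rings.
- The CG energy ranks geometries; it is not calibrated to binding free
  energies.
- Side chains beyond CB are not built by the generators; side-chain
  distance analyses require structures that carry the atoms.
- Secondary-structure classes from rectangular φ/ψ regions approximate
  pattern-based assignment programs; boundary conformations can differ.
- Chemical-shift prediction from structure is out of scope; the shift
  module compares *given* shift tables against the coil reference.
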