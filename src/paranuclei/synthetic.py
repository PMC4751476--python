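"""Synthetic structure generation: every input the pipeline needs,
without molecular dynamics or downloads.

Backbones are built from φ/ψ dihedrals by sequential internal-coordinate
(NeRF) placement with ideal covalent geometry; ensembles draw frames from
a mixture of dihedral states with configurable weights and noise,
emulating a pooled disordered-peptide trajectory with known ground truth;
ideal dimers apply a known screw transform so that the geometry-recovery
machinery can be tested against exact parameters.  All generators are
pure functions of their configuration, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Conformer, Ensemble, RigidTransform
from .params import load_ideal_geometry
from .screw import ScrewParameters

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float
               ) -> np.ndarray:
    """Place atom D so that |CD| = bond, ∠BCD = angle, τ(A,B,C,D) = torsion.

    The natural-extension reference-frame construction used by internal-
    coordinate chain builders.
    """
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(sequence: str, phi_psi: np.ndarray,
                   chain_id: str = "A") -> Conformer:
    """Build a peptide backbone (N, CA, C, O, plus CB except Gly) from
    per-residue (φ, ψ) in degrees.

    ``phi_psi`` has one row per residue; the first residue's φ and the
    last residue's ψ enter only through carbonyl placement.  Peptide
    bonds are trans (ω = 180°); measured dihedrals of the output match
    the inputs to well under half a degree.
    """
    sequence = sequence.strip().upper()
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"invalid residue letter {letter!r}")
    phi_psi = np.asarray(phi_psi, float)
    if phi_psi.shape != (len(sequence), 2):
        raise ValueError("phi_psi must have shape (n_residues, 2)")
    geo = load_ideal_geometry()
    bonds, angles, torsions = geo["bonds"], geo["angles"], geo["torsions"]

    coords: list[np.ndarray] = []
    names: list[str] = []
    elements: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []

    def add(name: str, element: str, resid: int, resname: str,
            xyz: np.ndarray) -> None:
        coords.append(xyz)
        names.append(name)
        elements.append(element)
        resids.append(resid)
        resnames.append(resname)

    # bootstrap the first residue in the xy-plane
    n_i = np.zeros(3)
    ca_i = np.array([bonds["N_CA"], 0.0, 0.0])
    a = np.radians(angles["N_CA_C"])
    c_i = ca_i + bonds["CA_C"] * np.array([-np.cos(a), np.sin(a), 0.0])

    for i, letter in enumerate(sequence):
        resname = ONE_TO_THREE[letter]
        resid = i + 1
        add("N", "N", resid, resname, n_i)
        add("CA", "C", resid, resname, ca_i)
        add("C", "C", resid, resname, c_i)
        psi = phi_psi[i, 1]
        add("O", "O", resid, resname,
            place_atom(n_i, ca_i, c_i, bonds["C_O"], angles["CA_C_O"],
                       psi + 180.0))
        if resname != "GLY":
            add("CB", "C", resid, resname,
                place_atom(c_i, n_i, ca_i, bonds["CA_CB"],
                           angles["N_CA_CB"], torsions["cb_improper"]))
        if i + 1 < len(sequence):
            n_next = place_atom(n_i, ca_i, c_i, bonds["C_N"],
                                angles["CA_C_N"], psi)
            ca_next = place_atom(ca_i, c_i, n_next, bonds["N_CA"],
                                 angles["C_N_CA"], torsions["omega"])
            c_next = place_atom(c_i, n_next, ca_next, bonds["CA_C"],
                                angles["N_CA_C"], phi_psi[i + 1, 0])
            n_i, ca_i, c_i = n_next, ca_next, c_next

    n = len(coords)
    return Conformer(np.array(coords), np.array(names, dtype="U6"),
                     np.array(elements, dtype="U2"),
                     np.array(resids, dtype=int),
                     np.array(resnames, dtype="U4"),
                     np.full(n, chain_id, dtype="U2"))


@dataclass
class StateSpec:
    """One conformational state of the generator mixture.

    ``phi``/``psi`` are per-residue target dihedrals in degrees (scalars
    broadcast); ``dihedral_sigma`` is the Gaussian jitter applied to both.
    """

    phi: float | np.ndarray
    psi: float | np.ndarray
    dihedral_sigma: float = 5.0
    name: str = ""


@dataclass
class GeneratorConfig:
    """Configuration of the mixture-ensemble generator.

    Frames draw a state by ``weights`` (must sum to 1), jitter that
    state's target dihedrals, build the backbone and add isotropic
    Cartesian noise of ``cartesian_sigma`` Å.  A fixed seed makes the
    output byte-identical across runs.
    """

    sequence: str
    states: list[StateSpec]
    weights: list[float]
    n_frames: int = 100
    cartesian_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.states) != len(self.weights):
            raise ValueError("one weight per state required")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("state weights must sum to 1")
        if self.cartesian_sigma < 0:
            raise ValueError("cartesian_sigma must be non-negative")


def sample_ensemble(cfg: GeneratorConfig) -> Ensemble:
    """Draw a seeded synthetic ensemble; frame labels record the state
    index each frame was drawn from."""
    rng = np.random.default_rng(cfg.seed)
    n_res = len(cfg.sequence)
    targets = []
    for st in cfg.states:
        phi = np.broadcast_to(np.asarray(st.phi, float), (n_res,))
        psi = np.broadcast_to(np.asarray(st.psi, float), (n_res,))
        targets.append((phi, psi, st.dihedral_sigma))
    states = rng.choice(len(cfg.states), size=cfg.n_frames, p=cfg.weights)
    conformers = []
    for k in range(cfg.n_frames):
        phi, psi, sig = targets[states[k]]
        pp = np.column_stack([
            phi + rng.normal(0.0, sig, n_res) if sig > 0 else phi,
            psi + rng.normal(0.0, sig, n_res) if sig > 0 else psi,
        ])
        c = build_backbone(cfg.sequence, pp)
        if cfg.cartesian_sigma > 0:
            c = c.with_coords(c.coords + rng.normal(
                0.0, cfg.cartesian_sigma, c.coords.shape))
        conformers.append(c)
    return Ensemble(conformers, labels=[int(s) for s in states])


def make_ideal_dimer(protomer: Conformer, screw: ScrewParameters
                     ) -> tuple[Conformer, Conformer, ScrewParameters]:
    """Dimer whose protomer2 is protomer1 under a known screw transform.

    Returns (protomer1, protomer2, generating screw) so that
    transform-extraction round trips can be asserted against exact
    ground truth.
    """
    t = screw.to_transform()
    p2 = protomer.transformed(t)
    p2 = Conformer(p2.coords, p2.atom_names, p2.elements, p2.resids,
                   p2.resnames, np.full(p2.n_atoms, "B", dtype="U2"))
    return protomer, p2, screw


def random_point_conformer(n_points: int, rng: np.random.Generator,
                           spread: float = 10.0) -> Conformer:
    """A toy rigid body of random CA pseudo-atoms (one per residue).

    Handy for geometry tests that need arbitrary non-coplanar point sets
    carrying the Conformer interface.
    """
    coords = rng.uniform(-spread, spread, size=(n_points, 3))
    return Conformer(coords,
                     np.full(n_points, "CA", dtype="U6"),
                     np.full(n_points, "C", dtype="U2"),
                     np.arange(1, n_points + 1),
                     np.full(n_points, "GLY", dtype="U4"),
                     np.full(n_points, "A", dtype="U2"))
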