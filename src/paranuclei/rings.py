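"""Ring-shaped oligomer construction and measurement.

A dimer interface whose screw is nearly cyclic (θ ≈ 360/N, small rise) is
turned into an exact N-fold ring by projecting the interface onto the
cyclic manifold (θ = 360/N, zero rise) and then relaxing the protomer pose
by a seeded Metropolis Monte-Carlo search that keeps the cyclic constraint
hard: every trial state is a rigid protomer move replicated by exact
N-fold symmetry, so the ring closure error is zero by construction at
every step.  Rings are measured (outer diameter, height, pore diameter),
their inter-protomer residue contacts mapped, and ring-on-ring stacks
proposed by reusing the coarse-grained docking engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import Conformer, RigidTransform
from .cgdock import CGModel, PoseCluster, coarse_grain, dock, \
    interaction_energy
from .screw import ScrewParameters, extend_helix, screw_from_transform, \
    split_chains


@dataclass
class MonteCarloConfig:
    """Schedule of the cyclic-constraint Monte-Carlo relaxation.

    Moves are small rotations of the protomer about its centroid
    (≤ ``max_rotation_deg``) and translations in the ring plane
    (≤ ``max_translation``, Å); ``temperature`` is the Metropolis energy
    scale in kcal/mol.
    """

    steps: int = 300
    max_rotation_deg: float = 2.0
    max_translation: float = 0.5
    temperature: float = 0.6
    seed: int = 0


@dataclass
class RingAssembly:
    """N protomers under exact N-fold cyclic symmetry.

    The protomer is stored in the symmetry frame (axis = +z through the
    origin); the interface transform is the exact 360/N rotation about
    that axis.  ``closure_error`` is the displacement of a test point
    under N applications of the interface transform (Å) and
    ``interface_energy`` the coarse-grained energy of one protomer with
    the rest of the ring (kcal/mol).
    """

    protomer: Conformer
    n: int
    interface: RigidTransform
    closure_error: float
    interface_energy: float

    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def screw(self) -> ScrewParameters:
        return ScrewParameters(axis=self.axis_direction,
                               point=self.axis_point,
                               angle=360.0 / self.n, rise=0.0)

    def assembly(self) -> Conformer:
        """The merged N-chain ring structure."""
        return extend_helix(self.protomer, self.interface, self.n)


@dataclass
class RingMetrics:
    """Ring dimensions in nm: outer diameter, height, pore diameter."""

    outer_diameter: float
    height: float
    pore_diameter: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pore_diameter <= self.outer_diameter):
            raise ValueError("pore diameter must lie in [0, outer diameter]")
        if self.height < 0:
            raise ValueError("height must be non-negative")


def _cyclic_interface(n: int) -> RigidTransform:
    rot = Rotation.from_rotvec([0.0, 0.0, 2.0 * np.pi / n]).as_matrix()
    return RigidTransform(rot, np.zeros(3))


def _to_axis_frame(protomer: Conformer, screw: ScrewParameters) -> Conformer:
    """Express a protomer in the frame with the screw axis along +z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(screw.axis, z)
    c = float(screw.axis @ z)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else Rotation.from_rotvec(
            [np.pi, 0.0, 0.0]).as_matrix()
    else:
        rot = Rotation.from_rotvec(
            v / np.linalg.norm(v) * np.arccos(np.clip(c, -1, 1))).as_matrix()
    frame = RigidTransform(rot, -rot @ screw.point)
    return protomer.transformed(frame)


def _ring_energy(cg: CGModel, interface: RigidTransform, n: int,
                 params: dict | None) -> float:
    """CG energy of protomer 1 with every other protomer of the ring."""
    total = 0.0
    current = interface
    for _ in range(n - 1):
        total += interaction_energy(cg, cg.transformed(current),
                                    params=params)
        current = interface.compose(current)
    return total


def closure_error_of(interface: RigidTransform, n: int,
                     test_point: np.ndarray | None = None) -> float:
    """Displacement (Å) of a test point under n applications of the
    interface transform; zero for an exactly cyclic interface."""
    if test_point is None:
        test_point = np.array([10.0, 0.0, 0.0])
    moved = interface.power(n).apply(test_point)
    return float(np.linalg.norm(moved - test_point))


def cyclize(protomer: Conformer, t: RigidTransform, n: int,
            mc_config: MonteCarloConfig | None = None,
            cg_params: dict | None = None) -> RingAssembly:
    """Enforce exact N-fold closure and relax the protomer pose.

    The screw of ``t`` is projected onto the cyclic manifold (rotation
    exactly 360/N about the screw axis, zero rise), the protomer is
    expressed in the axis frame, and a seeded Metropolis search perturbs
    the protomer pose — each trial replicated by exact symmetry — to
    lower the coarse-grained inter-protomer energy.  The best state seen
    is returned, so the final energy never exceeds the projected start's.
    """
    if not (3 <= n <= 24):
        raise ValueError("ring size must be between 3 and 24 protomers")
    if mc_config is None:
        mc_config = MonteCarloConfig()
    screw = screw_from_transform(t)
    if screw.degenerate:
        raise ValueError("pure translation cannot seed a ring")
    base = _to_axis_frame(protomer, screw)
    interface = _cyclic_interface(n)
    cg = coarse_grain(base, params=cg_params)

    rng = np.random.default_rng(mc_config.seed)
    coords = base.coords.copy()
    beads = cg.positions.copy()

    def energy_of(bead_pos: np.ndarray) -> float:
        model = CGModel(bead_pos, cg.radii, cg.charges, cg.epsilons,
                        cg.types, cg.resids)
        return _ring_energy(model, interface, n, cg_params)

    e_current = energy_of(beads)
    best_coords, best_beads, e_best = coords.copy(), beads.copy(), e_current
    improved = False
    for _ in range(mc_config.steps):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(-mc_config.max_rotation_deg,
                                       mc_config.max_rotation_deg))
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        shift = np.array([rng.uniform(-mc_config.max_translation,
                                      mc_config.max_translation),
                          rng.uniform(-mc_config.max_translation,
                                      mc_config.max_translation), 0.0])
        pivot = beads.mean(axis=0)
        trial_beads = (beads - pivot) @ rot.T + pivot + shift
        e_trial = energy_of(trial_beads)
        delta = e_trial - e_current
        if delta <= 0 or rng.random() < np.exp(
                -delta / max(mc_config.temperature, 1e-12)):
            beads = trial_beads
            coords = (coords - pivot) @ rot.T + pivot + shift
            e_current = e_trial
            if e_current < e_best:
                best_coords, best_beads = coords.copy(), beads.copy()
                e_best = e_current
                improved = True
    if not improved and mc_config.steps > 0:
        import logging
        logging.getLogger(__name__).info(
            "cyclize: no energy improvement over %d steps; "
            "returning the projected start", mc_config.steps)
    final = base.with_coords(best_coords)
    return RingAssembly(protomer=final, n=n, interface=interface,
                        closure_error=closure_error_of(interface, n),
                        interface_energy=e_best)


def ring_metrics(ring: RingAssembly | Conformer,
                 axis_direction: np.ndarray | None = None,
                 axis_point: np.ndarray | None = None) -> RingMetrics:
    """Ring dimensions from heavy-atom geometry, in nm.

    Operational definitions: outer diameter = twice the maximum radial
    distance from the symmetry axis, height = heavy-atom extent along the
    axis, pore diameter = twice the minimum radial distance.
    """
    if isinstance(ring, RingAssembly):
        structure = ring.assembly()
        axis_direction = ring.axis_direction
        axis_point = ring.axis_point
    else:
        structure = ring
        if axis_direction is None:
            raise ValueError("axis required for a bare structure")
        axis_point = np.zeros(3) if axis_point is None else axis_point
    u = np.asarray(axis_direction, float)
    u = u / np.linalg.norm(u)
    rel = structure.coords[structure.heavy_mask()] - np.asarray(axis_point)
    along = rel @ u
    radial = np.linalg.norm(rel - np.outer(along, u), axis=1)
    return RingMetrics(outer_diameter=2.0 * float(radial.max()) / 10.0,
                       height=float(along.max() - along.min()) / 10.0,
                       pore_diameter=2.0 * float(radial.min()) / 10.0)


def contact_map(protomer_a: Conformer, protomer_b: Conformer,
                cutoff: float = 0.45) -> pd.DataFrame:
    """Inter-protomer residue contact matrix.

    Entry (i, j) is True iff the minimum heavy-atom distance between
    residue i of A and residue j of B is below ``cutoff`` (nm).  Rows are
    residues of A, columns residues of B.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ha = protomer_a.heavy_mask()
    hb = protomer_b.heavy_mask()
    res_a = protomer_a.residue_ids()
    res_b = protomer_b.residue_ids()
    d = cdist(protomer_a.coords[ha], protomer_b.coords[hb]) / 10.0
    ra = protomer_a.resids[ha]
    rb = protomer_b.resids[hb]
    mat = np.zeros((len(res_a), len(res_b)), dtype=bool)
    for i, r1 in enumerate(res_a):
        rows = ra == r1
        for j, r2 in enumerate(res_b):
            mat[i, j] = d[np.ix_(rows, rb == r2)].min() < cutoff
    return pd.DataFrame(mat, index=res_a, columns=res_b)


@dataclass
class StackPose:
    """A ring-on-ring pose with the faces in contact.

    Face labels are "N" (the face enriched in the N-terminal residue
    range) or "C" for each ring.
    """

    cluster: PoseCluster
    face_ring1: str
    face_ring2: str

    @property
    def energy(self) -> float:
        return self.cluster.energy


def _face_direction(structure: Conformer, axis: np.ndarray,
                    face_residues: tuple[int, int]) -> float:
    """Signed axial offset of the face-residue range from the body mean."""
    u = axis / np.linalg.norm(axis)
    heavy = structure.heavy_mask()
    z = structure.coords[heavy] @ u
    sel = heavy & (structure.resids >= face_residues[0]) \
        & (structure.resids <= face_residues[1])
    if not sel.any():
        raise ValueError("face residue range selects no atoms")
    return float((structure.coords[sel] @ u).mean() - z.mean())


def label_stack_faces(s1: Conformer, axis1: np.ndarray,
                      ring2: RingAssembly, pose: RigidTransform,
                      face_residues: tuple[int, int]) -> tuple[str, str]:
    """Face labels ("N"/"C") of the two rings for one stacking pose.

    A ring presents its "N" face to the partner when the face-residue
    range lies on the side of the ring plane pointing at the partner.
    """
    axis1 = np.asarray(axis1, float)
    axis1 = axis1 / np.linalg.norm(axis1)
    n_off1 = _face_direction(s1, axis1, face_residues)
    c1 = s1.coords[s1.heavy_mask()].mean(axis=0)
    moved = ring2.assembly().transformed(pose)
    c2 = moved.coords[moved.heavy_mask()].mean(axis=0)
    toward2 = float((c2 - c1) @ axis1)
    face1 = "N" if np.sign(n_off1) == np.sign(toward2) else "C"
    axis2 = pose.rotation @ (ring2.axis_direction
                             / np.linalg.norm(ring2.axis_direction))
    n_off2 = _face_direction(moved, axis2, face_residues)
    toward1 = float((c1 - c2) @ axis2)
    face2 = "N" if np.sign(n_off2) == np.sign(toward1) else "C"
    return face1, face2


def stack_rings(ring1: RingAssembly, ring2: RingAssembly,
                face_residues: tuple[int, int] = (1, 9),
                n_points: int = 24, n_orientations: int = 2,
                cg_params: dict | None = None) -> list[StackPose]:
    """Dock one ring onto another and label the contacting faces.

    Reuses the systematic CG docking engine with ring1 fixed.  Each ranked
    pose is labelled by which face of each ring (N-terminal-enriched "N"
    face vs the opposite "C" face, classified by the mean axial position
    of ``face_residues``) points at the partner.
    """
    s1 = ring1.assembly()
    s2 = ring2.assembly()
    cg1 = coarse_grain(s1, params=cg_params)
    cg2 = coarse_grain(s2, params=cg_params)
    clusters = dock(cg1, cg2, n_points=n_points,
                    n_orientations=n_orientations, params=cg_params)
    axis1 = ring1.axis_direction / np.linalg.norm(ring1.axis_direction)
    out = []
    for cl in clusters:
        face1, face2 = label_stack_faces(s1, axis1, ring2,
                                         cl.representative.transform,
                                         face_residues)
        out.append(StackPose(cluster=cl, face_ring1=face1, face_ring2=face2))
    return out
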