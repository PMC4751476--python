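"""Screw-transformation analysis of oligomer interfaces.

Any proper rigid motion is, by Chasles' theorem, a rotation about an axis
combined with a translation along that same axis (a screw).  Extracting
the screw of the protomer1→protomer2 transform of a dimer immediately
yields the helical polymer that repeats the interface: rotation per step
θ gives the number of protomers per turn n = 360/|θ|, the rise per step d
gives the pitch P = n·|d|.  Ring-shaped N-mers are the nearly degenerate
case θ ≈ 360/N, d ≈ 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Conformer, RigidTransform, chain_letters, superpose

#: |θ| below which a transform is treated as a pure translation (degrees)
ANGLE_DEGENERACY_TOL = 0.1


@dataclass
class ScrewParameters:
    """Screw decomposition of a rigid transform.

    ``axis`` is a unit direction, ``point`` a point on the axis (Å),
    ``angle`` the rotation per step in degrees (0 < θ ≤ 180 by the
    package's convention; the axis direction carries the sense), and
    ``rise`` the signed translation per step along the axis (Å).
    Degenerate (near-zero rotation) screws are flagged; their helical
    descriptors are undefined.
    """

    axis: np.ndarray
    point: np.ndarray
    angle: float
    rise: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, float).reshape(3)
        self.point = np.asarray(self.point, float).reshape(3)
        norm = np.linalg.norm(self.axis)
        if abs(norm - 1.0) > 1e-8:
            if norm == 0:
                raise ValueError("axis direction cannot be zero")
            self.axis = self.axis / norm

    @property
    def protomers_per_turn(self) -> float:
        if self.degenerate:
            raise ValueError("degenerate screw: protomers per turn undefined")
        return 360.0 / abs(self.angle)

    @property
    def pitch_nm(self) -> float:
        """Axial advance per full turn, nm (absolute)."""
        if self.degenerate:
            raise ValueError("degenerate screw: pitch undefined")
        return self.protomers_per_turn * abs(self.rise) / 10.0

    @property
    def handedness(self) -> int:
        """+1 right-handed, −1 left-handed, 0 for zero rise."""
        return int(np.sign(self.angle * self.rise))

    def to_transform(self) -> RigidTransform:
        """Recompose the rigid transform this screw describes."""
        rot = Rotation.from_rotvec(
            np.radians(self.angle) * self.axis).as_matrix()
        trans = self.rise * self.axis + (np.eye(3) - rot) @ self.point
        return RigidTransform(rot, trans)


def transform_from_dimer(protomer1: Conformer, protomer2: Conformer,
                         selection: str = "ca") -> RigidTransform:
    """Optimal rigid transform mapping protomer1 onto protomer2.

    Least-squares superposition of matched atom selections (default CA
    atoms, matched by order).
    """
    from .ensemble import _selection_mask
    a = protomer1.coords[_selection_mask(protomer1, selection)]
    b = protomer2.coords[_selection_mask(protomer2, selection)]
    if len(a) != len(b):
        raise ValueError("protomer selections differ in atom count")
    transform, _ = superpose(a, b)
    return transform


def screw_from_transform(t: RigidTransform) -> ScrewParameters:
    """Chasles decomposition of a rigid transform into screw parameters.

    The rotation angle and axis come from the rotation-vector form; the
    rise is the translation's projection on the axis; the axis point
    solves the in-plane fixed-point equation
    (I − R) p = t_perp via the half-angle closed form.  Near-zero
    rotations return a degenerate flag rather than meaningless axis
    numbers.  Convention: θ ∈ (0, 180]; at θ = 180° (axis sign
    ambiguous) the axis is chosen so that the rise is ≥ 0.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < ANGLE_DEGENERACY_TOL:
        return ScrewParameters(axis=np.array([0.0, 0.0, 1.0]),
                               point=np.zeros(3), angle=0.0,
                               rise=float(np.linalg.norm(t.translation)),
                               degenerate=True)
    axis = rotvec / np.linalg.norm(rotvec)
    if angle > 180.0 - 1e-9:
        # axis sign ambiguous at a half turn: pick the sign giving rise >= 0
        if float(t.translation @ axis) < 0:
            axis = -axis
    rise = float(t.translation @ axis)
    t_perp = t.translation - rise * axis
    # p = (t_perp + cot(θ/2) * (axis × t_perp)) / 2 solves (I−R)p = t_perp
    half = np.radians(angle) / 2.0
    point = 0.5 * (t_perp + np.cross(axis, t_perp) / np.tan(half))
    return ScrewParameters(axis=axis, point=point, angle=angle, rise=rise)


def helical_descriptors(s: ScrewParameters) -> tuple[float, float, int]:
    """(protomers per turn, pitch in nm, handedness) of a screw."""
    if s.degenerate:
        raise ValueError("degenerate screw has no helical descriptors")
    return s.protomers_per_turn, s.pitch_nm, s.handedness


def extend_helix(protomer: Conformer, t: RigidTransform, n: int,
                 clash_distance: float = 1.0) -> Conformer:
    """Helical N-mer obtained by repeating the interface transform.

    Protomer k (1-based) is t^(k−1) applied to the input protomer; chains
    are relabelled A, B, C, …  A steric catastrophe (any inter-protomer CA
    pair closer than ``clash_distance`` Å) logs a warning but the assembly
    is still returned for inspection.
    """
    import logging
    if n < 2:
        raise ValueError("an assembly needs at least 2 protomers")
    letters = chain_letters(n)
    parts = []
    current = RigidTransform.identity()
    for k in range(n):
        moved = protomer.transformed(current)
        moved = Conformer(moved.coords, moved.atom_names, moved.elements,
                          moved.resids, moved.resnames,
                          np.full(moved.n_atoms, letters[k]))
        parts.append(moved)
        current = t.compose(current)
    merged = Conformer(
        np.concatenate([p.coords for p in parts]),
        np.concatenate([p.atom_names for p in parts]),
        np.concatenate([p.elements for p in parts]),
        np.concatenate([p.resids for p in parts]),
        np.concatenate([p.resnames for p in parts]),
        np.concatenate([p.chain_ids for p in parts]),
    )
    ca = [p.coords[p.atom_names == "CA"] for p in parts]
    if len(ca[0]):
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(ca[i][:, None] - ca[j][None], axis=-1)
                if d.min() < clash_distance:
                    logging.getLogger(__name__).warning(
                        "steric catastrophe between protomers %d and %d "
                        "(min CA distance %.2f Å)", i + 1, j + 1, d.min())
    return merged


def split_chains(assembly: Conformer) -> list[Conformer]:
    """Split a multi-chain assembly into per-protomer conformers,
    in chain order of appearance."""
    seen = []
    for cid in assembly.chain_ids:
        if cid not in seen:
            seen.append(cid)
    return [assembly.select(assembly.chain_ids == cid) for cid in seen]


@dataclass
class SelectionCriteria:
    """Geometric ring-candidate criteria.

    Keep screws whose protomers-per-turn lies in [n_min, n_max]
    (inclusive) and whose pitch is strictly below ``pitch_max_nm`` —
    operationalizing "nearly cyclic" purely by these printed bounds.
    ``marker_residue`` names the residue whose inward orientation is
    screened separately (default None → last residue, the C-terminus).
    """

    n_min: float = 5.0
    n_max: float = 6.0
    pitch_max_nm: float = 2.0
    marker_residue: int | None = None

    def __post_init__(self) -> None:
        if self.n_min > self.n_max:
            raise ValueError("n_min must not exceed n_max")
        if self.pitch_max_nm <= 0:
            raise ValueError("pitch_max_nm must be positive")


def filter_candidates(screws: list[ScrewParameters],
                      criteria: SelectionCriteria | None = None
                      ) -> tuple[list[int], list[str]]:
    """Indices of screws passing the ring criteria, plus per-screw reasons.

    Returns ``(passing_indices, reasons)`` where ``reasons[i]`` is
    ``"pass"`` or a short failure description.
    """
    if criteria is None:
        criteria = SelectionCriteria()
    passing, reasons = [], []
    for i, s in enumerate(screws):
        if s.degenerate:
            reasons.append("degenerate (pure translation)")
            continue
        n = s.protomers_per_turn
        p = s.pitch_nm
        if not (criteria.n_min <= n <= criteria.n_max):
            reasons.append(f"protomers per turn {n:.3g} outside "
                           f"[{criteria.n_min:g}, {criteria.n_max:g}]")
        elif not (p < criteria.pitch_max_nm):
            reasons.append(f"pitch {p:.3g} nm not below "
                           f"{criteria.pitch_max_nm:g} nm")
        else:
            passing.append(i)
            reasons.append("pass")
    return passing, reasons


def orientation_filter(assembly: Conformer, screw: ScrewParameters,
                       marker_residue: int | None = None) -> bool:
    """Whether a marker residue points toward the assembly axis.

    True iff, averaged over protomers, the marker residue's CA radial
    distance from the screw axis is strictly smaller than the protomer's
    mean CA radial distance.  The marker defaults to the last residue
    (the C-terminus); boundary equality is False.
    """
    if screw.degenerate:
        raise ValueError("degenerate screw has no defined axis")
    protomers = split_chains(assembly)
    marker_r, mean_r = [], []
    for p in protomers:
        resids = p.residue_ids()
        marker = marker_residue if marker_residue is not None \
            else int(resids[-1])
        ca = p.atom_names == "CA"
        if not ca.any():
            raise ValueError("assembly protomers lack CA atoms")
        radial = _radial_distance(p.coords[ca], screw)
        mean_r.append(radial.mean())
        mca = ca & (p.resids == marker)
        if not mca.any():
            raise ValueError(f"marker residue {marker} has no CA atom")
        marker_r.append(_radial_distance(p.coords[mca], screw).mean())
    return float(np.mean(marker_r)) < float(np.mean(mean_r))


def _radial_distance(points: np.ndarray, screw: ScrewParameters) -> np.ndarray:
    rel = np.atleast_2d(points) - screw.point
    along = rel @ screw.axis
    perp = rel - np.outer(along, screw.axis)
    return np.linalg.norm(perp, axis=1)
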