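"""Systematic rigid-body self-docking at coarse-grained resolution.

A peptide conformer is reduced to one backbone bead per residue (on CA)
plus one side-chain bead on the side-chain heavy-atom centroid (none for
glycine).  Ligand copies are placed on a deterministic sphere of start
positions around the receptor, each start pose is relaxed over the six
rigid-body degrees of freedom against a soft Lennard-Jones plus screened
Coulomb bead potential, and the relaxed poses are clustered by ligand-bead
RMSD and ranked by interaction energy.  The bead parameter set is plain
editable data (see ``data/cg_params.yaml``); it aims at plausible packed
interfaces, not at reproducing any published force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .core import Conformer, RigidTransform
from .params import load_cg_params

SIDECHAIN_EXCLUDE = ("N", "CA", "C", "O", "OXT")


@dataclass
class CGModel:
    """Bead model: positions (Å), radii (Å), charges (e), ε (kcal/mol)."""

    positions: np.ndarray
    radii: np.ndarray
    charges: np.ndarray
    epsilons: np.ndarray
    types: np.ndarray       # "BB" or "SC"
    resids: np.ndarray

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def largest_dimension(self) -> float:
        """Maximum bead-bead extent (Å)."""
        d = np.linalg.norm(self.positions[:, None] - self.positions[None],
                           axis=-1)
        return float(d.max())

    def transformed(self, t: RigidTransform) -> "CGModel":
        return CGModel(t.apply(self.positions), self.radii, self.charges,
                       self.epsilons, self.types, self.resids)


@dataclass
class DockPose:
    """A rigid pose of the ligand copy with its interaction energy."""

    transform: RigidTransform
    energy: float = np.inf
    converged: bool = False

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.energy):
            raise ValueError("a converged pose must have finite energy")


def coarse_grain(c: Conformer, scheme: str = "default",
                 params: dict | None = None) -> CGModel:
    """Map a conformer to the two-beads-per-residue coarse-grained model.

    Backbone bead on CA; side-chain bead on the side-chain heavy-atom
    centroid (glycine has none).  Side-chain charges ±1 on Asp/Glu and
    Lys/Arg; the terminal backbone beads carry the +1/−1 zwitterion
    charges.  Radii and ε come from the packaged parameter table.
    """
    if scheme != "default":
        raise ValueError(f"unknown coarse-graining scheme {scheme!r}")
    if params is None:
        params = load_cg_params()
    bb, sc = params["backbone"], params["sidechain"]
    heavy = c.heavy_mask()
    positions, radii, charges, epsilons, types, resids = \
        [], [], [], [], [], []
    seen: list[int] = []
    for r in c.residue_ids():
        r = int(r)
        mask = (c.resids == r) & heavy
        name = str(c.resnames[mask][0]).upper()
        if name not in sc["radius"] and name != "GLY":
            raise ValueError(f"unknown residue {name} at index {r}")
        ca = mask & (c.atom_names == "CA")
        if not ca.any():
            raise ValueError(f"residue {r} has no CA atom")
        positions.append(c.coords[ca][0])
        radii.append(bb["radius"])
        charges.append(bb["charge"])
        epsilons.append(params["sidechain"]["epsilon"])
        types.append("BB")
        resids.append(r)
        sc_mask = mask & ~np.isin(c.atom_names, SIDECHAIN_EXCLUDE)
        if sc_mask.any():
            positions.append(c.coords[sc_mask].mean(axis=0))
            radii.append(sc["radius"].get(name, bb["radius"]))
            charges.append(float(sc["charge"].get(name, 0.0)))
            epsilons.append(sc["epsilon"])
            types.append("SC")
            resids.append(r)
        seen.append(r)
    charges = np.array(charges, float)
    # zwitterion termini on the first/last backbone beads
    types_arr = np.array(types)
    bb_idx = np.flatnonzero(types_arr == "BB")
    charges[bb_idx[0]] += params["terminal_charges"]["nterm"]
    charges[bb_idx[-1]] += params["terminal_charges"]["cterm"]
    return CGModel(np.array(positions, float), np.array(radii, float),
                   charges, np.array(epsilons, float), types_arr,
                   np.array(resids, int))


def _pair_tables(receptor: CGModel, ligand: CGModel, params: dict):
    """Precompute σ, ε, qq and the soft-core linearization per pair."""
    sigma = receptor.radii[:, None] + ligand.radii[None, :]
    eps = np.sqrt(receptor.epsilons[:, None] * ligand.epsilons[None, :])
    qq = receptor.charges[:, None] * ligand.charges[None, :]
    return sigma, eps, qq


def interaction_energy(receptor: CGModel, ligand: CGModel,
                       pose: RigidTransform | DockPose | None = None,
                       params: dict | None = None) -> float:
    """Inter-body CG interaction energy in kcal/mol.

    Soft 12-6 Lennard-Jones (σ from the sum of bead radii, ε geometric
    mean) plus Coulomb screened by a distance-dependent dielectric
    ε(r) = slope·r.  Pairs beyond the cutoff contribute zero; below a
    soft-core fraction of σ the repulsion is continued linearly so the
    energy stays finite (never NaN) at overlap.
    """
    if params is None:
        params = load_cg_params()
    if isinstance(pose, DockPose):
        pose = pose.transform
    lig_pos = ligand.positions if pose is None else pose.apply(ligand.positions)
    sigma, eps, qq = _pair_tables(receptor, ligand, params)
    diff = receptor.positions[:, None, :] - lig_pos[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    cutoff = params["cutoff"]
    fcore = params["softcore_fraction"]
    kq = params["coulomb_constant"]
    slope = params["dielectric_slope"]

    within = r <= cutoff
    r_safe = np.where(r > 1e-12, r, 1e-12)
    # Lennard-Jones with linear soft-core continuation below fcore*sigma
    r_core = fcore * sigma
    r_lj = np.maximum(r_safe, r_core)
    s6 = (sigma / r_lj) ** 6
    e_lj = 4.0 * eps * (s6 ** 2 - s6)
    dldr = 4.0 * eps * (-12.0 * s6 ** 2 + 6.0 * s6) / r_lj
    below = r_safe < r_core
    e_lj = np.where(below, e_lj + dldr * (r_safe - r_core), e_lj)
    # screened Coulomb: eps(r) = slope * r  =>  E = kq q1 q2 / (slope r^2)
    r_c = np.maximum(r_safe, 0.5 * r_core)
    e_coul = kq * qq / (slope * r_c ** 2)
    return float(((e_lj + e_coul) * within).sum())


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors from the golden-spiral construction."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def generate_start_poses(receptor: CGModel, ligand: CGModel,
                         angular_spacing: float | None = None,
                         n_points: int | None = None,
                         n_orientations: int = 3,
                         margin: float = 1.2) -> list[RigidTransform]:
    """Deterministic start poses on a sphere around the receptor.

    The ligand centroid is placed on a golden-spiral sphere of radius
    ``margin`` × the receptor's largest dimension; at each point
    ``n_orientations`` spins about the radial direction are generated.
    The count of sphere points comes from ``n_points`` or from an
    ``angular_spacing`` in degrees (≈ one point per spacing² patch).
    The construction contains no randomness.
    """
    if n_points is None:
        if angular_spacing is None or angular_spacing <= 0:
            raise ValueError("give n_points or a positive angular_spacing")
        n_points = max(1, round(41253.0 / angular_spacing ** 2))
    radius = margin * receptor.largest_dimension()
    center = receptor.centroid()
    c_lig = ligand.centroid()
    poses = []
    for u in fibonacci_sphere(n_points):
        target = center + radius * u
        # base orientation: align the ligand's z axis with the inward
        # direction, then spin about the radial vector
        base = _align_z(-u)
        for j in range(n_orientations):
            spin = Rotation.from_rotvec(
                2.0 * np.pi * j / n_orientations * u).as_matrix()
            rot = spin @ base
            poses.append(RigidTransform(rot, target - rot @ c_lig))
    return poses


def _align_z(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto ``direction`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, direction)
    c = float(z @ direction)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else Rotation.from_rotvec(
            [np.pi, 0, 0]).as_matrix()
    return Rotation.from_rotvec(
        v / np.linalg.norm(v) * np.arccos(np.clip(c, -1, 1))).as_matrix()


def slide_to_contact(receptor: CGModel, ligand: CGModel,
                     pose: RigidTransform, gap: float = 1.0,
                     params: dict | None = None) -> RigidTransform:
    """Translate a pose along the receptor-ligand center line until the
    closest bead pair sits ``gap`` Å outside its contact distance.

    Start poses are generated outside the interaction cutoff, where the
    energy landscape is flat; this deterministic approach step brings the
    ligand into force range so local minimization can engage.  The pose
    orientation is unchanged.
    """
    lig_pos = pose.apply(ligand.positions)
    center_r = receptor.positions.mean(axis=0)
    center_l = lig_pos.mean(axis=0)
    direction = center_r - center_l
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        return pose
    direction = direction / norm
    sigma = receptor.radii[:, None] + ligand.radii[None, :]
    contact = 2.0 ** (1.0 / 6.0) * sigma + gap

    def min_excess(shift: float) -> float:
        moved = lig_pos + shift * direction
        d = np.linalg.norm(receptor.positions[:, None] - moved[None],
                           axis=-1)
        return float((d - contact).min())

    lo, hi = 0.0, norm
    if min_excess(0.0) <= 0.0:
        return pose  # already in contact
    if min_excess(hi) > 0.0:
        hi = norm  # sliding past the center never happens; clamp below
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_excess(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    shift = lo
    return RigidTransform(pose.rotation, pose.translation + shift * direction)


def _compose_increment(pose: RigidTransform, p: np.ndarray,
                       pivot: np.ndarray) -> RigidTransform:
    """Apply a 6-vector increment (3 translations, 3 axis-angle radians)
    to a pose, rotating about ``pivot`` (the ligand's current centroid)."""
    delta_r = Rotation.from_rotvec(p[3:]).as_matrix()
    rot = delta_r @ pose.rotation
    trans = delta_r @ (pose.translation - pivot) + pivot + p[:3]
    return RigidTransform(rot, trans)


def minimize_pose(receptor: CGModel, ligand: CGModel,
                  pose: RigidTransform | DockPose,
                  params: dict | None = None,
                  max_iter: int = 400, gtol: float = 1e-9) -> DockPose:
    """Relax a pose over the six rigid-body degrees of freedom.

    Local quasi-Newton minimization over 3 translations and 3 axis-angle
    rotation increments composed onto the current orientation (no Euler
    singularities).  The returned energy never exceeds the starting
    energy; non-convergence within ``max_iter`` flags the pose.
    """
    if params is None:
        params = load_cg_params()
    if isinstance(pose, DockPose):
        pose = pose.transform
    pivot = pose.apply(ligand.centroid())
    sigma, eps, qq = _pair_tables(receptor, ligand, params)

    def objective(p: np.ndarray) -> float:
        t = _compose_increment(pose, p, pivot)
        return interaction_energy(receptor, ligand, t, params)

    e_start = objective(np.zeros(6))
    res = minimize(objective, np.zeros(6), method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14,
                            "eps": 1e-6})
    if res.fun <= e_start:
        final = _compose_increment(pose, res.x, pivot)
        energy = float(res.fun)
    else:  # safeguard: never return an uphill result
        final, energy = pose, float(e_start)
    return DockPose(transform=final, energy=energy,
                    converged=bool(res.success or res.fun < e_start))


@dataclass
class PoseCluster:
    """A group of similar poses with its lowest-energy representative."""

    representative: DockPose
    members: list[int]

    @property
    def energy(self) -> float:
        return self.representative.energy


def cluster_and_rank(poses: list[DockPose], ligand: CGModel,
                     rmsd_cutoff: float = 2.0) -> list[PoseCluster]:
    """Single-linkage pose clustering and energy ranking.

    Pose similarity is ligand-bead RMSD with the receptor frame held
    fixed (no re-superposition), cutoff in Å.  Each cluster is
    represented by its lowest-energy member; clusters are returned sorted
    by representative energy, ascending.  Unconverged poses are ignored;
    none converged yields an empty list with a warning.
    """
    import logging
    converged = [i for i, p in enumerate(poses) if p.converged]
    if not converged:
        logging.getLogger(__name__).warning("no converged poses to cluster")
        return []
    coords = np.stack([poses[i].transform.apply(ligand.positions)
                       for i in converged])
    n = len(converged)
    if n == 1:
        labels = np.array([1])
    else:
        diffs = coords[:, None] - coords[None]
        rmsd = np.sqrt((diffs ** 2).sum(axis=-1).mean(axis=-1))
        labels = fcluster(linkage(squareform(rmsd, checks=False),
                                  method="single"),
                          t=rmsd_cutoff, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = [converged[j] for j in np.flatnonzero(labels == lab)]
        rep = min(members, key=lambda i: poses[i].energy)
        clusters.append(PoseCluster(representative=poses[rep],
                                    members=members))
    clusters.sort(key=lambda c: c.energy)
    return clusters


def dock(receptor: CGModel, ligand: CGModel,
         n_points: int = 32, n_orientations: int = 3,
         margin: float = 1.2, rmsd_cutoff: float = 2.0,
         params: dict | None = None) -> list[PoseCluster]:
    """Full systematic docking run: start poses → relaxation → ranking.

    Deterministic end to end: identical inputs and parameters give
    identical pose tables.
    """
    starts = generate_start_poses(receptor, ligand, n_points=n_points,
                                  n_orientations=n_orientations,
                                  margin=margin)
    relaxed = [minimize_pose(receptor, ligand,
                             slide_to_contact(receptor, ligand, s,
                                              params=params), params)
               for s in starts]
    return cluster_and_rank(relaxed, ligand, rmsd_cutoff)
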