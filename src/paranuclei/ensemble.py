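"""Ensemble observables for a disordered-peptide conformational ensemble.

Implements the analysis layer that links simulated conformers to NMR
observables and to conformer selection: backbone dihedrals, Karplus
back-calculated ³J(HN-Hα) couplings, secondary chemical shifts relative to
a random-coil reference, secondary-structure propensities, the RMSD/Rg
free-energy surface, and neighbor-count (gromos-style) clustering used to
pick representative conformations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Conformer, Ensemble
from .io import ObservableTable
from .params import KarplusParameters, load_karplus

logger = logging.getLogger(__name__)

# Boltzmann constant in kcal/(mol K)
BOLTZMANN_KCAL = 0.0019872

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "S": 32.06, "D": 2.014}

_BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT", "H", "HA", "HN", "H1", "H2",
                   "H3")


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle(s) in degrees, in (−180, 180].

    Accepts single points or stacked (..., 3) arrays; the standard
    two-plane atan2 formulation.
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 to honor the (−180, 180] convention
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


@dataclass
class DihedralSeries:
    """Per-frame, per-residue backbone φ/ψ in degrees; NaN marks missing.

    The first residue has no φ and the last has no ψ by construction.
    """

    phi: np.ndarray      # (n_frames, n_residues)
    psi: np.ndarray      # (n_frames, n_residues)
    resids: np.ndarray   # (n_residues,) 1-based indices

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


def backbone_dihedrals(ensemble: Ensemble, chain_id: str | None = None
                       ) -> DihedralSeries:
    """Backbone φ/ψ for every frame of an ensemble.

    φ(i) is the C(i−1)-N(i)-CA(i)-C(i) torsion and ψ(i) the
    N(i)-CA(i)-C(i)-N(i+1) torsion; residues missing a backbone atom are
    marked NaN with a logged warning.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    ref = ensemble[0]
    resids = ref.residue_ids(chain_id)
    n_res = len(resids)
    # resolve atom indices once; topology is shared across frames
    idx = {}
    for r in resids:
        for name in ("N", "CA", "C"):
            idx[(int(r), name)] = ref.atom_index(int(r), name, chain_id)
    coords = ensemble.coords_array()
    phi = np.full((len(ensemble), n_res), np.nan)
    psi = np.full((len(ensemble), n_res), np.nan)
    warned = set()
    for j, r in enumerate(resids):
        r = int(r)
        n_i, ca_i, c_i = idx[(r, "N")], idx[(r, "CA")], idx[(r, "C")]
        if min(n_i, ca_i, c_i) < 0:
            if r not in warned:
                logger.warning("residue %d lacks backbone atoms; "
                               "dihedrals marked missing", r)
                warned.add(r)
            continue
        if j > 0:
            c_prev = idx.get((int(resids[j - 1]), "C"), -1)
            if c_prev >= 0:
                phi[:, j] = dihedral_angle(coords[:, c_prev], coords[:, n_i],
                                           coords[:, ca_i], coords[:, c_i])
        if j < n_res - 1:
            n_next = idx.get((int(resids[j + 1]), "N"), -1)
            if n_next >= 0:
                psi[:, j] = dihedral_angle(coords[:, n_i], coords[:, ca_i],
                                           coords[:, c_i], coords[:, n_next])
    return DihedralSeries(phi=phi, psi=psi, resids=np.asarray(resids))


def karplus_j(phi_deg: np.ndarray, params: KarplusParameters) -> np.ndarray:
    """Evaluate the three-term Karplus curve at backbone φ (degrees)."""
    u = np.cos(np.radians(np.asarray(phi_deg) - params.offset_deg))
    return params.A * u ** 2 + params.B * u + params.C


def jcoupling_profile(dihedrals: DihedralSeries,
                      params: KarplusParameters | None = None
                      ) -> ObservableTable:
    """Ensemble-averaged ³J(HN-Hα) per residue in Hz.

    Residues with no defined φ in any frame (the N-terminus) are omitted.
    """
    if dihedrals.n_frames == 0:
        raise ValueError("no frames in dihedral series")
    if params is None:
        params = load_karplus()
    values: dict[int, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_j = np.nanmean(karplus_j(dihedrals.phi, params), axis=0)
    for r, j in zip(dihedrals.resids, mean_j):
        if np.isfinite(j):
            values[int(r)] = float(j)
    return ObservableTable(values, kind="jcoupling", label="3J(HN-HA)")


def secondary_shift(observed: ObservableTable, coil_reference: ObservableTable,
                    convention: str = "coil_minus_obs") -> ObservableTable:
    """Secondary chemical shift Δδ per residue.

    The default convention is Δδ = δ_coil − δ (deviation of the coil
    reference from the observed/back-calculated shift); pass
    ``convention="obs_minus_coil"`` for the opposite sign common
    elsewhere in the literature.  Residues absent or missing in either
    table are missing in the output.
    """
    if observed.kind != "shift" or coil_reference.kind != "shift":
        raise ValueError("secondary shifts require two shift tables "
                         f"(got {observed.kind!r} vs {coil_reference.kind!r})")
    if convention not in ("coil_minus_obs", "obs_minus_coil"):
        raise ValueError(f"unknown sign convention {convention!r}")
    sign = 1.0 if convention == "coil_minus_obs" else -1.0
    values: dict[int, float | None] = {}
    for r, obs in observed.values.items():
        coil = coil_reference.values.get(r)
        if obs is None or coil is None:
            values[r] = None
        else:
            values[r] = sign * (coil - obs)
    return ObservableTable(values, kind="shift", label="secondary_shift")


def pearson(x: ObservableTable, y: ObservableTable) -> float:
    """Pearson correlation over residues present in both tables."""
    shared = sorted(set(x.present()) & set(y.present()))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared residues with values")
    xv = np.array([x.values[r] for r in shared])
    yv = np.array([y.values[r] for r in shared])
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(stats.pearsonr(xv, yv).statistic)


# -- secondary structure ---------------------------------------------------

#: φ/ψ regions (degrees) of the dihedral-space fallback assigner.  These
#: are broad canonical basins, a deterministic stand-in for a full
#: pattern-recognition assignment: H covers the α-helical basin, E the
#: β/extended strip, T the remaining bridge/turn regions including the
#: left-handed helical island, everything else is coil (C).
SS_REGIONS = {
    "H": {"phi": (-100.0, -30.0), "psi": (-80.0, -5.0)},
    "E": {"phi": (-180.0, -100.0), "psi_up": (90.0, 180.0),
          "psi_down": (-180.0, -170.0)},
    "T_left": {"phi": (30.0, 90.0), "psi": (-20.0, 80.0)},
    "T_bridge": {"phi": (-180.0, 0.0), "psi": (-120.0, 60.0)},
}

STRIDE_CLASS_MAP = {"H": "H", "G": "H", "I": "H",
                    "E": "E", "B": "E", "b": "E",
                    "T": "T"}


def assign_secondary_structure(dihedrals: DihedralSeries, frame: int
                               ) -> np.ndarray:
    """Per-residue class in {H, E, T, C} for one frame, by φ/ψ region."""
    phi = dihedrals.phi[frame]
    psi = dihedrals.psi[frame]
    out = np.full(dihedrals.n_residues, "C", dtype="U1")
    for j in range(dihedrals.n_residues):
        out[j] = _classify_phipsi(phi[j], psi[j])
    return out


def _classify_phipsi(phi: float, psi: float) -> str:
    if not (np.isfinite(phi) and np.isfinite(psi)):
        return "C"
    h = SS_REGIONS["H"]
    if h["phi"][0] < phi < h["phi"][1] and h["psi"][0] < psi < h["psi"][1]:
        return "H"
    e = SS_REGIONS["E"]
    if e["phi"][0] <= phi <= e["phi"][1] and (
            e["psi_up"][0] < psi <= e["psi_up"][1]
            or e["psi_down"][0] <= psi <= e["psi_down"][1]):
        return "E"
    tl = SS_REGIONS["T_left"]
    if tl["phi"][0] < phi < tl["phi"][1] and tl["psi"][0] < psi < tl["psi"][1]:
        return "T"
    tb = SS_REGIONS["T_bridge"]
    if tb["phi"][0] < phi < tb["phi"][1] and tb["psi"][0] < psi < tb["psi"][1]:
        return "T"
    return "C"


def map_external_classes(letters) -> np.ndarray:
    """Map per-residue letters of an external assigner to {H, E, T, C}.

    Helical types (H, G, I) group to H, extended (E, B) to E, turns (T)
    to T; everything else is coil.
    """
    return np.array([STRIDE_CLASS_MAP.get(str(x), "C") for x in letters],
                    dtype="U1")


def parse_external_assignments(path) -> np.ndarray:
    """Parse a per-frame secondary-structure file into grouped classes.

    Expected format: one line of one-letter codes per frame (comments
    starting with ``#`` ignored); returns an (n_frames, n_residues) array.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(map_external_classes(list(line)))
    if not rows:
        raise ValueError(f"{path}: no assignment lines")
    return np.stack(rows)


def ss_propensity(ensemble: Ensemble | None = None,
                  dihedrals: DihedralSeries | None = None,
                  assignments: np.ndarray | None = None
                  ) -> dict[str, ObservableTable]:
    """Per-residue percentage of helical, extended and turn conformations.

    Accepts an ensemble (dihedrals computed internally), a precomputed
    dihedral series, or an explicit (n_frames, n_residues) class array.
    Returns one propensity table per class; the three profiles sum to
    ≤ 100 at every residue (coil takes the remainder).
    """
    if assignments is None:
        if dihedrals is None:
            if ensemble is None:
                raise ValueError("provide an ensemble, dihedrals "
                                 "or assignments")
            dihedrals = backbone_dihedrals(ensemble)
        assignments = np.stack([
            assign_secondary_structure(dihedrals, f)
            for f in range(dihedrals.n_frames)])
        resids = dihedrals.resids
    else:
        assignments = np.asarray(assignments)
        resids = np.arange(1, assignments.shape[1] + 1)
    n_frames = assignments.shape[0]
    out = {}
    for cls in ("H", "E", "T"):
        frac = 100.0 * (assignments == cls).sum(axis=0) / n_frames
        out[cls] = ObservableTable(
            {int(r): float(v) for r, v in zip(resids, frac)},
            kind="propensity", label=f"{cls}_percent")
    return out


# -- geometry observables --------------------------------------------------

def _selection_mask(c: Conformer, selection: str) -> np.ndarray:
    """Atom mask for a named selection.

    ``ca``: CA atoms; ``backbone``: N/CA/C heavy backbone; ``heavy``:
    all non-hydrogens; ``all``: everything.
    """
    if selection == "ca":
        return c.atom_names == "CA"
    if selection == "backbone":
        return np.isin(c.atom_names, ("N", "CA", "C")) & c.heavy_mask()
    if selection == "heavy":
        return c.heavy_mask()
    if selection == "all":
        return np.ones(c.n_atoms, dtype=bool)
    raise ValueError(f"unknown selection {selection!r}")


def kabsch_rmsd(a: Conformer, b: Conformer, selection: str = "backbone"
                ) -> float:
    """Minimum RMSD between two conformers over rigid superpositions (nm)."""
    ma, mb = _selection_mask(a, selection), _selection_mask(b, selection)
    pa, pb = a.coords[ma], b.coords[mb]
    if len(pa) != len(pb):
        raise ValueError("selections differ in atom count")
    from .core import superpose
    _, rmsd_ang = superpose(pa, pb)
    return rmsd_ang / 10.0


def pairwise_rmsd_matrix(coords: np.ndarray, chunk: int = 64) -> np.ndarray:
    """All-pairs minimum RMSD for stacked selected coordinates (nm).

    ``coords`` has shape (n_frames, n_atoms, 3) in Å.  Uses the
    singular-value identity rmsd² = (‖A‖² + ‖B‖² − 2(σ₁+σ₂±σ₃))/n with
    batched 3×3 SVDs, so the full matrix for ~10³ frames is tractable.
    """
    x = np.asarray(coords, float)
    m, k, _ = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    sq = np.einsum("ikd,ikd->i", x, x)
    out = np.zeros((m, m))
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        h = np.einsum("ikd,jke->ijde", x[start:stop], x)
        u, s, vt = np.linalg.svd(h)
        sign = np.sign(np.linalg.det(u @ vt))
        tr = s[..., 0] + s[..., 1] + sign * s[..., 2]
        d2 = (sq[start:stop, None] + sq[None, :] - 2.0 * tr) / k
        out[start:stop] = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(out, 0.0)
    # enforce exact symmetry against round-off
    out = 0.5 * (out + out.T)
    return out / 10.0


def radius_of_gyration(c: Conformer, mass_weighted: bool = False,
                       heavy_only: bool = True) -> float:
    """Radius of gyration in nm (about the center of mass, or the
    geometric center when unweighted)."""
    mask = c.heavy_mask() if heavy_only else np.ones(c.n_atoms, bool)
    coords = c.coords[mask]
    if len(coords) == 0:
        raise ValueError("no atoms selected")
    if mass_weighted:
        w = np.array([ATOMIC_MASSES.get(el, 12.011)
                      for el in c.elements[mask]])
    else:
        w = np.ones(len(coords))
    w = w / w.sum()
    center = (coords * w[:, None]).sum(axis=0)
    rg2 = (w * ((coords - center) ** 2).sum(axis=1)).sum()
    return float(np.sqrt(rg2)) / 10.0


@dataclass
class FreeEnergySurface:
    """2-D free-energy surface over (RMSD, Rg) with F = −kT ln N.

    Bin edges are in nm; ``free_energy`` is shifted so its occupied
    minimum is zero and holds NaN on empty bins.
    """

    rmsd_edges: np.ndarray
    rg_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    temperature: float
    boltzmann: float = BOLTZMANN_KCAL

    @property
    def kt(self) -> float:
        return self.boltzmann * self.temperature


def free_energy_from_counts(counts: np.ndarray, temperature: float = 300.0,
                            boltzmann: float = BOLTZMANN_KCAL) -> np.ndarray:
    """F = −kT ln N per bin, min-shifted to zero; empty bins → NaN."""
    counts = np.asarray(counts, dtype=float)
    if not (counts > 0).any():
        raise ValueError("no occupied bins")
    kt = boltzmann * temperature
    with np.errstate(divide="ignore"):
        f = np.where(counts > 0, -kt * np.log(counts), np.nan)
    return f - np.nanmin(f)


def free_energy_surface(ensemble: Ensemble, reference: Conformer,
                        bins: int | tuple = 32, temperature: float = 300.0,
                        selection: str = "backbone",
                        mass_weighted_rg: bool = False) -> FreeEnergySurface:
    """Free-energy surface over (RMSD to a reference conformer, Rg).

    Both axes in nm; counts are binned with :func:`numpy.histogram2d` and
    converted through F = −kT ln N at the analysis temperature (default
    300 K, the center of the sampled replica ladder).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    rmsd = np.array([kabsch_rmsd(c, reference, selection) for c in ensemble])
    rg = np.array([radius_of_gyration(c, mass_weighted_rg) for c in ensemble])
    counts, rmsd_edges, rg_edges = np.histogram2d(rmsd, rg, bins=bins)
    f = free_energy_from_counts(counts, temperature)
    return FreeEnergySurface(rmsd_edges=rmsd_edges, rg_edges=rg_edges,
                             counts=counts, free_energy=f,
                             temperature=temperature)


# -- clustering ------------------------------------------------------------

@dataclass
class ClusterSet:
    """Partition of frames into neighbor-count clusters.

    ``clusters`` holds member frame indices (representative first is not
    implied; see ``representatives``); clusters are ordered by decreasing
    size with ties broken by lower representative index.
    """

    clusters: list[list[int]]
    representatives: list[int]
    cutoff: float

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def gromos_cluster(ensemble: Ensemble | np.ndarray, cutoff: float = 0.2,
                   selection: str = "backbone") -> ClusterSet:
    """Neighbor-count conformational clustering (the gromos method).

    Iteratively: count, for every remaining frame, its neighbors within
    the RMSD ``cutoff`` (nm); the frame with the most neighbors (ties →
    lowest frame index) seeds a cluster, it and its neighbors are removed;
    repeat until no frame remains.  The seed frame is the cluster
    representative.  Accepts an :class:`Ensemble` or a precomputed
    pairwise RMSD matrix.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(ensemble, np.ndarray) and ensemble.ndim == 2:
        dmat = ensemble
    else:
        ref = ensemble[0]
        mask = _selection_mask(ref, selection)
        coords = ensemble.coords_array()[:, mask]
        dmat = pairwise_rmsd_matrix(coords)
    n = len(dmat)
    adjacency = dmat <= cutoff
    np.fill_diagonal(adjacency, False)
    remaining = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    reps: list[int] = []
    while remaining.any():
        counts = (adjacency & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero((adjacency[center] & remaining))
        group = sorted({center, *members.tolist()})
        clusters.append([int(g) for g in group])
        reps.append(center)
        remaining[group] = False
    order = sorted(range(len(clusters)),
                   key=lambda i: (-len(clusters[i]), reps[i]))
    return ClusterSet(clusters=[clusters[i] for i in order],
                      representatives=[reps[i] for i in order],
                      cutoff=cutoff)


def min_sidechain_distance(c: Conformer, res_a: int, res_b: int,
                           chain_a: str | None = None,
                           chain_b: str | None = None) -> float:
    """Minimal heavy-atom distance between two side chains, in nm.

    Backbone atoms (N, CA, C, O, OXT) and hydrogens are excluded; glycine
    contributes its CA as the side-chain stand-in.
    """
    def sidechain(resid: int, chain: str | None) -> np.ndarray:
        mask = (c.resids == resid) & c.heavy_mask()
        if chain is not None:
            mask &= c.chain_ids == chain
        if not mask.any():
            raise ValueError(f"residue {resid} not found")
        sc = mask & ~np.isin(c.atom_names, ("N", "CA", "C", "O", "OXT"))
        if not sc.any():  # glycine: fall back to CA
            sc = mask & (c.atom_names == "CA")
        if not sc.any():
            raise ValueError(f"residue {resid} has no usable atoms")
        return c.coords[sc]

    pa = sidechain(res_a, chain_a)
    pb = sidechain(res_b, chain_b)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min()) / 10.0
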