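"""Core domain types shared across the package.

Coordinates are Cartesian and carried in angstrom (Å) throughout; lengths
that the amyloid-oligomer literature quotes in nm (RMSD axes, ring
diameters, helical pitch) are converted at the reporting boundary only.
Residue numbering is 1-based, matching PDB convention, and residue ranges
are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")
HYDROGEN_ELEMENTS = ("H", "D")


class TopologyError(ValueError):
    """Raised when structures that must share a topology do not."""


@dataclass
class Conformer:
    """One peptide structure: coordinates plus per-atom/per-residue metadata.

    Parameters
    ----------
    coords : (n_atoms, 3) float array, Å.
    atom_names : per-atom PDB atom names (e.g. ``"CA"``).
    elements : per-atom element symbols.
    resids : per-atom 1-based residue indices.
    resnames : per-atom 3-letter residue names.
    chain_ids : per-atom single-character chain identifiers.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chain_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype="U4")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U2")
        for arr in (self.atom_names, self.elements, self.resids,
                    self.resnames, self.chain_ids):
            if len(arr) != n:
                raise ValueError("all per-atom arrays must match coords length")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask selecting non-hydrogen atoms."""
        return ~np.isin(self.elements, HYDROGEN_ELEMENTS)

    def select(self, mask: np.ndarray) -> "Conformer":
        return Conformer(self.coords[mask], self.atom_names[mask],
                         self.elements[mask], self.resids[mask],
                         self.resnames[mask], self.chain_ids[mask])

    def atom_index(self, resid: int, atom_name: str,
                   chain_id: str | None = None) -> int:
        """Index of a named atom, or -1 if absent."""
        mask = (self.resids == resid) & (self.atom_names == atom_name)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        idx = np.flatnonzero(mask)
        return int(idx[0]) if len(idx) else -1

    def residue_ids(self, chain_id: str | None = None) -> np.ndarray:
        """Ordered unique residue indices (optionally of one chain)."""
        resids = self.resids if chain_id is None else \
            self.resids[self.chain_ids == chain_id]
        _, first = np.unique(resids, return_index=True)
        return resids[np.sort(first)]

    def with_coords(self, coords: np.ndarray) -> "Conformer":
        """Copy sharing metadata with replaced coordinates."""
        return Conformer(np.asarray(coords, float), self.atom_names,
                         self.elements, self.resids, self.resnames,
                         self.chain_ids)

    def transformed(self, transform: "RigidTransform") -> "Conformer":
        return self.with_coords(transform.apply(self.coords))

    def centroid(self, heavy_only: bool = True) -> np.ndarray:
        coords = self.coords[self.heavy_mask()] if heavy_only else self.coords
        return coords.mean(axis=0)


@dataclass
class Ensemble:
    """Ordered collection of conformers sharing one topology.

    Stands in for pooled trajectory frames; ``labels`` may carry frame
    times, replica temperatures or generator state indices.
    """

    conformers: list[Conformer]
    labels: list | None = None

    def __post_init__(self) -> None:
        if self.conformers:
            ref = self.conformers[0]
            for i, c in enumerate(self.conformers):
                if c.n_atoms != ref.n_atoms or \
                        not np.array_equal(c.atom_names, ref.atom_names):
                    raise TopologyError(
                        f"conformer {i} does not share the ensemble topology")
        if self.labels is not None and len(self.labels) != len(self.conformers):
            raise ValueError("labels length must match number of conformers")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self) -> Iterator[Conformer]:
        return iter(self.conformers)

    def __getitem__(self, i) -> Conformer:
        return self.conformers[i]

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([c.coords for c in self.conformers])


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R x + t (rotation then translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def power(self, k: int) -> "RigidTransform":
        """k-fold composition (k ≥ 0)."""
        result = RigidTransform.identity()
        for _ in range(k):
            result = self.compose(result)
        return result


def superpose(mobile: np.ndarray, target: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the optimal proper rigid transform and the residual RMSD (Å).
    Standard Kabsch solution via SVD of the covariance matrix, with the
    determinant sign correction that excludes reflections.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2:
        raise ValueError("point sets must have identical (n, 3) shapes")
    if len(mobile) < 3:
        raise ValueError("need at least 3 points for superposition")
    if weights is None:
        weights = np.ones(len(mobile))
    w = np.asarray(weights, float)[:, None] / np.sum(weights)
    cm = (mobile * w).sum(axis=0)
    ct = (target * w).sum(axis=0)
    a = mobile - cm
    b = target - ct
    h = (a * w).T @ b
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    # collinearity check: two near-zero singular values leave the rotation
    # about the point line undetermined
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; superposition is degenerate")
    trans = ct - rot @ cm
    moved = a @ rot.T
    rmsd = float(np.sqrt((((moved - b) ** 2).sum(axis=1) * w[:, 0]).sum()))
    return RigidTransform(rot, trans), rmsd


def chain_letters(n: int) -> list[str]:
    """Chain identifiers A, B, C, ... for an n-protomer assembly."""
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    if n > len(alphabet):
        raise ValueError(f"cannot label more than {len(alphabet)} chains")
    return list(alphabet[:n])
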