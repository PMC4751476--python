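"""Structure and observable-table input/output.

Multi-model PDB is the primary interchange format (one MODEL block per
conformer); a minimal XYZ reader/writer is provided for coordinate-only
workflows.  Tabular per-residue observables (J-couplings in Hz, chemical
shifts in ppm, secondary-structure propensities) travel as delimited text
with a ``residue`` index column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import Conformer, Ensemble, TopologyError

OBSERVABLE_KINDS = ("jcoupling", "shift", "propensity")


@dataclass
class ObservableTable:
    """Per-residue observable values keyed by 1-based residue index.

    ``values`` maps residue index to a float or ``None`` (explicitly
    missing).  ``kind`` is one of ``jcoupling`` (Hz), ``shift`` (ppm) or
    ``propensity`` (dimensionless); ``label`` records provenance (e.g. a
    nucleus name or an experiment tag).
    """

    values: dict[int, float | None]
    kind: str = "shift"
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in OBSERVABLE_KINDS:
            raise ValueError(f"unknown observable kind {self.kind!r}")
        for res, val in self.values.items():
            if val is not None and not math.isfinite(val):
                raise ValueError(f"non-finite value at residue {res}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def residues(self) -> list[int]:
        return sorted(self.values)

    def missing(self) -> list[int]:
        return sorted(r for r, v in self.values.items() if v is None)

    def present(self) -> dict[int, float]:
        return {r: v for r, v in self.values.items() if v is not None}

    def to_series(self) -> pd.Series:
        s = pd.Series({r: (np.nan if v is None else v)
                       for r, v in sorted(self.values.items())}, dtype=float)
        s.index.name = "residue"
        return s


def _ensemble_to_stack(ensemble: Ensemble) -> struc.AtomArrayStack:
    ref = ensemble[0]
    n = ref.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = ref.coords.astype(np.float32)
    arr.atom_name = ref.atom_names
    arr.element = ref.elements
    arr.res_id = ref.resids
    arr.res_name = ref.resnames
    arr.chain_id = ref.chain_ids
    arr.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([arr] * len(ensemble))
    stack.coord = ensemble.coords_array().astype(np.float32)
    return stack


def _stack_to_ensemble(stack: struc.AtomArrayStack) -> Ensemble:
    conformers = []
    for i in range(stack.stack_depth()):
        arr = stack[i]
        conformers.append(Conformer(
            coords=np.asarray(arr.coord, dtype=float),
            atom_names=arr.atom_name,
            elements=arr.element,
            resids=arr.res_id,
            resnames=arr.res_name,
            chain_ids=arr.chain_id,
        ))
    return Ensemble(conformers)


def read_structures(path: str | Path, format: str | None = None) -> Ensemble:
    """Read a multi-model PDB or XYZ file into an :class:`Ensemble`.

    One conformer is produced per MODEL record (PDB) or per frame (XYZ);
    atom order is preserved and coordinates are in Å.  ``format`` defaults
    to the file suffix.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        pdb = PDBFile.read(str(path))
        try:
            stack = pdb.get_structure()
        except Exception as exc:  # biotite raises on ragged models
            raise TopologyError(
                f"{path}: inconsistent models or malformed records: {exc}"
            ) from exc
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        if stack.stack_depth() == 0 or stack.array_length() == 0:
            raise ValueError(f"{path}: no atoms found")
        return _stack_to_ensemble(stack)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def write_structures(ensemble: Ensemble, path: str | Path,
                     format: str | None = None) -> Path:
    """Write an ensemble as multi-model PDB (MODEL/ENDMDL) or XYZ."""
    if len(ensemble) == 0:
        raise ValueError("cannot write an empty ensemble")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        pdb = PDBFile()
        pdb.set_structure(_ensemble_to_stack(ensemble))
        pdb.write(str(path))
        if len(ensemble) == 1:
            # keep MODEL/ENDMDL framing even for a single conformer
            body = path.read_text()
            if not body.lstrip().startswith("MODEL"):
                path.write_text(f"MODEL        1\n{body}ENDMDL\n")
    elif fmt == "xyz":
        _write_xyz(ensemble, path)
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")
    return path


def _read_xyz(path: Path) -> Ensemble:
    """Plain XYZ: frames of ``count / comment / element x y z`` lines.

    XYZ carries no residue metadata; atoms are placed in a single UNK
    residue on chain A, so XYZ ensembles suit coordinate-only analyses.
    """
    conformers = []
    lines = path.read_text().splitlines()
    i, n_prev = 0, None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{i + 1}: truncated frame")
        elements, coords = [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + j}: malformed atom line")
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if n_prev is not None and n != n_prev:
            raise TopologyError(f"{path}: frame atom counts differ")
        n_prev = n
        conformers.append(Conformer(
            coords=np.array(coords),
            atom_names=np.array(elements, dtype="U6"),
            elements=np.array(elements, dtype="U2"),
            resids=np.ones(n, dtype=int),
            resnames=np.full(n, "UNK"),
            chain_ids=np.full(n, "A"),
        ))
        i += 2 + n
    if not conformers:
        raise ValueError(f"{path}: no frames found")
    return Ensemble(conformers)


def _write_xyz(ensemble: Ensemble, path: Path) -> None:
    with open(path, "w") as fh:
        for k, c in enumerate(ensemble):
            fh.write(f"{c.n_atoms}\nframe {k + 1}\n")
            for el, xyz in zip(c.elements, c.coords):
                fh.write(f"{el or 'X':<3s} {xyz[0]:12.6f} {xyz[1]:12.6f} "
                         f"{xyz[2]:12.6f}\n")


def read_observables(path: str | Path, kind: str = "shift",
                     label: str = "") -> ObservableTable:
    """Read a delimited ``residue<TAB>value`` table.

    Empty value cells are preserved as explicitly missing entries.
    Duplicate residue indices are a validation error.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "residue" not in cols:
        raise ValueError(f"{path}: missing 'residue' column")
    value_col = cols.get("value")
    if value_col is None:
        others = [c for c in df.columns if c != cols["residue"]]
        if not others:
            raise ValueError(f"{path}: missing value column")
        value_col = others[0]
    resid = df[cols["residue"]].astype(int)
    if resid.duplicated().any():
        dupes = sorted(resid[resid.duplicated()].unique())
        raise ValueError(f"{path}: duplicate residue indices {dupes}")
    values: dict[int, float | None] = {}
    for r, v in zip(resid, pd.to_numeric(df[value_col], errors="coerce")):
        values[int(r)] = None if pd.isna(v) else float(v)
    return ObservableTable(values, kind=kind, label=label or str(value_col))


def write_observables(table: ObservableTable, path: str | Path) -> Path:
    """Write an observable table as TSV (missing values as empty cells)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("residue\tvalue\n")
        for r in table.residues:
            v = table.values[r]
            fh.write(f"{r}\t{'' if v is None else repr(v)}\n")
    return path


def read_coil_reference(path: str | Path, nucleus: str = "CA") -> ObservableTable:
    """Read a random-coil shift reference (residue-name keyed) table.

    Returns a table keyed by residue *name* lookups deferred to
    :func:`coil_table_for_sequence`; here the raw per-residue-type values.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if nucleus not in df.columns:
        raise ValueError(f"no column {nucleus!r} in coil reference")
    mapping = {str(row["residue"]).upper(): row[nucleus]
               for _, row in df.iterrows()}
    return mapping


def coil_table_for_sequence(resnames: list[str], nucleus: str = "CA",
                            reference: dict[str, float] | None = None,
                            ) -> ObservableTable:
    """Random-coil shift per residue of a concrete sequence.

    ``resnames`` is the 3-letter sequence in residue order (index 1-based).
    Residue types absent from the reference (e.g. Gly CB) become missing.
    """
    if reference is None:
        from .params import load_coil_reference
        reference = load_coil_reference(nucleus)
    values: dict[int, float | None] = {}
    for i, name in enumerate(resnames, start=1):
        v = reference.get(name.upper())
        values[i] = None if v is None or pd.isna(v) else float(v)
    return ObservableTable(values, kind="shift", label=f"coil_{nucleus}")
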