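"""Loaders for packaged parameter tables (Karplus coefficients, random-coil
shifts, coarse-grained bead parameters, ideal backbone geometry)."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml


def _data_path(name: str):
    return resources.files("paranuclei.data").joinpath(name)


@dataclass(frozen=True)
class KarplusParameters:
    """Coefficients of J(φ) = A cos²(φ−offset) + B cos(φ−offset) + C (Hz)."""

    A: float
    B: float
    C: float
    offset_deg: float = 60.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("Karplus A coefficient must be positive")

    def analytic_range(self) -> tuple[float, float]:
        """Exact (min, max) of the Karplus curve over all φ.

        With u = cos(φ−offset) ∈ [−1, 1] the curve is the parabola
        A u² + B u + C; extrema lie at u = ±1 and, when inside the
        interval, at the vertex u = −B/(2A).
        """
        candidates = [self.A + self.B + self.C, self.A - self.B + self.C]
        vertex = -self.B / (2.0 * self.A)
        if -1.0 <= vertex <= 1.0:
            candidates.append(self.C - self.B ** 2 / (4.0 * self.A))
        return min(candidates), max(candidates)


@lru_cache(maxsize=None)
def load_karplus(name: str | None = None) -> KarplusParameters:
    """Load a named Karplus parameter set (default per the data file)."""
    with _data_path("karplus.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    key = name or cfg["default"]
    entry = cfg[key]
    return KarplusParameters(A=float(entry["A"]), B=float(entry["B"]),
                             C=float(entry["C"]),
                             offset_deg=float(entry["offset_deg"]))


@lru_cache(maxsize=None)
def load_coil_reference(nucleus: str = "CA") -> dict[str, float]:
    """Random-coil chemical shifts (ppm) keyed by 3-letter residue name."""
    with _data_path("coil_shifts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    if nucleus not in df.columns:
        raise ValueError(f"no coil reference for nucleus {nucleus!r}")
    out = {}
    for _, row in df.iterrows():
        v = row[nucleus]
        if pd.notna(v):
            out[str(row["residue"]).upper()] = float(v)
    return out


@lru_cache(maxsize=None)
def load_cg_params() -> dict:
    """Bead radii/charges and energy-model constants for the CG force field."""
    with _data_path("cg_params.yaml").open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def load_ideal_geometry() -> dict:
    """Ideal backbone bond lengths (Å), angles and fixed torsions (deg)."""
    with _data_path("geometry.yaml").open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def load_abeta42_sequence() -> str:
    """The 42-residue amyloid-beta sequence (1-letter) from packaged FASTA."""
    text = _data_path("abeta42.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines()
                   if line and not line.startswith(">"))
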