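import numpy as np
import pytest

from paranuclei.core import Conformer, Ensemble
from paranuclei.synthetic import build_backbone, random_point_conformer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tripeptide():
    """Small extended peptide with side chains of distinct charge."""
    phi_psi = np.column_stack([np.full(3, -120.0), np.full(3, 130.0)])
    return build_backbone("DKG", phi_psi)


@pytest.fixture
def helical_peptide():
    phi_psi = np.column_stack([np.full(12, -57.0), np.full(12, -47.0)])
    return build_backbone("A" * 12, phi_psi)


@pytest.fixture
def point_body(rng):
    """A 25-point rigid toy body for geometry tests."""
    return random_point_conformer(25, rng)


def toy_conformer(coords, atom_name="CA"):
    """Wrap bare coordinates as a one-chain pseudo-CA conformer."""
    coords = np.asarray(coords, float)
    n = len(coords)
    return Conformer(coords,
                     np.full(n, atom_name, dtype="U6"),
                     np.full(n, "C", dtype="U2"),
                     np.arange(1, n + 1),
                     np.full(n, "GLY", dtype="U4"),
                     np.full(n, "A", dtype="U2"))


def toy_ensemble(frames):
    return Ensemble([toy_conformer(f) for f in frames])
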