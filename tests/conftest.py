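"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from cblpocket import synthetic
from cblpocket.structure_io import Structure, read_structure

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


def deposited_structure(pdb_id: str) -> Structure:
    """Load deposited coordinates from data/structures/<id>.{cif,pdb}.

    The regression tests against published crystal structures need the
    deposited files on disk; they are not bundled with the repository.
    """
    for ext in (".cif", ".pdb"):
        path = DATA_DIR / "structures" / f"{pdb_id.upper()}{ext}"
        if path.exists():
            return read_structure(path)
    raise FileNotFoundError(
        f"deposited coordinates for {pdb_id} not found; download {pdb_id}.cif "
        f"into {DATA_DIR / 'structures'} to run this regression"
    )


def deposited_sequences() -> dict[str, str]:
    """Transporter sequences from data/sequences/tc_sequences.fasta
    (UniProt: rat Q9R0D6, human P20062, bovine Q9XSC9)."""
    from cblpocket.sequence_conservation import read_fasta

    path = DATA_DIR / "sequences" / "tc_sequences.fasta"
    if not path.exists():
        raise FileNotFoundError(
            f"transporter sequences not found; place tc_sequences.fasta in {path.parent}"
        )
    return read_fasta(path)


@pytest.fixture(scope="session")
def pocket() -> Structure:
    return synthetic.make_pocket(seed=0)


@pytest.fixture(scope="session")
def blocked_pocket() -> Structure:
    return synthetic.make_pocket(block_offset=1.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
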