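"""Optimal rigid-body superposition (Kabsch) and Cα RMSD profiles.

The Kabsch solution is computed from the SVD of the coordinate
cross-covariance, with the reflection corrected to a proper rotation
(det = +1) by flipping the sign of the smallest singular vector — mirror
superpositions are chemically meaningless for protein comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AtomRecord, Structure

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "GeometryError",
    "kabsch",
    "pair_by_alignment",
    "domain_superpose",
]


class GeometryError(ValueError):
    """Degenerate or incompatible geometry for superposition."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R x + t (rotation R orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ np.asarray(self.rotation).T + np.asarray(
            self.translation
        )

    def inverse(self) -> "RigidTransform":
        R = np.asarray(self.rotation)
        return RigidTransform(R.T, -(R.T @ np.asarray(self.translation)))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    per_pair_deviation: np.ndarray


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Parameters are N×3 coordinate arrays of equal length, N ≥ 3, not
    collinear. Returns the minimising proper transform, the RMSD after
    applying it, and per-pair deviations.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape != ref.shape:
        raise GeometryError(f"expected matching N×3 arrays, got {mob.shape} and {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")

    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    P = mob - mob_c
    Q = ref - ref_c
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise GeometryError("mobile points are collinear")

    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c

    transform = RigidTransform(R, t)
    moved = transform.apply(mob)
    dev = np.linalg.norm(moved - ref, axis=1)
    rmsd = float(np.sqrt(np.mean(dev**2)))
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_pairs=n, per_pair_deviation=dev)


def _ca_by_residue(chain_atoms: Structure | list[AtomRecord]) -> dict[int, AtomRecord]:
    atoms = chain_atoms.atoms if isinstance(chain_atoms, Structure) else chain_atoms
    out: dict[int, AtomRecord] = {}
    for a in atoms:
        if a.name == "CA" and a.element.upper() == "C" and a.res_seq not in out:
            out[a.res_seq] = a
    return out


def pair_by_alignment(
    a: Structure,
    b: Structure,
    alignment: list[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Paired Cα coordinate arrays following a residue-pair alignment.

    ``alignment`` lists (res_seq in a, res_seq in b); pairs where either Cα
    is missing are dropped, order follows the alignment.
    """
    ca_a = _ca_by_residue(a)
    ca_b = _ca_by_residue(b)
    pa, pb = [], []
    for ra, rb in alignment:
        if ra in ca_a and rb in ca_b:
            pa.append(ca_a[ra].coord)
            pb.append(ca_b[rb].coord)
    if not pa:
        raise GeometryError("alignment produced no Cα pairs")
    return np.array(pa), np.array(pb)


def domain_superpose(
    a: Structure,
    b: Structure,
    domain_range: tuple[int, int],
    report_range: tuple[int, int],
    alignment: list[tuple[int, int]] | None = None,
) -> dict:
    """Superpose on one residue interval, report deviations over another.

    Fits the Kabsch transform on Cα pairs inside ``domain_range``, applies it
    to ``a``, and reports per-residue Cα deviations over ``report_range``.
    With no explicit alignment, residues are paired by identical numbering.
    """
    ca_a = _ca_by_residue(a)
    ca_b = _ca_by_residue(b)
    if alignment is None:
        alignment = [(r, r) for r in sorted(set(ca_a) & set(ca_b))]

    fit_pairs = [(ra, rb) for ra, rb in alignment
                 if domain_range[0] <= rb <= domain_range[1] and ra in ca_a and rb in ca_b]
    rep_pairs = [(ra, rb) for ra, rb in alignment
                 if report_range[0] <= rb <= report_range[1] and ra in ca_a and rb in ca_b]
    if not fit_pairs or not rep_pairs:
        raise GeometryError("empty residue overlap for fit or report range")

    fit_a = np.array([ca_a[ra].coord for ra, _ in fit_pairs])
    fit_b = np.array([ca_b[rb].coord for _, rb in fit_pairs])
    sup = kabsch(fit_a, fit_b)

    rep_a = np.array([ca_a[ra].coord for ra, _ in rep_pairs])
    rep_b = np.array([ca_b[rb].coord for _, rb in rep_pairs])
    dev = np.linalg.norm(sup.transform.apply(rep_a) - rep_b, axis=1)
    return {
        "transform": sup.transform,
        "fit_rmsd": sup.rmsd,
        "residues": [rb for _, rb in rep_pairs],
        "deviations": dev,
        "max_deviation": float(dev.max()),
    }
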