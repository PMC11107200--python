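"""Corrin butterfly fold angle and axial coordination geometry.

The corrin macrocycle of cobalamin flexes like a butterfly about the axis
through cobalt and the C10 meso carbon. The fold angle is the angle between
the total-least-squares planes of the two half-rings — plane A through
N21, C4, C5, C6, N22, C9, C10 and plane B through C10, C11, N23, C14, C15,
C16, N24 (C10 shared) — folded into [0°, 90°]. Axial geometry reports the
Co–DMB-nitrogen (α, lower face) and Co–β-ligand bond lengths and calls the
base-on/base-off state from the α distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import (
    FOLD_SET_A,
    FOLD_SET_B,
    CorrinAtomSet,
    Structure,
    extract_corrin,
)
from .superposition import GeometryError

__all__ = ["CorrinReport", "fit_plane", "corrin_fold_angle", "axial_geometry", "corrin_report"]

#: α-axial distance at or below which the DMB base is considered coordinated.
BASE_ON_CUTOFF = 2.5
#: search radius for a β-axial coordinating atom.
BETA_CUTOFF = 3.0


@dataclass
class CorrinReport:
    """Geometry summary for one cobalamin instance."""

    fold_angle: float                   # degrees, in [0, 90]
    co_alpha_dist: float | None         # Å, Co to DMB nitrogen
    co_beta_dist: float | None          # Å, Co to β-axial atom
    beta_ligand_identity: str           # e.g. "GSH SG", "HIS193 NE2", "none"
    base_on: bool

    def to_dict(self) -> dict:
        return {
            "fold_angle_deg": self.fold_angle,
            "co_alpha_dist_A": self.co_alpha_dist,
            "co_beta_dist_A": self.co_beta_dist,
            "beta_ligand": self.beta_ligand_identity,
            "base_on": self.base_on,
        }


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through ``points`` (M×3, M ≥ 3).

    Returns (unit normal, centroid). The normal is the eigenvector of the
    coordinate covariance with the smallest eigenvalue; its sign is fixed to
    have a non-negative z component (callers needing the corrin local frame
    orient it along Co→β themselves).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError(f"plane fit needs M×3 with M ≥ 3, got {pts.shape}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[1] < 1e-10 * max(w[2], 1.0):
        raise GeometryError("points are collinear; plane undefined")
    normal = v[:, 0]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return normal, centroid


def corrin_fold_angle(corrin: CorrinAtomSet) -> float:
    """Butterfly angle (degrees) between the two half-ring planes."""
    atoms = corrin.fold_atoms()
    missing = [n for n in set(FOLD_SET_A + FOLD_SET_B) if n not in atoms]
    if missing:
        raise GeometryError(f"fold-angle atoms missing: {sorted(missing)}")
    plane_a = np.array([atoms[n].coord for n in FOLD_SET_A])
    plane_b = np.array([atoms[n].coord for n in FOLD_SET_B])
    na, _ = fit_plane(plane_a)
    nb, _ = fit_plane(plane_b)
    cosang = abs(float(np.dot(na, nb)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return min(angle, 180.0 - angle)


def axial_geometry(corrin: CorrinAtomSet) -> CorrinReport:
    """Axial bond lengths, β-ligand identity and base-on call, plus fold angle."""
    co = corrin.co.coord
    if corrin.dmb_n is not None:
        alpha = float(np.linalg.norm(corrin.dmb_n.coord - co))
    else:
        alpha = None
    if corrin.beta_ligand_atom is not None:
        b = corrin.beta_ligand_atom
        beta = float(np.linalg.norm(b.coord - co))
        identity = f"{b.res_name}{b.res_seq} {b.name}"
    else:
        beta = None
        identity = "none"
    return CorrinReport(
        fold_angle=corrin_fold_angle(corrin),
        co_alpha_dist=alpha,
        co_beta_dist=beta if (beta is not None and beta <= BETA_CUTOFF) else None,
        beta_ligand_identity=identity if (beta is not None and beta <= BETA_CUTOFF) else "none",
        base_on=bool(alpha is not None and alpha <= BASE_ON_CUTOFF),
    )


def corrin_report(structure: Structure) -> CorrinReport:
    """Convenience: extract the corrin from a structure and report its geometry."""
    return axial_geometry(extract_corrin(structure))
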