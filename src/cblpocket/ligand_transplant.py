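"""Ligand transplantation and steric-clash screening across transporters.

The glutathionyl moiety of a GSCbl complex is placed into another
cobalamin-transporter complex by superposing the corrin macrocycles
(Kabsch on the 13 butterfly atoms plus cobalt, matched by atom name) and
applying the resulting transform to the glutathione atoms only — the
target keeps its own cobalamin. A steric clash between transplanted atom i
and a target protein atom j is scored when

    d(i, j) < r_i + r_j − soft_tol,

with a soft tolerance absorbing van der Waals contact softness; overlaps
exceeding the severe tier indicate a pocket that cannot accommodate the
β-ligand without rearrangement. Waters and the target's own cobalamin are
excluded from the clash targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    DEFAULT_ELEMENT_TABLE,
    AtomRecord,
    ElementTable,
    Structure,
    extract_corrin,
)
from .superposition import GeometryError, RigidTransform, kabsch

__all__ = ["ClashReport", "transplant", "SOFT_TOL", "SEVERE_TOL"]

SOFT_TOL = 0.4    # Å subtracted from the vdW-sum before calling a clash
SEVERE_TOL = 0.6  # Å overlap at or above which a clash is flagged severe
MIN_FIT_ATOMS = 8
MAX_FIT_RMSD = 1.5  # Å; above this the corrin superposition is unreliable

#: atom names used to match the two corrins (fold set plus cobalt)
CORRIN_FIT_NAMES = (
    "CO", "N21", "C4", "C5", "C6", "N22", "C9", "C10",
    "C11", "N23", "C14", "C15", "C16", "N24",
)


@dataclass
class Clash:
    chain: str
    res_name: str
    res_seq: int
    atom: str
    ligand_atom: str
    overlap: float          # Å, positive
    severe: bool


@dataclass
class ClashReport:
    n_clashes: int
    worst_overlap: float
    clashes: list[Clash]
    transform: RigidTransform
    corrin_fit_rmsd: float
    n_fit_atoms: int
    transplanted: Structure = field(repr=False, default=None)

    @property
    def n_severe(self) -> int:
        return sum(c.severe for c in self.clashes)

    def to_dict(self) -> dict:
        return {
            "n_clashes": self.n_clashes,
            "n_severe": self.n_severe,
            "worst_overlap_A": self.worst_overlap,
            "corrin_fit_rmsd_A": self.corrin_fit_rmsd,
            "n_fit_atoms": self.n_fit_atoms,
            "clashes": [
                {
                    "chain": c.chain,
                    "residue": f"{c.res_name}{c.res_seq}",
                    "atom": c.atom,
                    "ligand_atom": c.ligand_atom,
                    "overlap_A": round(c.overlap, 3),
                    "severe": c.severe,
                }
                for c in self.clashes
            ],
        }


def _corrin_fit_coords(structure: Structure) -> tuple[dict[str, np.ndarray], object]:
    corrin = extract_corrin(structure)
    coords = {"CO": corrin.co.coord}
    for name, atom in corrin.fold_atoms().items():
        if name in CORRIN_FIT_NAMES:
            coords[name] = atom.coord
    return coords, corrin


def transplant(
    source: Structure,
    target: Structure,
    soft_tol: float = SOFT_TOL,
    severe_tol: float = SEVERE_TOL,
    elements: ElementTable = DEFAULT_ELEMENT_TABLE,
) -> ClashReport:
    """Transplant the source's β-axial ligand into the target pocket.

    ``source`` must contain a cobalamin whose β-axial atom belongs to a
    separate component (the glutathione); ``target`` any cobalamin complex.
    Raises :class:`GeometryError` when fewer than 8 corrin atoms match by
    name or the corrin fit RMSD exceeds 1.5 Å.
    """
    src = source.reduce_altlocs()
    tgt = target.reduce_altlocs()

    src_coords, src_corrin = _corrin_fit_coords(src)
    tgt_coords, tgt_corrin = _corrin_fit_coords(tgt)

    if src_corrin.beta_ligand_atom is None:
        raise GeometryError("source cobalamin has no β-axial ligand to transplant")
    beta = src_corrin.beta_ligand_atom
    if beta.residue_id == src_corrin.co.residue_id:
        raise GeometryError("source β-axial atom belongs to the cobalamin itself; "
                            "no separate ligand component to transplant")

    common = [n for n in CORRIN_FIT_NAMES if n in src_coords and n in tgt_coords]
    if len(common) < MIN_FIT_ATOMS:
        raise GeometryError(
            f"only {len(common)} corrin atoms match by name (need ≥ {MIN_FIT_ATOMS})"
        )
    sup = kabsch(
        np.array([src_coords[n] for n in common]),
        np.array([tgt_coords[n] for n in common]),
    )
    if sup.rmsd > MAX_FIT_RMSD:
        raise GeometryError(
            f"corrin superposition unreliable: rmsd {sup.rmsd:.2f} Å > {MAX_FIT_RMSD} Å"
        )

    gsh = src.select(lambda a, rid=beta.residue_id: a.residue_id == rid)
    moved = gsh.transformed(sup.transform.rotation, sup.transform.translation)

    # clash targets: target heavy atoms minus waters and its own cobalamin
    excluded = {tgt_corrin.co.residue_id}
    if tgt_corrin.dmb_n is not None:
        excluded.add(tgt_corrin.dmb_n.residue_id)
    if tgt_corrin.beta_ligand_atom is not None:
        excluded.add(tgt_corrin.beta_ligand_atom.residue_id)
    pocket = [
        a for a in tgt.atoms
        if not a.is_water() and not a.is_hydrogen() and a.residue_id not in excluded
    ]

    clashes: list[Clash] = []
    for la in moved.atoms:
        if la.is_hydrogen():
            continue
        r_l = elements.radius(la.element)
        for pa in pocket:
            d = float(np.linalg.norm(la.coord - pa.coord))
            overlap = r_l + elements.radius(pa.element) - soft_tol - d
            if overlap > 0:
                clashes.append(
                    Clash(
                        chain=pa.chain,
                        res_name=pa.res_name,
                        res_seq=pa.res_seq,
                        atom=pa.name,
                        ligand_atom=la.name,
                        overlap=overlap,
                        severe=overlap >= (severe_tol - soft_tol),
                    )
                )
    clashes.sort(key=lambda c: -c.overlap)
    return ClashReport(
        n_clashes=len(clashes),
        worst_overlap=clashes[0].overlap if clashes else 0.0,
        clashes=clashes,
        transform=sup.transform,
        corrin_fit_rmsd=sup.rmsd,
        n_fit_atoms=len(common),
        transplanted=moved,
    )
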