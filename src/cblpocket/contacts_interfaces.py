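"""Polar contacts, disulfides, and SASA-based buried interface areas.

Solvent-accessible surface area follows Shrake–Rupley: each heavy atom is
covered with a deterministic quasi-uniform point set (golden-spiral lattice)
on the sphere of radius r_vdW + probe, and the accessible fraction is the
fraction of points not buried inside any neighbouring sphere. The buried
area between two disjoint components is half the SASA lost on association,

    buried(A, B) = (SASA(A) + SASA(B) − SASA(A ∪ B)) / 2,

the same construction interface servers use, computed here without solvent.

Polar-contact fingerprinting is distance-based: a direct contact is an N/O
atom of the ligand within the cutoff of an N/O atom of the protein; a
water bridge is a water oxygen within the cutoff of both. No angular term
is applied by default, matching how dashed-bond contact counts are usually
drawn in structure figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    DEFAULT_ELEMENT_TABLE,
    AtomRecord,
    ElementTable,
    Structure,
)

__all__ = [
    "PolarContact",
    "InterfaceReport",
    "sasa",
    "total_sasa",
    "buried_area",
    "polar_contacts",
    "find_disulfides",
    "helix_dipole_contact",
    "interface_report",
]

POLAR_CUTOFF = 3.5     # Å donor–acceptor distance
SS_CUTOFF = 2.5        # Å Sγ–Sγ
PROBE_RADIUS = 1.4     # Å water probe
N_SPHERE_POINTS = 960


@dataclass(frozen=True)
class PolarContact:
    """One polar interaction between a ligand atom and a protein atom."""

    ligand_atom: tuple[str, str, int, str]    # (chain, res_name, res_seq, atom name)
    protein_atom: tuple[str, str, int, str]
    distance: float                            # Å; for bridges the longer leg
    kind: str                                  # "direct" | "water_bridge"
    water: tuple[str, int] | None = None       # (chain, res_seq) of bridging water

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "water_bridge"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.kind == "water_bridge" and self.water is None:
            raise ValueError("water_bridge contact requires a bridging water id")


@dataclass
class InterfaceReport:
    """Pairwise buried areas between labelled components and their ranking."""

    buried: dict[tuple[str, str], float]       # Å² per unordered pair
    component_sasa: dict[str, float]           # Å² isolated-component SASA
    ranking: list[tuple[str, str]]             # pairs by descending buried area

    def to_dict(self) -> dict:
        return {
            "buried_A2": {f"{a}/{b}": v for (a, b), v in self.buried.items()},
            "component_sasa_A2": dict(self.component_sasa),
            "ranking": [f"{a}/{b}" for a, b in self.ranking],
        }


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    atoms: Structure | list[AtomRecord],
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    elements: ElementTable = DEFAULT_ELEMENT_TABLE,
) -> np.ndarray:
    """Per-atom Shrake–Rupley solvent-accessible areas (Å²).

    Hydrogens contribute no area and do not occlude (united-atom model).
    The returned array is aligned with the input heavy-atom order filtered
    in place: hydrogens get 0.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100 for usable quadrature")
    atom_list = atoms.atoms if isinstance(atoms, Structure) else list(atoms)
    areas = np.zeros(len(atom_list))
    heavy_idx = [i for i, a in enumerate(atom_list) if not a.is_hydrogen()]
    if not heavy_idx:
        return areas

    coords = np.array([atom_list[i].coord for i in heavy_idx])
    radii = np.array([elements.radius(atom_list[i].element) for i in heavy_idx]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()

    for k in range(len(heavy_idx)):
        pts = coords[k] + radii[k] * unit
        neighbors = [j for j in tree.query_ball_point(coords[k], radii[k] + max_r) if j != k]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        areas[heavy_idx[k]] = 4.0 * np.pi * radii[k] ** 2 * accessible.mean()
    return areas


def total_sasa(atoms, **kwargs) -> float:
    """Total SASA (Å²) of an atom set."""
    return float(sasa(atoms, **kwargs).sum())


def buried_area(
    a: Structure | list[AtomRecord],
    b: Structure | list[AtomRecord],
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    elements: ElementTable = DEFAULT_ELEMENT_TABLE,
) -> float:
    """Buried interface area (Å²) between two disjoint atom sets."""
    la = a.atoms if isinstance(a, Structure) else list(a)
    lb = b.atoms if isinstance(b, Structure) else list(b)
    keys_a = {(x.chain, x.res_seq, x.icode, x.name, x.altloc) for x in la}
    keys_b = {(x.chain, x.res_seq, x.icode, x.name, x.altloc) for x in lb}
    if keys_a & keys_b:
        raise ValueError("components share atoms; buried area requires disjoint sets")
    kw = dict(probe=probe, n_points=n_points, elements=elements)
    sa = total_sasa(la, **kw)
    sb = total_sasa(lb, **kw)
    # canonical union order makes buried_area(a, b) == buried_area(b, a) exact
    union = sorted(la + lb, key=lambda x: (x.chain, x.res_seq, x.icode, x.name, x.altloc))
    sab = total_sasa(union, **kw)
    return (sa + sb - sab) / 2.0


def polar_contacts(
    ligand: Structure | list[AtomRecord],
    protein: Structure | list[AtomRecord],
    waters: Structure | list[AtomRecord] | None = None,
    cutoff: float = POLAR_CUTOFF,
    elements: ElementTable = DEFAULT_ELEMENT_TABLE,
) -> list[PolarContact]:
    """Direct and water-mediated polar contacts between ligand and protein.

    Each (ligand atom, protein atom) pair is reported once as direct if
    within ``cutoff``; each (ligand atom, water, protein atom) triple once as
    a bridge when the water oxygen is within ``cutoff`` of both. A pair in
    direct contact is not additionally counted through a water.
    """
    lig = [a for a in (ligand.atoms if isinstance(ligand, Structure) else ligand)
           if elements.is_polar(a)]
    prot = [a for a in (protein.atoms if isinstance(protein, Structure) else protein)
            if elements.is_polar(a)]
    wat = [a for a in ((waters.atoms if isinstance(waters, Structure) else waters) or [])
           if a.element.upper() == "O"]

    contacts: list[PolarContact] = []
    direct_pairs: set[tuple] = set()

    def key(a: AtomRecord) -> tuple[str, str, int, str]:
        return (a.chain, a.res_name, a.res_seq, a.name)

    for la in lig:
        for pa in prot:
            d = float(np.linalg.norm(la.coord - pa.coord))
            if d <= cutoff:
                contacts.append(PolarContact(key(la), key(pa), d, "direct"))
                direct_pairs.add((key(la), key(pa)))

    for w in wat:
        near_lig = [(la, float(np.linalg.norm(la.coord - w.coord))) for la in lig]
        near_lig = [(la, d) for la, d in near_lig if d <= cutoff]
        if not near_lig:
            continue
        near_prot = [(pa, float(np.linalg.norm(pa.coord - w.coord))) for pa in prot]
        near_prot = [(pa, d) for pa, d in near_prot if d <= cutoff]
        for la, dl in near_lig:
            for pa, dp in near_prot:
                if (key(la), key(pa)) in direct_pairs:
                    continue
                contacts.append(
                    PolarContact(key(la), key(pa), max(dl, dp), "water_bridge",
                                 water=(w.chain, w.res_seq))
                )
    return contacts


def find_disulfides(structure: Structure, max_ss: float = SS_CUTOFF) -> list[tuple]:
    """Cys–Cys disulfide pairs: Sγ atoms within ``max_ss`` Å, paired greedily
    by ascending distance so that no cysteine appears twice.

    Returns [((chain, res_seq), (chain, res_seq), distance Å), ...] with the
    lower residue first in each pair, sorted by first residue.
    """
    st = structure.reduce_altlocs()
    sg = [a for a in st.atoms if a.res_name == "CYS" and a.name == "SG"]
    candidates = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            d = float(np.linalg.norm(sg[i].coord - sg[j].coord))
            if d <= max_ss:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    pairs = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = sg[i], sg[j]
        ra, rb = (a.chain, a.res_seq), (b.chain, b.res_seq)
        if rb < ra:
            ra, rb = rb, ra
        pairs.append((ra, rb, d))
    return sorted(pairs)


def helix_dipole_contact(
    carboxylate: Structure | list[AtomRecord],
    helix_n_terminal: Structure | list[AtomRecord],
    cutoff: float = POLAR_CUTOFF,
) -> tuple[bool, float]:
    """Whether a carboxylate caps a helix N terminus (dipole interaction).

    True iff any carboxylate oxygen lies within ``cutoff`` of a backbone
    amide nitrogen of the helix's first residues. Returns (flag, min dist).
    """
    ox = [a for a in (carboxylate.atoms if isinstance(carboxylate, Structure) else carboxylate)
          if a.element.upper() == "O"]
    if not ox:
        raise ValueError("carboxylate selection contains no oxygen atoms")
    amide_n = [a for a in (helix_n_terminal.atoms if isinstance(helix_n_terminal, Structure)
                           else helix_n_terminal)
               if a.name == "N" and a.element.upper() == "N"]
    if not amide_n:
        return False, float("inf")
    dmin = min(float(np.linalg.norm(o.coord - n.coord)) for o in ox for n in amide_n)
    return dmin <= cutoff, dmin


def interface_report(
    components: dict[str, Structure | list[AtomRecord]],
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    elements: ElementTable = DEFAULT_ELEMENT_TABLE,
) -> InterfaceReport:
    """Pairwise buried areas between labelled components, ranked descending.

    Components are typically the ligand and the two protein domains; waters
    should be excluded from the partition beforehand (interface areas are
    computed solvent-free).
    """
    labels = list(components)
    kw = dict(probe=probe, n_points=n_points, elements=elements)
    comp_sasa = {lab: total_sasa(components[lab], **kw) for lab in labels}
    buried: dict[tuple[str, str], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            buried[(a, b)] = buried_area(components[a], components[b], **kw)
    ranking = sorted(buried, key=lambda p: buried[p], reverse=True)
    return InterfaceReport(buried=buried, component_sasa=comp_sasa, ranking=ranking)
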