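"""Macromolecular structure I/O and the uniform atom model.

Structures are read from PDB or mmCIF files (via gemmi) into a flat,
ordered list of :class:`AtomRecord`. All ATOM/HETATM records are kept,
including waters, alternate locations and insertion codes; hydrogens are
retained in the model but ignored by the surface-area and clash routines
(united-atom radii).

Cobalamin cofactors are located chemically — a cobalt equatorially
coordinated by four nitrogens — rather than by the three-letter component
code, because hydroxo-, glutathionyl- and cyano-cobalamin are deposited
under different codes in different entries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "ElementTable",
    "DEFAULT_ELEMENT_TABLE",
    "CorrinAtomSet",
    "read_structure",
    "write_pdb",
    "parse_selection",
    "extract_corrin",
    "AmbiguousCorrinError",
    "SelectionError",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: The 13 atoms of the butterfly definition: two half-ring planes sharing C10.
FOLD_SET_A = ("N21", "C4", "C5", "C6", "N22", "C9", "C10")
FOLD_SET_B = ("C10", "C11", "N23", "C14", "C15", "C16", "N24")
EQUATORIAL_N = ("N21", "N22", "N23", "N24")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, PDB conventions, coordinates in Å."""

    serial: int
    name: str
    altloc: str
    res_name: str
    chain: str
    res_seq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    element: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1] for {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, res_seq, icode) — identifies the residue this atom belongs to."""
        return (self.chain, self.res_seq, self.icode)

    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Structure:
    """Ordered atom container with a flat list of :class:`AtomRecord`."""

    atoms: list[AtomRecord]
    id: str = ""
    dialect: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain, a.res_seq, a.icode, a.name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom key {key} in structure {self.id!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """N×3 coordinate array in atom order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def select(self, predicate: str | Callable[[AtomRecord], bool]) -> "Structure":
        """Order-preserving atom subset; ``predicate`` is a selection
        expression string (see :func:`parse_selection`) or a callable."""
        if isinstance(predicate, str):
            predicate = parse_selection(predicate)
        return Structure([a for a in self.atoms if predicate(a)], id=self.id, dialect=self.dialect)

    def reduce_altlocs(self) -> "Structure":
        """Keep one conformer per (chain, res_seq, icode, name): the highest
        occupancy, ties broken by altloc identifier order."""
        best: dict[tuple, AtomRecord] = {}
        order: list[tuple] = []
        for a in self.atoms:
            key = (a.chain, a.res_seq, a.icode, a.name)
            if key not in best:
                best[key] = a
                order.append(key)
            else:
                b = best[key]
                if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                    best[key] = a
        atoms = [replace(best[k], altloc="") for k in order]
        return Structure(atoms, id=self.id, dialect=self.dialect)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy: x ↦ R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new = []
        for a in self.atoms:
            v = R @ a.coord + t
            new.append(replace(a, x=float(v[0]), y=float(v[1]), z=float(v[2])))
        return Structure(new, id=self.id, dialect=self.dialect)

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Atoms grouped by (chain, res_seq, icode), insertion order preserved."""
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out


def _altloc_rank(altloc: str) -> float:
    # empty altloc sorts above any letter; otherwise reverse-alphabetical so
    # that 'A' beats 'B' when occupancies tie
    return np.inf if altloc == "" else -ord(altloc)


# ---------------------------------------------------------------------------
# element radii and polar classification

class ElementTable:
    """Van der Waals radii (Å) per element and polar-atom classification.

    The default radii are a standard united-atom set; cobalt uses its
    ionic/metallic radius since only clash and coordination geometry, not
    electronic structure, is modelled. Radii can be overridden per element
    (e.g. from a YAML config).
    """

    DEFAULT_RADII = {
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "S": 1.80,
        "P": 1.80,
        "CO": 1.26,
        "H": 1.09,
        "D": 1.09,
    }
    FALLBACK_RADIUS = 1.70

    def __init__(self, radii: dict[str, float] | None = None, fallback: float | None = None):
        self.radii = dict(self.DEFAULT_RADII)
        if radii:
            for el, r in radii.items():
                if r <= 0:
                    raise ValueError(f"non-positive radius {r} for element {el}")
                self.radii[el.upper()] = float(r)
        self.fallback = float(fallback) if fallback is not None else self.FALLBACK_RADIUS
        if self.fallback <= 0:
            raise ValueError("fallback radius must be positive")

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.fallback)

    @staticmethod
    def is_polar(atom: AtomRecord) -> bool:
        """Hydrogen-bond capable heavy atom: any nitrogen or oxygen.

        Distance-based polar-contact fingerprinting treats every N/O as a
        potential donor or acceptor; sulfur is excluded by default (thioether
        and metal-bonded sulfurs dominate in this system).
        """
        return atom.element.upper() in ("N", "O")


DEFAULT_ELEMENT_TABLE = ElementTable()


# ---------------------------------------------------------------------------
# reading and writing

def read_structure(path: str | Path, dialect: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM records are retained, waters included; insertion codes
    and alternate locations are preserved as deposited.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise IOError(f"structure file not found: {path}")
    if dialect not in ("pdb", "mmcif", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}; expected pdb, mmcif or auto")

    if dialect == "pdb":
        st = gemmi.read_pdb(str(path))
        used = "pdb"
    elif dialect == "mmcif":
        st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        used = "mmcif"
    else:
        st = gemmi.read_structure(str(path))
        used = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"

    st.setup_entities()
    atoms: list[AtomRecord] = []
    serial = 0
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        altloc=atom.altloc if atom.altloc else "",
                        res_name=res.name,
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                        element=atom.element.name,
                    )
                )
    return Structure(atoms, id=st.name or path.stem, dialect=used)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column PDB ATOM/HETATM records (coordinates to 3 decimals)."""
    std_aa = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
    lines = []
    for a in structure.atoms:
        record = "ATOM  " if a.res_name in std_aa else "HETATM"
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial % 100000:5d} {name:<4.4s}{a.altloc or ' ':1s}"
            f"{a.res_name:>3.3s} {a.chain[:1]:1s}{a.res_seq % 10000:4d}{a.icode or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element.upper():>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selection expressions

class SelectionError(ValueError):
    """Malformed selection expression."""


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {"chain", "resname", "resi", "name", "element", "water", "protein",
             "hetero", "all", "none", "and", "or", "not"}


def parse_selection(expr: str) -> Callable[[AtomRecord], bool]:
    """Compile a selection expression into a predicate.

    Grammar (infix, ``and`` binds tighter than ``or``)::

        chain A | resname HOH,GSH | resi 10-50 | resi 193 | name SG,CA
        element S | water | all | none | not <term> | ( ... )

    Examples: ``"chain A and resi 154-155 and name N"``, ``"not water"``.
    """
    tokens = _TOKEN_RE.findall(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise SelectionError(f"unexpected end of expression: {expr!r}")
        t = tokens[pos]
        pos += 1
        return t

    def parse_or():
        node = parse_and()
        while peek() is not None and peek().lower() == "or":
            take()
            rhs = parse_and()
            node = (lambda a, l=node, r=rhs: l(a) or r(a))
        return node

    def parse_and():
        node = parse_term()
        while peek() is not None and peek().lower() == "and":
            take()
            rhs = parse_term()
            node = (lambda a, l=node, r=rhs: l(a) and r(a))
        return node

    def parse_term():
        t = take()
        tl = t.lower()
        if t == "(":
            node = parse_or()
            if take() != ")":
                raise SelectionError(f"unbalanced parentheses in {expr!r}")
            return node
        if tl == "not":
            inner = parse_term()
            return lambda a, f=inner: not f(a)
        if tl == "all":
            return lambda a: True
        if tl == "none":
            return lambda a: False
        if tl == "water":
            return lambda a: a.is_water()
        if tl == "hetero":
            return lambda a: not _is_protein(a)
        if tl == "protein":
            return _is_protein
        if tl in ("chain", "resname", "name", "element"):
            arg = take()
            if arg.lower() in _KEYWORDS or arg in "()":
                raise SelectionError(f"keyword {tl!r} needs an argument in {expr!r}")
            values = {v.upper() for v in arg.split(",")}
            attr = {"chain": "chain", "resname": "res_name", "name": "name",
                    "element": "element"}[tl]
            return lambda a, attr=attr, values=values: getattr(a, attr).upper() in values
        if tl == "resi":
            arg = take()
            ranges = []
            for part in arg.split(","):
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", part)
                if not m:
                    raise SelectionError(f"bad residue range {part!r} in {expr!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                ranges.append((lo, hi))
            return lambda a, ranges=tuple(ranges): any(lo <= a.res_seq <= hi for lo, hi in ranges)
        raise SelectionError(f"unknown selection token {t!r} in {expr!r}")

    predicate = parse_or()
    if pos != len(tokens):
        raise SelectionError(f"trailing tokens {' '.join(tokens[pos:])!r} in {expr!r}")
    return predicate


_PROTEIN_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


def _is_protein(a: AtomRecord) -> bool:
    return a.res_name in _PROTEIN_RES


# ---------------------------------------------------------------------------
# corrin extraction

class AmbiguousCorrinError(ValueError):
    """Zero or several cobalt-corrin candidates; message lists them."""


@dataclass
class CorrinAtomSet:
    """The cobalamin atoms geometry works on, resolved by PDB atom name.

    ``dmb_n`` is the α-axial (lower face) dimethylbenzimidazole nitrogen
    coordinating cobalt; ``beta_ligand_atom`` is the upper-face coordinating
    atom (e.g. a glutathione Sγ or a histidine Nε2), or None when the β site
    is empty.
    """

    co: AtomRecord
    equatorial_n: dict[str, AtomRecord]          # keys N21..N24
    ring_carbons: dict[str, AtomRecord]          # keys C1..C19 as present
    dmb_n: AtomRecord | None
    beta_ligand_atom: AtomRecord | None

    def fold_atoms(self) -> dict[str, AtomRecord]:
        out = dict(self.equatorial_n)
        out.update(self.ring_carbons)
        return out

    def atom(self, name: str) -> AtomRecord:
        if name in self.equatorial_n:
            return self.equatorial_n[name]
        if name in self.ring_carbons:
            return self.ring_carbons[name]
        raise KeyError(name)


def extract_corrin(
    structure: Structure,
    coordination_cutoff: float = 2.5,
    beta_cutoff: float = 3.0,
) -> CorrinAtomSet:
    """Locate the (single) cobalt-corrin cofactor and resolve its atoms.

    Chemistry-based: a corrin candidate is a cobalt with at least four
    nitrogens within ``coordination_cutoff`` Å. The α-axial nitrogen is the
    non-equatorial coordinating N; the β-axial atom is the nearest
    non-corrin-ring heavy atom within ``beta_cutoff`` Å on the opposite face.
    """
    st = structure.reduce_altlocs()
    heavy = [a for a in st.atoms if not a.is_hydrogen()]
    cobalts = [a for a in heavy if a.element.upper() == "CO"]
    nitrogens = [a for a in heavy if a.element.upper() == "N"]

    candidates = []
    for co in cobalts:
        near_n = [n for n in nitrogens if np.linalg.norm(n.coord - co.coord) <= coordination_cutoff]
        if len(near_n) >= 4:
            candidates.append((co, near_n))
    if len(candidates) != 1:
        listing = ", ".join(f"{co.chain}/{co.res_name}{co.res_seq}" for co, _ in candidates)
        raise AmbiguousCorrinError(
            f"expected exactly one cobalt-corrin candidate, found {len(candidates)}"
            + (f": {listing}" if listing else "")
        )
    co, near_n = candidates[0]

    corrin_res = co.residue_id
    res_atoms = [a for a in heavy if a.residue_id == corrin_res]
    equatorial = {a.name: a for a in res_atoms if a.name in EQUATORIAL_N}
    if len(equatorial) < 4:
        # fall back to geometry: the four coordinating N closest to Co
        near_sorted = sorted(near_n, key=lambda n: np.linalg.norm(n.coord - co.coord))
        missing = [nm for nm in EQUATORIAL_N if nm not in equatorial]
        raise AmbiguousCorrinError(
            f"corrin residue {corrin_res} lacks equatorial nitrogens {missing} "
            f"(found {sorted(equatorial)} near Co with {len(near_sorted)} coordinating N)"
        )
    ring_carbons = {
        a.name: a
        for a in res_atoms
        if re.fullmatch(r"C(1?[0-9])", a.name) and 1 <= int(a.name[1:]) <= 19
    }

    # α-axial: coordinating nitrogen that is not one of N21..N24
    eq_ids = {id(a) for a in equatorial.values()}
    alpha = [n for n in near_n if id(n) not in eq_ids]
    dmb_n = min(alpha, key=lambda n: np.linalg.norm(n.coord - co.coord)) if alpha else None

    # β-axial: nearest non-ring heavy atom on the face opposite the α nitrogen
    ring_ids = {id(a) for a in res_atoms}
    if dmb_n is not None:
        up = co.coord - dmb_n.coord
    else:
        up = _plane_normal([a.coord for a in equatorial.values()])
    up = up / np.linalg.norm(up)
    beta = None
    beta_d = np.inf
    for a in heavy:
        if id(a) in ring_ids or a is co:
            continue
        v = a.coord - co.coord
        d = np.linalg.norm(v)
        if d <= beta_cutoff and np.dot(v, up) > 0 and d < beta_d:
            beta, beta_d = a, d
    return CorrinAtomSet(co=co, equatorial_n=equatorial, ring_carbons=ring_carbons,
                         dmb_n=dmb_n, beta_ligand_atom=beta)


def _plane_normal(points: Iterable[np.ndarray]) -> np.ndarray:
    pts = np.asarray(list(points), dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]
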