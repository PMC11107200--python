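"""Seeded synthetic-data generators with known ground truth.

Every input class the analysis consumes can be generated here with the
controlling parameter known exactly, so each stage is testable offline:

* idealized corrin macrocycles with a prescribed butterfly fold angle,
* a pseudo binding pocket (corrin + glutathione-like chain + protein shell)
  with known contact and clash structure,
* two-band absorbance spectra with prescribed peak positions/heights,
* thermophoresis dilution series from a known Kd and probe concentration,
* homolog sequences with prescribed substitutions.

The corrin template is canonical, not crystallographic: cobalt at the
origin, the four equatorial nitrogens at 1.9 Å, ring carbons at in-plane
positions following the macrocycle connectivity, and the DMB nitrogen
2.2 Å below cobalt. Folding rotates the C11–C19/N23/N24 half about the
Co–C10 axis, so the generated butterfly angle equals the parameter exactly.
Only topology and atom naming must match the analysis code; no force-field
realism is attempted.
"""

from __future__ import annotations

import numpy as np

from .structure_io import AtomRecord, Structure

__all__ = [
    "make_corrin",
    "make_pocket",
    "make_spectrum",
    "hocbl_like_spectrum",
    "gscbl_like_spectrum",
    "make_mst_curve",
    "make_mst_traces",
    "make_homolog",
]

# (name, azimuth °, radius Å); the fold axis runs through Co and C10 (x-axis).
_CORRIN_TEMPLATE = [
    ("C10", 0.0, 3.4),
    ("C11", 15.0, 2.9), ("C12", 35.0, 3.4), ("C13", 55.0, 3.4), ("C14", 75.0, 2.9),
    ("C15", 95.0, 3.4),
    ("C16", 115.0, 2.9), ("C17", 140.0, 3.4), ("C18", 160.0, 3.4), ("C19", 175.0, 2.9),
    ("C1", 185.0, 2.9), ("C2", 205.0, 3.4), ("C3", 230.0, 3.4), ("C4", 245.0, 2.9),
    ("C5", 265.0, 3.4),
    ("C6", 285.0, 2.9), ("C7", 305.0, 3.4), ("C8", 325.0, 3.4), ("C9", 345.0, 2.9),
    ("N21", 215.0, 1.9), ("N22", 315.0, 1.9), ("N23", 45.0, 1.9), ("N24", 135.0, 1.9),
]

ALPHA_DIST = 2.2  # Å, Co to DMB nitrogen in the template


def _atom(serial, name, res_name, chain, res_seq, xyz, element, b=20.0):
    return AtomRecord(serial=serial, name=name, altloc="", res_name=res_name,
                      chain=chain, res_seq=res_seq, icode="",
                      x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
                      occupancy=1.0, b_factor=b, element=element)


def make_corrin(
    fold_angle: float,
    seed: int = 0,
    jitter: float = 0.0,
    beta_ligand_dist: float | None = None,
    with_dmb: bool = True,
) -> Structure:
    """Idealized corrin with a prescribed butterfly fold angle (degrees).

    ``jitter`` adds isotropic Gaussian coordinate noise (Å, seeded);
    ``beta_ligand_dist`` optionally places a glutathione-like sulfur that
    distance above cobalt (β face) as a separate GSH component.
    """
    if not 0.0 <= fold_angle <= 45.0:
        raise ValueError(f"fold angle {fold_angle}° outside the supported [0°, 45°] range")
    rng = np.random.default_rng(seed)
    theta = np.radians(fold_angle)
    rot_x = np.array([[1.0, 0.0, 0.0],
                      [0.0, np.cos(theta), -np.sin(theta)],
                      [0.0, np.sin(theta), np.cos(theta)]])

    atoms = [_atom(1, "CO", "B12", "X", 1, (0.0, 0.0, 0.0), "Co")]
    serial = 1
    for name, az_deg, radius in _CORRIN_TEMPLATE:
        az = np.radians(az_deg)
        xyz = np.array([radius * np.cos(az), radius * np.sin(az), 0.0])
        if 0.0 < az_deg < 180.0:  # the folded half; C10 stays on the axis
            xyz = rot_x @ xyz
        serial += 1
        atoms.append(_atom(serial, name, "B12", "X", 1, xyz, name[0] if name[0] != "N" else "N"))
    if with_dmb:
        serial += 1
        atoms.append(_atom(serial, "N3B", "B12", "X", 1, (0.0, 0.0, -ALPHA_DIST), "N"))
    if beta_ligand_dist is not None:
        serial += 1
        atoms.append(_atom(serial, "SG", "GSH", "X", 2, (0.0, 0.0, beta_ligand_dist), "S"))

    if jitter > 0:
        noisy = []
        for a in atoms:
            dx, dy, dz = rng.normal(0.0, jitter, 3)
            noisy.append(_atom(a.serial, a.name, a.res_name, a.chain, a.res_seq,
                               (a.x + dx, a.y + dy, a.z + dz), a.element))
        atoms = noisy
    return Structure(atoms, id=f"corrin_fold{fold_angle:g}", dialect="synthetic")


# glutathione-like β-ligand chain rising from the corrin β face; the terminal
# OXT is deliberately isolated (> 3 Å from its neighbours) so a blocking atom
# placed above it produces exactly one hand-computable overlap.
_GSH_CHAIN = [
    ("SG", (0.0, 0.0, 2.4), "S"),
    ("CB", (0.0, 0.9, 3.6), "C"),
    ("CA", (0.0, 0.5, 5.0), "C"),
    ("N", (0.0, 1.1, 6.3), "N"),
    ("C", (0.0, 0.7, 7.7), "C"),
    ("O", (1.1, 0.9, 8.3), "O"),
    ("OXT", (0.0, 0.0, 11.0), "O"),
]


def make_pocket(
    block_offset: float | None = None,
    seed: int = 0,
    fold_angle: float = 5.0,
    shell_radius: float = 16.0,
    n_shell: int = 180,
    with_waters: bool = True,
) -> Structure:
    """Corrin + glutathione-like ligand inside a pseudo-protein shell.

    Known ground truth: one direct polar contact (ligand N to Ser-like OG at
    2.9 Å), one water bridge (ligand O — water — Asn-like ND2, 2.8 Å legs),
    and zero steric clashes. With ``block_offset`` set, a single carbon is
    placed that many Å above the ligand's terminal OXT oxygen, forcing
    exactly one clash of overlap r_C + r_O − soft_tol − block_offset.
    """
    corrin = make_corrin(fold_angle, seed=seed)
    atoms = list(corrin.atoms)
    serial = max(a.serial for a in atoms)

    for name, xyz, el in _GSH_CHAIN:
        serial += 1
        atoms.append(_atom(serial, name, "GSH", "X", 2, xyz, el))

    # fixed near-pocket protein atoms with known contact distances
    serial += 1
    atoms.append(_atom(serial, "OG", "SER", "A", 901, (0.0, 4.0, 6.3), "O"))
    serial += 1
    atoms.append(_atom(serial, "ND2", "ASN", "A", 902, (6.7, 0.9, 8.3), "N"))

    if block_offset is not None:
        if block_offset <= 0:
            raise ValueError("block_offset must be positive")
        ox = dict((n, xyz) for n, xyz, _ in _GSH_CHAIN)["OXT"]
        serial += 1
        atoms.append(_atom(serial, "CB", "ALA", "A", 903,
                           (ox[0], ox[1], ox[2] + block_offset), "C"))

    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O"]
    names = {"C": "CB", "N": "N", "O": "O"}
    for i in range(n_shell):
        v = rng.normal(size=3)
        v = v / np.linalg.norm(v) * shell_radius
        el = elements[i % 3]
        serial += 1
        atoms.append(_atom(serial, names[el], "GLY", "A", i + 1, tuple(v), el))

    if with_waters:
        serial += 1
        atoms.append(_atom(serial, "O", "HOH", "W", 1, (3.9, 0.9, 8.3), "O"))
        serial += 1
        atoms.append(_atom(serial, "O", "HOH", "W", 2, (-6.0, -6.0, -6.0), "O"))
    return Structure(atoms, id="pocket", dialect="synthetic")


# ---------------------------------------------------------------------------
# spectra

def make_spectrum(
    peaks: list[tuple[float, float, float]],
    noise: float = 0.0,
    seed: int = 0,
    grid: tuple[float, float, float] = (300.0, 700.0, 1.0),
    label: str = "synthetic",
):
    """Gaussian-sum spectrum: peaks are (center nm, height AU, sigma nm)."""
    from .spectra_binding import Spectrum

    lo, hi, step = grid
    w = np.arange(lo, hi + step / 2, step)
    a = np.zeros_like(w)
    for center, height, sigma in peaks:
        if sigma <= 0 or height < 0:
            raise ValueError("peak sigma must be positive and height non-negative")
        a += height * np.exp(-((w - center) ** 2) / (2.0 * sigma**2))
    if noise > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise, a.shape)
    return Spectrum(w, a, label=label)


def hocbl_like_spectrum(noise: float = 0.0, seed: int = 0):
    """Hydroxocobalamin-like two-band spectrum: sharp γ, moderate α/β."""
    return make_spectrum([(357.0, 1.0, 9.0), (530.0, 0.40, 20.0)],
                         noise=noise, seed=seed, label="HOCbl-like")


def gscbl_like_spectrum(noise: float = 0.0, seed: int = 0,
                        gamma_ratio: float = 0.5, red_shift: float = 12.0):
    """Glutathionylcobalamin-like spectrum: collapsed γ, red-shifted α/β.

    Total band area is conserved (intensity lost from γ reappears under
    α/β), so after area normalization against the hydroxo-form reference the
    γ-peak height ratio equals ``gamma_ratio`` exactly.
    """
    # Gaussian areas: height × σ × √(2π); redistribute the γ loss onto α/β
    ab_height = (9.0 * 1.0 + 20.0 * 0.40 - 9.0 * gamma_ratio) / 20.0
    return make_spectrum(
        [(357.0, 1.0 * gamma_ratio, 9.0), (530.0 + red_shift, ab_height, 20.0)],
        noise=noise, seed=seed, label="GSCbl-like",
    )


# ---------------------------------------------------------------------------
# MST

def make_mst_curve(
    kd: float,
    probe: float,
    amplitude: float = -60.0,
    noise: float = 0.0,
    seed: int = 0,
    baseline: float = 1000.0,
    top: float = 800e-9,
    n: int = 16,
    dilution: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔFnorm dilution series (ascending concentrations, per-mil values).

    A 16-point two-fold dilution from 800 nM mirrors a standard MST layout;
    ``noise`` is the i.i.d. Gaussian SD as a fraction of |amplitude|.
    """
    from .spectra_binding import _bound_fraction

    conc = np.array([top / dilution**i for i in range(n)][::-1])
    frac = _bound_fraction(conc, probe, kd)
    y = baseline + amplitude * frac
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise * abs(amplitude), y.shape)
    return conc, y


def make_mst_traces(
    kd: float,
    probe: float,
    amplitude: float = -60.0,
    noise: float = 0.0,
    seed: int = 0,
    baseline: float = 1000.0,
    top: float = 800e-9,
    n: int = 16,
    dilution: float = 2.0,
):
    """Per-capillary thermophoresis traces consistent with the binding curve.

    Each trace is flat at the cold level for t < 5 s, relaxes between 5 and
    10 s, and is flat at the hot level afterwards, so that Fnorm evaluated
    with cold window (0, 4) s and hot window (15, 25) s reproduces the
    underlying isotherm exactly in the noiseless case.
    """
    from .spectra_binding import ThermophoresisTrace, _bound_fraction

    rng = np.random.default_rng(seed)
    conc, _ = make_mst_curve(kd, probe, amplitude, 0.0, seed, baseline, top, n, dilution)
    t = np.arange(0.0, 30.0 + 1e-9, 0.25)
    traces = []
    for c in conc:
        target = (baseline + amplitude * float(_bound_fraction(np.array([c]), probe, kd)[0])) / 1000.0
        f = np.ones_like(t)
        ramp = (t >= 5.0) & (t < 10.0)
        f[ramp] = 1.0 + (target - 1.0) * (t[ramp] - 5.0) / 5.0
        f[t >= 10.0] = target
        if noise > 0:
            f = f + rng.normal(0.0, noise * abs(1.0 - target + 1e-12), f.shape)
        traces.append(ThermophoresisTrace(time=t.copy(), fluorescence=f, concentration=float(c)))
    return traces


# ---------------------------------------------------------------------------
# sequences

def make_homolog(
    reference: str,
    mutations: dict[int, str] | int,
    seed: int = 0,
) -> str:
    """Homolog of ``reference`` with exact substitutions (no indels).

    ``mutations`` is either {1-based position: new residue} or a count of
    random substitutions (seeded, positions distinct, residues changed)."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    seq = list(reference.upper())
    if isinstance(mutations, int):
        rng = np.random.default_rng(seed)
        if mutations > len(seq):
            raise ValueError("more mutations than positions")
        positions = rng.choice(len(seq), size=mutations, replace=False)
        muts = {}
        for p in positions:
            choices = [c for c in alphabet if c != seq[p]]
            muts[int(p) + 1] = choices[int(rng.integers(len(choices)))]
        mutations = muts
    for pos, aa in mutations.items():
        if not 1 <= pos <= len(seq):
            raise ValueError(f"mutation position {pos} outside sequence length {len(seq)}")
        seq[pos - 1] = aa.upper()
    return "".join(seq)
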