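"""SASA against analytic and Monte-Carlo oracles; contacts and disulfides."""

from __future__ import annotations

import numpy as np
import pytest

from cblpocket.contacts_interfaces import (
    buried_area,
    find_disulfides,
    helix_dipole_contact,
    interface_report,
    polar_contacts,
    sasa,
    total_sasa,
)
from cblpocket.structure_io import AtomRecord, Structure

from .conftest import random_rotation

PROBE = 1.4
R_C, R_N, R_O, R_S = 1.70, 1.55, 1.52, 1.80


def atom(name, element, xyz, res_name="ALA", chain="A", res_seq=1, serial=None):
    return AtomRecord(serial if serial is not None else 1, name, "", res_name, chain,
                      res_seq, "", float(xyz[0]), float(xyz[1]), float(xyz[2]),
                      1.0, 10.0, element)


def atoms(*specs):
    return [atom(n, e, xyz, res_seq=i + 1, serial=i + 1) for i, (n, e, xyz) in enumerate(specs)]


def mc_sasa_two_spheres(c1, c2, r1, r2, n=1_000_000, seed=0):
    """Monte-Carlo oracle: uniform points on each expanded sphere, count the
    fraction not inside the other expanded sphere."""
    rng = np.random.default_rng(seed)
    total = 0.0
    for c, r, other_c, other_r in ((c1, r1, c2, r2), (c2, r2, c1, r1)):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = np.asarray(c) + r * v
        outside = np.linalg.norm(pts - np.asarray(other_c), axis=1) > other_r
        total += 4.0 * np.pi * r**2 * outside.mean()
    return total


class TestSasa:
    def test_isolated_sphere_analytic(self):
        """Single nitrogen: SASA = 4π(r + probe)² within quadrature error."""
        area = total_sasa(atoms(("N", "N", (0, 0, 0))))
        expected = 4.0 * np.pi * (R_N + PROBE) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_additive(self):
        area = total_sasa(atoms(("N", "N", (0, 0, 0)), ("O", "O", (100, 0, 0))))
        expected = 4.0 * np.pi * ((R_N + PROBE) ** 2 + (R_O + PROBE) ** 2)
        assert area == pytest.approx(expected, rel=0.01)

    def test_two_overlapping_carbons_vs_monte_carlo(self):
        pair = atoms(("C1", "C", (0, 0, 0)), ("C2", "C", (2.0, 0, 0)))
        got = total_sasa(pair)
        r = R_C + PROBE
        want = mc_sasa_two_spheres((0, 0, 0), (2.0, 0, 0), r, r)
        assert got == pytest.approx(want, rel=0.02)

    def test_monotone_under_added_occluders(self, rng):
        """Adding environment atoms never increases any existing atom's area."""
        base = atoms(("C1", "C", (0, 0, 0)), ("C2", "C", (2.5, 0, 0)))
        areas0 = sasa(base)[:2]
        extra = base + [atom("C3", "C", (1.2, 1.8, 0), res_seq=3, serial=3)]
        areas1 = sasa(extra)[:2]
        assert np.all(areas1 <= areas0 + 1e-9)

    def test_empty_set_and_bad_parameters(self):
        assert total_sasa([]) == 0.0
        with pytest.raises(ValueError):
            sasa(atoms(("C", "C", (0, 0, 0))), probe=-1.0)
        with pytest.raises(ValueError):
            sasa(atoms(("C", "C", (0, 0, 0))), n_points=10)

    def test_hydrogens_ignored(self):
        with_h = atoms(("C1", "C", (0, 0, 0)), ("H1", "H", (1.1, 0, 0)))
        assert total_sasa(with_h) == pytest.approx(
            total_sasa(atoms(("C1", "C", (0, 0, 0)))), abs=1e-9
        )


class TestBuriedArea:
    def test_distant_components_zero(self):
        a = atoms(("C1", "C", (0, 0, 0)))
        b = [atom("C2", "C", (100, 0, 0), chain="B", serial=2)]
        assert buried_area(a, b) == pytest.approx(0.0, abs=0.5)

    def test_two_sphere_analytic_cap(self):
        """Buried area equals π(R₁h₁ + R₂h₂), the mean of the two lost caps."""
        d = 2.0
        a = atoms(("C1", "C", (0, 0, 0)))
        b = [atom("O1", "O", (d, 0, 0), chain="B", serial=2)]
        r1, r2 = R_C + PROBE, R_O + PROBE
        h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
        h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
        expected = np.pi * (r1 * h1 + r2 * h2)
        assert buried_area(a, b) == pytest.approx(expected, rel=0.02)

    def test_symmetry_exact(self, pocket):
        lig = pocket.select("resname GSH")
        prot = pocket.select("chain A")
        assert buried_area(lig, prot) == buried_area(prot, lig)

    def test_overlapping_membership_rejected(self, pocket):
        lig = pocket.select("resname GSH")
        with pytest.raises(ValueError):
            buried_area(lig, lig)


class TestPolarContacts:
    def test_direct_contact_within_cutoff(self):
        lig = atoms(("N1", "N", (0, 0, 0)))
        prot = [atom("O1", "O", (2.8, 0, 0), chain="B", serial=2)]
        found = polar_contacts(lig, prot)
        assert len(found) == 1 and found[0].kind == "direct"
        assert found[0].distance == pytest.approx(2.8)

    def test_no_contact_beyond_cutoff(self):
        lig = atoms(("N1", "N", (0, 0, 0)))
        prot = [atom("O1", "O", (4.0, 0, 0), chain="B", serial=2)]
        assert polar_contacts(lig, prot, cutoff=3.5) == []

    def test_water_bridge_counted_once(self):
        lig = atoms(("O1", "O", (0, 0, 0)))
        prot = [atom("N1", "N", (5.6, 0, 0), chain="B", serial=2)]
        wat = [atom("O", "O", (2.8, 0, 0), res_name="HOH", chain="W", serial=3)]
        found = polar_contacts(lig, prot, wat)
        assert len(found) == 1
        c = found[0]
        assert c.kind == "water_bridge" and c.water == ("W", 1)
        assert c.distance == pytest.approx(2.8)

    def test_pocket_ground_truth(self, pocket):
        lig = pocket.select("resname GSH")
        prot = pocket.select("chain A")
        wat = pocket.select("water")
        found = polar_contacts(lig, prot, wat)
        kinds = sorted(c.kind for c in found)
        assert kinds == ["direct", "water_bridge"]

    def test_count_invariant_under_rigid_motion(self, pocket, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3) * 15.0
        moved = pocket.transformed(R, t)
        for st in (pocket, moved):
            found = polar_contacts(st.select("resname GSH"), st.select("chain A"),
                                   st.select("water"))
            assert len(found) == 2


class TestDisulfides:
    def cys_pair(self, d):
        return Structure([
            atom("SG", "S", (0, 0, 0), res_name="CYS", res_seq=10, serial=1),
            atom("SG", "S", (d, 0, 0), res_name="CYS", res_seq=20, serial=2),
        ])

    def test_bonded_pair_found(self):
        pairs = find_disulfides(self.cys_pair(2.05))
        assert len(pairs) == 1
        (ca, ra), (cb, rb), d = pairs[0]
        assert (ra, rb) == (10, 20) and d == pytest.approx(2.05)

    def test_distant_pair_rejected(self):
        assert find_disulfides(self.cys_pair(3.5)) == []

    def test_greedy_pairing_no_cys_reuse(self):
        # three cysteines in a row: the closest pair wins, the third is left out
        st = Structure([
            atom("SG", "S", (0, 0, 0), res_name="CYS", res_seq=1, serial=1),
            atom("SG", "S", (2.0, 0, 0), res_name="CYS", res_seq=2, serial=2),
            atom("SG", "S", (4.2, 0, 0), res_name="CYS", res_seq=3, serial=3),
        ])
        pairs = find_disulfides(st)
        assert len(pairs) == 1
        assert pairs[0][0][1] == 1 and pairs[0][1][1] == 2


class TestHelixDipole:
    def test_capping_carboxylate_detected(self):
        carbox = atoms(("OE1", "O", (0, 0, 0)))
        helix = [atom("N", "N", (2.9, 0, 0), res_seq=154, serial=2),
                 atom("N", "N", (6.0, 0, 0), res_seq=155, serial=3)]
        flag, dmin = helix_dipole_contact(carbox, helix)
        assert flag is True and dmin == pytest.approx(2.9)

    def test_distant_carboxylate_rejected(self):
        carbox = atoms(("OE1", "O", (0, 0, 0)))
        helix = [atom("N", "N", (5.0, 0, 0), res_seq=154, serial=2)]
        flag, dmin = helix_dipole_contact(carbox, helix, cutoff=3.5)
        assert flag is False and dmin == pytest.approx(5.0)

    def test_requires_oxygens(self):
        with pytest.raises(ValueError):
            helix_dipole_contact(atoms(("CG", "C", (0, 0, 0))), [])


class TestInterfaceRanking:
    def test_pocket_partition_ranks_by_burial(self, pocket):
        """The ligand buries more surface against the near-pocket atoms than
        the distant shell does against either."""
        cbl = pocket.select("resname B12 or resname GSH")
        near = pocket.select("chain A and resi 901-903")
        shell = pocket.select("chain A and resi 1-200")
        rep = interface_report({"ligand": cbl, "near": near, "shell": shell},
                               n_points=240)
        assert rep.ranking[0] == ("ligand", "near")
        assert rep.buried[("ligand", "near")] >= rep.buried[("ligand", "shell")] - 1.0
        assert all(v >= -1.0 for v in rep.buried.values())
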