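"""Contact census, surface areas, hydrogen bonds, ring interactions."""

import numpy as np
import pytest

from aptastruct.chemistry import vdw_radius
from aptastruct.interface import (
    buried_area_decomposition, detect_hydrogen_bonds, detect_ring_interactions,
    find_contact_residues, group_bidentate, shrake_rupley_sasa,
    solvent_accessible_area,
)
from aptastruct.model import Atom, Chain, Residue, StructureModel
from aptastruct.synthetic import transformed

from conftest import random_rotation


def two_atom_model(distance: float) -> StructureModel:
    prot = Residue("A", 1, "ALA", atoms=[Atom("CB", "C", np.zeros(3))])
    nuc = Residue("C", 1, "A",
                  atoms=[Atom("C2", "C", np.array([distance, 0.0, 0.0]))])
    return StructureModel("two_atoms", [Chain("A", [prot]), Chain("C", [nuc])])


def random_toy_complex(rng: np.random.Generator, n_per_side: int = 100) -> StructureModel:
    """Random point clouds labeled as protein / nucleic residues."""
    prot_res, nuc_res = [], []
    for i in range(n_per_side // 2):
        atoms = [Atom(f"C{j}", "C", rng.uniform(-10, 10, 3)) for j in range(2)]
        prot_res.append(Residue("A", i + 1, "GLY", atoms=atoms))
        atoms = [Atom(f"C{j}", "C", rng.uniform(-10, 10, 3)) for j in range(2)]
        nuc_res.append(Residue("C", i + 1, "A", atoms=atoms))
    return StructureModel("random_toy", [Chain("A", prot_res), Chain("C", nuc_res)])


class TestContactCensus:
    @pytest.mark.parametrize("d,cutoff,expected", [
        (3.6, 3.7, 1),
        (3.6, 3.5, 0),
        (3.70, 3.7, 1),     # boundary inclusive
    ])
    def test_cutoff_boundary(self, d, cutoff, expected):
        census = find_contact_residues(two_atom_model(d), ["A"], ["C"], cutoff=cutoff)
        assert len(census.residues_per_chain["A"]) == expected

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            find_contact_residues(two_atom_model(3.0), ["A"], ["C"], cutoff=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_toy_complex(rng)
        census = find_contact_residues(model, ["A"], ["C"], cutoff=3.7)

        # O(n^2) oracle
        expected_pairs = set()
        expected_residues = set()
        for pres in model.chain("A").residues:
            for pa in pres.atoms:
                for nres in model.chain("C").residues:
                    for na in nres.atoms:
                        if np.linalg.norm(pa.position - na.position) <= 3.7:
                            expected_pairs.add((pres.number, pa.name, nres.number, na.name))
                            expected_residues.add(pres.number)
        got_pairs = {(c.protein_atom[1], c.protein_atom[2], c.nucleic_atom[1],
                      c.nucleic_atom[2]) for c in census.contacts}
        assert got_pairs == expected_pairs
        assert set(census.residues_per_chain["A"]) == expected_residues

    def test_census_invariant_under_rigid_motion(self, toy_symmetric, rng):
        before = find_contact_residues(toy_symmetric, ["A", "B"], ["E", "F"])
        moved = transformed(toy_symmetric, random_rotation(rng), rng.normal(size=3) * 8)
        after = find_contact_residues(moved, ["A", "B"], ["E", "F"])
        assert before.residues_per_chain == after.residues_per_chain
        assert len(before.contacts) == len(after.contacts)


class TestSasa:
    def test_isolated_atom_matches_sphere(self):
        r = vdw_radius("C")
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]))
        analytic = 4 * np.pi * (r + 1.4) ** 2
        assert area[0] == pytest.approx(analytic, rel=0.005)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        radii = np.array([1.7, 1.52])
        areas = shrake_rupley_sasa(coords, radii)
        for a, r in zip(areas, radii):
            assert a == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=0.005)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0])
    def test_two_equal_spheres_match_cap_formula(self, d):
        # two equal spheres of SAS radius R at distance d < 2R: each loses a
        # cap of area 2*pi*R*(R - d/2)
        r_vdw = 1.7
        big_r = r_vdw + 1.4
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = shrake_rupley_sasa(coords, np.array([r_vdw, r_vdw]))
        analytic = 4 * np.pi * big_r**2 - 2 * np.pi * big_r * (big_r - d / 2)
        for a in areas:
            assert a == pytest.approx(analytic, rel=0.005)

    def test_doubling_points_changes_little(self, toy_symmetric):
        lo = solvent_accessible_area(toy_symmetric, ["A"], n_points=960)
        hi = solvent_accessible_area(toy_symmetric, ["A"], n_points=1920)
        assert sum(hi.values()) == pytest.approx(sum(lo.values()), rel=0.01)

    def test_against_independent_implementation(self, toy_symmetric):
        """Cross-check the in-package Shrake-Rupley against biotite's, using
        identical radii so only the point sampling differs."""
        import biotite.structure as struc

        refs = [(r, a) for r in toy_symmetric.chain("A").residues for a in r.atoms]
        arr = struc.AtomArray(len(refs))
        for i, (res, atom) in enumerate(refs):
            arr.coord[i] = atom.position
            arr.chain_id[i] = res.chain_id
            arr.res_id[i] = res.number
            arr.res_name[i] = res.name
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element
        radii = np.array([vdw_radius(a.element) for _, a in refs])
        ours = solvent_accessible_area(toy_symmetric, ["A"], n_points=960)
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii)
        assert sum(ours.values()) == pytest.approx(float(np.nansum(theirs)), rel=0.02)

    def test_unknown_element_rejected(self):
        model = StructureModel("bad", [Chain("A", [
            Residue("A", 1, "ALA", atoms=[Atom("XX", "XX", np.zeros(3))])])])
        with pytest.raises(KeyError, match="XX"):
            solvent_accessible_area(model, ["A"])


class TestBuriedArea:
    def test_non_touching_components_bury_nothing(self):
        prot = Residue("A", 1, "ALA", atoms=[Atom("CB", "C", np.zeros(3))])
        nuc = Residue("C", 1, "A", atoms=[Atom("C2", "C", np.array([40.0, 0, 0]))])
        model = StructureModel("apart", [Chain("A", [prot]), Chain("C", [nuc])])
        res = buried_area_decomposition(model, ["A"], ["C"])
        assert res["total"] == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_complex_buries_equally(self, toy_symmetric):
        res = buried_area_decomposition(toy_symmetric, ["A", "B"], ["E", "F"],
                                        n_points=1920)
        a, b = res["per_domain"]["chain_A"], res["per_domain"]["chain_B"]
        assert a > 10.0    # the toy interface is real
        assert a == pytest.approx(b, rel=0.01)
        assert res["total"] == pytest.approx(a + b, abs=0.5)

    def test_burial_decreases_when_pulled_apart(self, toy_symmetric):
        totals = []
        for shift in (0.0, 4.0, 40.0):
            moved = transformed(toy_symmetric, np.eye(3), np.zeros(3))
            for cid in ("E", "F"):
                for r in moved.chain(cid).residues:
                    for a in r.atoms:
                        a.position = a.position + np.array([0.0, 0.0, shift])
            totals.append(buried_area_decomposition(
                moved, ["A", "B"], ["E", "F"])["total"])
        assert totals[0] >= totals[1] >= totals[2]
        assert totals[2] == pytest.approx(0.0, abs=1e-6)

    def test_overlapping_domains_rejected(self, toy_symmetric):
        with pytest.raises(ValueError, match="overlap"):
            buried_area_decomposition(
                toy_symmetric, ["A", "B"], ["E", "F"],
                domains={"d1": ("A", [(1, 20)]), "d2": ("A", [(15, 36)])})


def _make_residue(chain, number, name, atoms):
    return Residue(chain, number, name,
                   atoms=[Atom(n, e, np.array(p, dtype=float)) for n, e, p in atoms])


class TestHydrogenBonds:
    def _model(self, acceptor_pos, antecedent_pos=(-1.2, 0.8, 0.0)):
        # serine hydroxyl donor (OG, antecedent CB) vs adenine N1 acceptor
        ser = _make_residue("A", 1, "SER", [
            ("CB", "C", antecedent_pos), ("OG", "O", (0.0, 0.0, 0.0))])
        ade = _make_residue("C", 1, "A", [("N1", "N", acceptor_pos)])
        return StructureModel("hb", [Chain("A", [ser]), Chain("C", [ade])])

    def test_ideal_geometry_is_one_bond(self):
        bonds = detect_hydrogen_bonds(self._model((2.9, 0.0, 0.0)), ["A"], ["C"])
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].antecedent_angle > 140.0

    def test_long_distance_rejected(self):
        assert detect_hydrogen_bonds(self._model((4.0, 0.0, 0.0)), ["A"], ["C"]) == []

    def test_acute_antecedent_angle_rejected(self):
        # acceptor placed on the same side as the antecedent
        bonds = detect_hydrogen_bonds(
            self._model((-2.0, 2.0, 0.0)), ["A"], ["C"])
        assert bonds == []

    def test_bidentate_grouping(self):
        # arginine guanidinium donating to both Hoogsteen atoms of a guanine
        arg = _make_residue("A", 1, "ARG", [
            ("CZ", "C", (0.0, 0.0, 0.0)),
            ("NH1", "N", (1.2, 0.7, 0.0)),
            ("NH2", "N", (1.2, -0.7, 0.0)),
        ])
        gua = _make_residue("C", 1, "G", [
            ("O6", "O", (3.9, 1.0, 0.0)),
            ("N7", "N", (3.9, -1.0, 0.0)),
        ])
        model = StructureModel("bident", [Chain("A", [arg]), Chain("C", [gua])])
        bonds = detect_hydrogen_bonds(model, ["A"], ["C"])
        grouped = group_bidentate(bonds)
        assert len(grouped[(("A", 1), ("C", 1))]) >= 2


def _hexagon(center, normal_axis="z", radius=1.4):
    pts = []
    for k in range(6):
        ang = np.pi * k / 3
        if normal_axis == "z":
            pts.append((center[0] + radius * np.cos(ang),
                        center[1] + radius * np.sin(ang), center[2]))
        else:  # normal along x: ring in the y-z plane
            pts.append((center[0], center[1] + radius * np.cos(ang),
                        center[2] + radius * np.sin(ang)))
    return pts


class TestRingInteractions:
    RING_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

    def _tyr(self, center, normal_axis="z"):
        return _make_residue("A", 1, "TYR", [
            (n, "C", p) for n, p in zip(self.RING_NAMES, _hexagon(center, normal_axis))])

    def _ade(self, center, normal_axis="z"):
        names = ("N1", "C2", "N3", "C4", "C5", "C6")
        elements = ("N", "C", "N", "C", "C", "C")
        return _make_residue("C", 1, "A", [
            (n, e, p) for (n, e), p in
            zip(zip(names, elements), _hexagon(center, normal_axis))])

    def test_parallel_coaxial_rings_stack(self):
        model = StructureModel("stack", [
            Chain("A", [self._tyr((0, 0, 0))]), Chain("C", [self._ade((0, 0, 3.5))])])
        hits = detect_ring_interactions(model, ["A"], ["C"])
        stacks = [h for h in hits if h.kind == "stacking"]
        assert len(stacks) == 1
        assert stacks[0].centroid_distance == pytest.approx(3.5, abs=1e-6)
        assert stacks[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_rings_do_not_stack(self):
        model = StructureModel("perp", [
            Chain("A", [self._tyr((0, 0, 0))]),
            Chain("C", [self._ade((0, 0, 3.5), normal_axis="x")])])
        hits = detect_ring_interactions(model, ["A"], ["C"])
        assert [h for h in hits if h.kind == "stacking"] == []

    def test_cation_above_ring_plane_hits(self):
        lys = _make_residue("A", 1, "LYS", [("NZ", "N", (0.0, 0.0, 4.0))])
        model = StructureModel("catpi", [
            Chain("A", [lys]), Chain("C", [self._ade((0, 0, 0))])])
        hits = detect_ring_interactions(model, ["A"], ["C"])
        cat = [h for h in hits if h.kind == "cation_pi"]
        assert len(cat) == 1
        assert cat[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_cation_in_ring_plane_rejected(self):
        lys = _make_residue("A", 1, "LYS", [("NZ", "N", (4.5, 0.0, 0.0))])
        model = StructureModel("catpi_edge", [
            Chain("A", [lys]), Chain("C", [self._ade((0, 0, 0))])])
        hits = detect_ring_interactions(model, ["A"], ["C"])
        assert [h for h in hits if h.kind == "cation_pi"] == []
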