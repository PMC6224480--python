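"""Geometric structure operations against brute-force and analytic oracles."""

import numpy as np
import pytest

from tprbind.structure import (
    ResidueSelection,
    SelectionUnion,
    StructureModel,
    buried_surface_area,
    confinement_concentration,
    contact_residues,
    crystal_neighbours,
    helix_fraction,
    hydrogen_bonds,
    merge,
    parse_structure,
    shrake_rupley_asa,
    superpose,
    translate,
    write_pdb,
)
from tprbind.synthetic import build_toy_helix


def two_atom_model(distance, element_a="C", element_b="C"):
    """Two single-atom chains separated along x."""
    return StructureModel(
        chain_ids=["A", "B"],
        residue_numbers=np.array([1, 1]),
        insertion_codes=["", ""],
        residue_names=["ALA", "ALA"],
        atom_names=[element_a + "X1", element_b + "X2"],
        elements=[element_a, element_b],
        coords=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
    )


def random_toy_structure(rng, n_chains=2, n_res=5):
    """Random point cloud organised into chains/residues (one atom each)."""
    chains, resnums, icodes, resnames, atnames, elements, coords = \
        [], [], [], [], [], [], []
    for c in range(n_chains):
        cid = chr(ord("A") + c)
        centre = rng.uniform(-15, 15, size=3)
        for r in range(1, n_res + 1):
            for k, el in enumerate(("N", "CA", "C")):
                chains.append(cid)
                resnums.append(r)
                icodes.append("")
                resnames.append("GLY")
                atnames.append(el if el != "CA" else "CA")
                elements.append("C" if el == "CA" else el[0])
                coords.append(centre + rng.uniform(-8, 8, size=3))
    return StructureModel(
        chain_ids=chains, residue_numbers=np.array(resnums),
        insertion_codes=icodes, residue_names=resnames, atom_names=atnames,
        elements=elements, coords=np.array(coords))


class TestToyHelix:
    def test_ca_ca_distance_canonical(self):
        h = build_toy_helix(20)
        ca = h.coords[h.select(atom_name="CA")]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(d, 3.83, atol=0.05)

    def test_ca_i_i4_distance_from_parametric_oracle(self):
        # chord of the parametric helix: sqrt((4*rise)^2 + (2 r sin(2*twist))^2)
        r, rise, twist = 2.3, 1.5, np.radians(100.0)
        expect = np.hypot(4 * rise, 2 * r * np.sin(2 * twist))
        h = build_toy_helix(20)
        ca = h.coords[h.select(atom_name="CA")]
        d = np.linalg.norm(ca[4:] - ca[:-4], axis=1)
        assert np.allclose(d, expect, atol=1e-9)
        assert expect == pytest.approx(6.2, abs=0.1)

    def test_helix_fraction_near_one(self):
        assert helix_fraction(build_toy_helix(20)) >= 0.8

    def test_extended_chain_has_zero_helix_fraction(self):
        # straight chain: O(i)..N(i+4) far beyond the hydrogen-bond cutoff
        n = 12
        coords, chains, resnums, atnames, elements = [], [], [], [], []
        for i in range(n):
            for j, name in enumerate(("N", "CA", "C", "O")):
                coords.append([3.5 * i + 0.8 * j, 0.0, 0.0])
                chains.append("A")
                resnums.append(i + 1)
                atnames.append(name)
                elements.append(name[0])
        model = StructureModel(
            chain_ids=chains, residue_numbers=np.array(resnums),
            insertion_codes=[""] * len(chains), residue_names=["ALA"] * len(chains),
            atom_names=atnames, elements=elements, coords=np.array(coords))
        assert helix_fraction(model) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_toy_helix(3)

    def test_distant_helices_share_no_contacts(self):
        h1 = build_toy_helix(12, "A")
        h2 = translate(build_toy_helix(12, "B"), (50.0, 0.0, 0.0))
        rep = contact_residues(merge([h1, h2]), ResidueSelection("A"),
                               ResidueSelection("B"))
        assert rep.contact_residues_a == () and rep.contact_residues_b == ()


class TestParseRoundTrip:
    def test_toy_helix_pdb_round_trip(self, tmp_path):
        h = build_toy_helix(10)
        path = tmp_path / "helix.pdb"
        write_pdb(h, path)
        back = parse_structure(path, fmt="pdb")
        assert len(back) == len(h)
        assert np.allclose(back.coords, h.coords, atol=1e-3)
        assert back.atom_names == h.atom_names
        assert back.residue_numbers.tolist() == h.residue_numbers.tolist()

    def test_minimal_two_atom_fixture(self, tmp_path):
        path = tmp_path / "two.pdb"
        write_pdb(two_atom_model(3.0), path)
        model = parse_structure(path)
        assert len(model) == 2
        assert model.coords[1][0] == pytest.approx(3.0, abs=1e-3)

    def test_malformed_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\nloop_\nbroken")
        from tprbind.structure import ParseError
        with pytest.raises((ParseError, Exception)):
            parse_structure(bad, fmt="mmcif")


class TestContacts:
    @pytest.mark.parametrize("d, expect_hit", [(4.19, True), (4.21, False)])
    def test_cutoff_is_sharp(self, d, expect_hit):
        rep = contact_residues(two_atom_model(d), ResidueSelection("A"),
                               ResidueSelection("B"), cutoff=4.2)
        assert bool(rep.contact_residues_a) == expect_hit
        assert bool(rep.contact_residues_b) == expect_hit

    def test_overlapping_selections_rejected(self):
        m = two_atom_model(3.0)
        with pytest.raises(ValueError):
            contact_residues(m, ResidueSelection("A"), ResidueSelection("A"))

    def test_matches_brute_force_on_random_structures(self, rng):
        """Contact and neighbour operations equal all-pairs brute force on
        100 random toy structures."""
        for _ in range(100):
            m = random_toy_structure(rng)
            sel_a, sel_b = ResidueSelection("A"), ResidueSelection("B")
            rep = contact_residues(m, sel_a, sel_b, cutoff=4.2)
            ia = m.select(sel_a)
            ib = m.select(sel_b)
            dmat = np.linalg.norm(
                m.coords[ia][:, None, :] - m.coords[ib][None, :, :], axis=2)
            hit_a = sorted({
                (m.chain_ids[i], int(m.residue_numbers[i]), m.insertion_codes[i],
                 m.residue_names[i])
                for k, i in enumerate(ia) if dmat[k].min() <= 4.2})
            hit_b = sorted({
                (m.chain_ids[i], int(m.residue_numbers[i]), m.insertion_codes[i],
                 m.residue_names[i])
                for k, i in enumerate(ib) if dmat[:, k].min() <= 4.2})
            assert list(rep.contact_residues_a) == hit_a
            assert list(rep.contact_residues_b) == hit_b
            # crystal neighbours against the same distance matrix (CA only)
            got = crystal_neighbours(m, "A", cutoff=10.0)
            ca_a = m.coords[m.select(sel_a, atom_name="CA")]
            ca_b = m.coords[m.select(sel_b, atom_name="CA")]
            dmin = np.linalg.norm(
                ca_a[:, None, :] - ca_b[None, :, :], axis=2).min()
            assert (["B"] if dmin <= 10.0 else []) == got


class TestHydrogenBonds:
    def test_oxygen_pair_within_cutoff(self):
        m = two_atom_model(3.3, "O", "O")
        bonds = hydrogen_bonds(m, ResidueSelection("A"), ResidueSelection("B"))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(3.3)

    def test_carbon_excluded(self):
        m = two_atom_model(3.0, "N", "C")
        assert hydrogen_bonds(m, ResidueSelection("A"),
                              ResidueSelection("B")) == []

    def test_symmetric_in_side_order(self, rng):
        m = random_toy_structure(rng)
        b1 = hydrogen_bonds(m, ResidueSelection("A"), ResidueSelection("B"))
        b2 = hydrogen_bonds(m, ResidueSelection("B"), ResidueSelection("A"))
        assert {(b.atom_a, b.atom_b) for b in b1} == \
               {(b.atom_b, b.atom_a) for b in b2}

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            m = random_toy_structure(rng)
            bonds = hydrogen_bonds(m, ResidueSelection("A"), ResidueSelection("B"),
                                   cutoff=3.4)
            expected = set()
            for i in range(len(m)):
                for j in range(len(m)):
                    if m.chain_ids[i] == "A" and m.chain_ids[j] == "B" \
                            and m.elements[i] in "NO" and m.elements[j] in "NO":
                        d = np.linalg.norm(m.coords[i] - m.coords[j])
                        if d <= 3.4:
                            expected.add((i, j))
            assert len(bonds) == len(expected)


class TestBuriedArea:
    def test_single_atom_asa_matches_analytic_sphere(self):
        """Isolated carbon: ASA = 4 pi (1.70 + 1.4)^2, within 0.5% at 960
        sample points."""
        asa = shrake_rupley_asa(np.zeros((1, 3)), ["C"], n_points=960)
        analytic = 4.0 * np.pi * (1.70 + 1.4) ** 2
        assert asa[0] == pytest.approx(analytic, rel=0.005)
        assert analytic == pytest.approx(120.8, abs=0.1)

    def test_distant_sides_bury_nothing(self):
        h1 = build_toy_helix(8, "A")
        h2 = translate(build_toy_helix(8, "B"), (100.0, 0.0, 0.0))
        ba, bb = buried_surface_area(merge([h1, h2]), ResidueSelection("A"),
                                     ResidueSelection("B"))
        assert abs(ba) < 1.0 and abs(bb) < 1.0

    def test_swap_swaps_outputs(self):
        h1 = build_toy_helix(8, "A")
        h2 = translate(build_toy_helix(6, "B"), (7.0, 0.0, 0.0))
        m = merge([h1, h2])
        ba, bb = buried_surface_area(m, ResidueSelection("A"), ResidueSelection("B"))
        bb2, ba2 = buried_surface_area(m, ResidueSelection("B"), ResidueSelection("A"))
        assert ba == pytest.approx(ba2, abs=1e-9)
        assert bb == pytest.approx(bb2, abs=1e-9)

    def test_monotone_on_approach(self):
        h1 = build_toy_helix(8, "A")
        buried = []
        for sep in (14.0, 10.0, 8.0, 6.5):
            h2 = translate(build_toy_helix(8, "B"), (sep, 0.0, 0.0))
            ba, _ = buried_surface_area(merge([h1, h2]), ResidueSelection("A"),
                                        ResidueSelection("B"), n_points=480)
            buried.append(ba)
        assert all(b2 >= b1 - 0.5 for b1, b2 in zip(buried, buried[1:]))
        assert buried[-1] > buried[0]

    def test_union_selection_covers_dimer_partner(self):
        h1 = build_toy_helix(8, "A")
        h2 = translate(build_toy_helix(8, "B"), (7.0, 0.0, 0.0))
        h3 = translate(build_toy_helix(8, "C"), (-7.0, 0.0, 0.0))
        m = merge([h1, h2, h3])
        both = SelectionUnion((ResidueSelection("B"), ResidueSelection("C")))
        ba_pair, _ = buried_surface_area(m, ResidueSelection("A"), both)
        ba_single, _ = buried_surface_area(m, ResidueSelection("A"),
                                           ResidueSelection("B"))
        assert ba_pair > ba_single


class TestSuperpose:
    def test_identity_gives_zero_rmsd(self):
        h = build_toy_helix(15)
        res = superpose(h, ResidueSelection("A"), h, ResidueSelection("A"))
        assert res.rmsd < 1e-12
        assert res.n_atoms == 15

    def test_recovers_constructed_rigid_transform(self, rng):
        h = build_toy_helix(15)
        # random proper rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-20, 20, size=3)
        moved = StructureModel(
            chain_ids=list(h.chain_ids), residue_numbers=h.residue_numbers.copy(),
            insertion_codes=list(h.insertion_codes),
            residue_names=list(h.residue_names), atom_names=list(h.atom_names),
            elements=list(h.elements), coords=h.coords @ q.T + t)
        res = superpose(moved, ResidueSelection("A"), h, ResidueSelection("A"))
        assert res.rmsd < 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rotation.T @ res.rotation == pytest.approx(np.eye(3), abs=1e-9)

    def test_rmsd_invariant_under_rigid_motion(self, rng):
        h1 = build_toy_helix(15)
        h2 = build_toy_helix(15)
        # perturb one copy so rmsd is nonzero
        h2 = StructureModel(
            chain_ids=list(h2.chain_ids), residue_numbers=h2.residue_numbers.copy(),
            insertion_codes=list(h2.insertion_codes),
            residue_names=list(h2.residue_names), atom_names=list(h2.atom_names),
            elements=list(h2.elements),
            coords=h2.coords + rng.normal(0, 0.3, size=h2.coords.shape))
        base = superpose(h1, ResidueSelection("A"), h2, ResidueSelection("A")).rmsd
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        h1_moved = StructureModel(
            chain_ids=list(h1.chain_ids), residue_numbers=h1.residue_numbers.copy(),
            insertion_codes=list(h1.insertion_codes),
            residue_names=list(h1.residue_names), atom_names=list(h1.atom_names),
            elements=list(h1.elements), coords=h1.coords @ q.T + 5.0)
        moved = superpose(h1_moved, ResidueSelection("A"), h2,
                          ResidueSelection("A")).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_offset_mapping_matches_shifted_numbering(self):
        h1 = build_toy_helix(15)
        h2 = build_toy_helix(15)
        shifted = StructureModel(
            chain_ids=list(h2.chain_ids),
            residue_numbers=h2.residue_numbers + 15,
            insertion_codes=list(h2.insertion_codes),
            residue_names=list(h2.residue_names), atom_names=list(h2.atom_names),
            elements=list(h2.elements), coords=h2.coords)
        res = superpose(h1, ResidueSelection("A", ((1, 15),)),
                        shifted, ResidueSelection("A", ((16, 30),)))
        assert res.n_atoms == 15
        assert res.rmsd < 1e-12

    def test_too_few_atoms_rejected(self):
        h = build_toy_helix(4)
        with pytest.raises(ValueError):
            superpose(h, ResidueSelection("A", ((1, 2),)),
                      h, ResidueSelection("A", ((1, 2),)))


class TestCrystalNeighbours:
    @pytest.mark.parametrize("sep, expected", [(9.9, ["B"]), (10.1, [])])
    def test_cutoff_sharp_on_closest_ca(self, sep, expected):
        # CA radius is 2.3 A: place helix axes so the closest CA pair is sep
        h1 = build_toy_helix(8, "A")
        h2 = translate(build_toy_helix(8, "B"), (0.0, 0.0, 0.0))
        ca1 = h1.coords[h1.select(atom_name="CA")]
        ca2 = h2.coords[h2.select(atom_name="CA")]
        base = min(np.linalg.norm(a - b) for a in ca1 for b in ca2
                   if not np.allclose(a, b))
        # shift along x until the minimum CA-CA distance equals sep
        from scipy.optimize import brentq

        def min_d(dx):
            return min(np.linalg.norm(a - (b + np.array([dx, 0, 0])))
                       for a in ca1 for b in ca2) - sep

        dx = brentq(min_d, sep - 5.0, sep + 5.0)
        m = merge([h1, translate(h2, (dx, 0.0, 0.0))])
        assert crystal_neighbours(m, "A", cutoff=10.0) == expected

    def test_isolated_chain_has_no_neighbours(self):
        assert crystal_neighbours(build_toy_helix(8, "A"), "A") == []

    def test_missing_chain_rejected(self):
        with pytest.raises(ValueError):
            crystal_neighbours(build_toy_helix(8, "A"), "Z")


class TestConfinement:
    def test_zero_molecules(self):
        assert confinement_concentration(0, 150.0) == 0.0

    def test_two_molecules_in_150A_sphere(self):
        """Two tethered domains in a 150 A sphere exceed 100 uM; the
        unit-conversion oracle gives ~235 uM."""
        c = confinement_concentration(2, 150.0)
        assert c >= 100.0
        oracle = 2.0 / (6.02214076e23 * 1.4137167e-20) * 1e6
        assert c == pytest.approx(oracle, rel=1e-4)
        assert c == pytest.approx(235.0, abs=1.0)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            confinement_concentration(2, 0.0)
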