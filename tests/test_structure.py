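"""Parsing, acceptor taxonomy, and contact-scan geometry."""

import math

import numpy as np
import pytest

from halokit.elements import AcceptorClass
from halokit.errors import EmptyStructureError, GeometryError, ParameterError, ParseError
from halokit.simulate import build_synthetic_complex
from halokit.structure import (
    AtomRecord,
    compute_angle,
    find_acceptors,
    find_halogen_sites,
    parse_structure,
    scan_contacts,
)

HETATM_BR = (
    "HETATM    1 BR1  LIG L 501      10.000  20.000  30.000  1.00  0.00          BR"
)


def _atom(name, element, resname, resnum, xyz, kind, chain="A", serial=1):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_number=resnum,
        chain=chain,
        xyz=np.asarray(xyz, dtype=float),
        record_kind=kind,
    )


class TestParse:
    def test_single_hetatm_line(self):
        atoms = parse_structure(HETATM_BR + "\nEND\n")
        assert len(atoms) == 1
        a = atoms[0]
        assert a.element == "BR"
        assert a.record_kind == "hetero"
        np.testing.assert_allclose(a.xyz, [10.0, 20.0, 30.0])

    def test_empty_input_raises(self):
        with pytest.raises(EmptyStructureError):
            parse_structure("END\n")

    def test_truncated_record_reports_line_number(self):
        text = HETATM_BR + "\nHETATM    2 BR2  LIG L 501      10.000\n"
        with pytest.raises(ParseError, match="line 2"):
            parse_structure(text)

    def test_altloc_keeps_highest_occupancy_tie_broken_alphabetically(self):
        lines = [
            "ATOM      1  O  AGLY A   1       0.000   0.000   0.000  0.50  0.00           O",
            "ATOM      2  O  BGLY A   1       5.000   0.000   0.000  0.50  0.00           O",
        ]
        atoms = parse_structure("\n".join(lines) + "\nEND\n")
        assert len(atoms) == 1
        assert atoms[0].altloc == "A"
        assert atoms[0].xyz[0] == pytest.approx(0.0)

    def test_hydrogens_dropped(self):
        lines = [
            HETATM_BR,
            "HETATM    2  H1  LIG L 501      11.000  20.000  30.000  1.00  0.00           H",
        ]
        atoms = parse_structure("\n".join(lines) + "\nEND\n")
        assert [a.element for a in atoms] == ["BR"]

    def test_generator_round_trip_matches_manifest_atom_count(self):
        text, manifest = build_synthetic_complex(
            [(3.2, 160.0, 130.0, "backbone_carbonyl_O")], seed=11
        )
        atoms = parse_structure(text)
        assert len(atoms) == manifest["n_atoms"]


class TestComputeAngle:
    def test_collinear_is_180(self):
        assert compute_angle([0, 0, 0], [1, 0, 0], [2, 0, 0]) == pytest.approx(180.0)

    def test_right_angle(self):
        assert compute_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_matches_law_of_cosines_on_random_triples(self, rng):
        for _ in range(200):
            a, b, c = rng.normal(size=(3, 3))
            ab = np.linalg.norm(a - b)
            cb = np.linalg.norm(c - b)
            ac = np.linalg.norm(a - c)
            expected = math.degrees(
                math.acos(np.clip((ab**2 + cb**2 - ac**2) / (2 * ab * cb), -1, 1))
            )
            assert compute_angle(a, b, c) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_arm_raises(self):
        with pytest.raises(GeometryError):
            compute_angle([1, 1, 1], [1, 1, 1], [0, 0, 0])


class TestHalogenSites:
    def test_structure_without_halogens_is_empty(self):
        atoms = [_atom("O", "O", "HOH", 1, [0, 0, 0], "water")]
        assert find_halogen_sites(atoms) == []

    def test_bond_assignment_matches_brute_force(self, rng):
        # ligand with two bromines and several carbons: each Br must pair
        # with its nearest carbon within the covalent ceiling
        carbons = [
            _atom(f"C{i}", "C", "LIG", 9, rng.uniform(-3, 3, 3), "hetero", serial=i)
            for i in range(1, 5)
        ]
        bromines = []
        for j, c in enumerate(carbons[:2]):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            bromines.append(
                _atom(f"BR{j}", "BR", "LIG", 9, c.xyz + 1.9 * direction, "hetero", serial=10 + j)
            )
        atoms = carbons + bromines
        sites = find_halogen_sites(atoms, "LIG")
        assert len(sites) == 2
        for site in sites:
            dists = {c.name: np.linalg.norm(site.x_atom.xyz - c.xyz) for c in carbons}
            best = min((d, n) for n, d in dists.items() if d <= 2.1)[1]
            assert site.c_atom.name == best

    def test_halogen_without_carbon_is_flagged_not_dropped(self):
        atoms = [_atom("BR1", "BR", "LIG", 9, [0, 0, 0], "hetero")]
        sites = find_halogen_sites(atoms, "LIG")
        assert len(sites) == 1
        assert not sites[0].bonded


class TestAcceptors:
    def test_single_water_molecule(self):
        atoms = [_atom("O", "O", "HOH", 1, [0, 0, 0], "water")]
        accs = find_acceptors(atoms)
        assert len(accs) == 1
        assert accs[0].acceptor_class is AcceptorClass.WATER_O

    def test_histidine_yields_ring_nitrogens_and_pi_centroid(self):
        # planar imidazole ring, regular pentagon of radius 1.15 A
        ring_names = ["CG", "ND1", "CD2", "CE1", "NE2"]
        order = ["CG", "ND1", "CE1", "NE2", "CD2"]  # pentagon adjacency
        atoms = []
        for i, name in enumerate(order):
            th = 2 * math.pi * i / 5
            elem = "N" if name.startswith("N") else "C"
            atoms.append(
                _atom(name, elem, "HIS", 7, [1.15 * math.cos(th), 1.15 * math.sin(th), 0],
                      "polymer", serial=i)
            )
        accs = find_acceptors(atoms)
        classes = sorted(a.acceptor_class.value for a in accs)
        assert classes.count("sidechain_N") == 2
        assert classes.count("pi_system") == 1
        centroid = [a for a in accs if a.acceptor_class is AcceptorClass.PI_SYSTEM][0]
        np.testing.assert_allclose(centroid.atom.xyz, [0, 0, 0], atol=1e-12)
        assert all(n in ring_names for n in order)

    def test_census_on_generated_complex_matches_hand_enumeration(self):
        planted = [
            (3.0, 170.0, 130.0, "backbone_carbonyl_O"),
            (3.3, 150.0, None, "water_O"),
            (3.1, 160.0, 120.0, "sidechain_O"),
        ]
        text, _ = build_synthetic_complex(planted, seed=4, decoys=2)
        atoms = parse_structure(text)
        accs = find_acceptors(atoms)
        census = {}
        for a in accs:
            census[a.acceptor_class.value] = census.get(a.acceptor_class.value, 0) + 1
        # hand count: 1 Gly backbone O; Ser contributes OG + its own backbone O;
        # 1 planted water + 2 decoy waters
        assert census == {"backbone_carbonyl_O": 2, "sidechain_O": 1, "water_O": 3}


class TestScanContacts:
    def _planted_atoms(self, d=3.2, theta=170.0):
        x = _atom("BR1", "BR", "LIG", 9, [0.0, 0.0, 0.0], "hetero", serial=1)
        c = _atom("C1", "C", "LIG", 9, [1.9, 0.0, 0.0], "hetero", serial=2)
        th = math.radians(theta)
        acc = _atom(
            "O", "O", "HOH", 77, [d * math.cos(th), d * math.sin(th), 0.0], "water", serial=3
        )
        return [x, c, acc]

    def test_exact_planted_geometry_recovered(self):
        contacts = scan_contacts(self._planted_atoms(3.2, 170.0), ligand_selector="LIG")
        assert len(contacts) == 1
        assert contacts[0].d == pytest.approx(3.2, abs=1e-6)
        assert contacts[0].theta_cxa == pytest.approx(170.0, abs=1e-6)

    def test_acceptor_beyond_threshold_excluded(self):
        contacts = scan_contacts(self._planted_atoms(d=4.5), ligand_selector="LIG")
        assert contacts == []

    def test_threshold_monotone_containment(self):
        text, _ = build_synthetic_complex(
            [(3.2, 160.0, 130.0, "backbone_carbonyl_O"), (3.9, 150.0, None, "water_O")],
            seed=2,
        )
        atoms = parse_structure(text)
        def key(c):
            return (c.site.x_atom.serial, c.acceptor.name, round(c.d, 9))
        small = {key(c) for c in scan_contacts(atoms, 3.5, ligand_selector="LIG")}
        large = {key(c) for c in scan_contacts(atoms, 4.0, ligand_selector="LIG")}
        assert small <= large
        assert len(large) == 2

    def test_rigid_motion_invariance(self, rng):
        text, _ = build_synthetic_complex(
            [(3.1, 155.0, 140.0, "sidechain_N"), (3.4, 165.0, None, "pi_system")], seed=5
        )
        atoms = parse_structure(text)
        ref = scan_contacts(atoms, ligand_selector="LIG")
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-50, 50, 3)
        moved = []
        for a in atoms:
            b = AtomRecord(**{**a.__dict__, "xyz": q @ a.xyz + t})
            moved.append(b)
        out = scan_contacts(moved, ligand_selector="LIG")
        assert len(out) == len(ref)
        for c_ref, c_out in zip(ref, out):
            assert c_out.d == pytest.approx(c_ref.d, abs=1e-9)
            assert c_out.theta_cxa == pytest.approx(c_ref.theta_cxa, abs=1e-9)
            if c_ref.theta_xac is not None:
                assert c_out.theta_xac == pytest.approx(c_ref.theta_xac, abs=1e-9)

    def test_intra_ligand_acceptors_excluded(self):
        # a ligand oxygen next to the halogen must not register as a contact
        atoms = self._planted_atoms()
        atoms.append(_atom("O1", "O", "LIG", 9, [0.0, 3.0, 0.0], "hetero", serial=9))
        contacts = scan_contacts(atoms, ligand_selector="LIG")
        assert {c.acceptor.residue_name for c in contacts} == {"HOH"}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ParameterError):
            scan_contacts(self._planted_atoms(), threshold=-1.0)
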