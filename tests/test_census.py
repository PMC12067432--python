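"""Functional-group census, ALT, gyration radius, SASA, hydrogen bonds."""

import math

import numpy as np
import pytest

from petnano.census import (census, count_alt, count_hbonds,
                            gyration_radius, heaviest_component_mass,
                            hydrophilicity, main_particle_ids, sasa)
from petnano.constants import VDW_RADII
from petnano.core import Atom, MolecularSystem, connected_components, \
    molar_mass

from conftest import make_molecule, water
from oracles import oracle_census, random_molecule

# -- textbook molecules (graph-only) --------------------------------------

METHYL_ACETATE = [  # CH3-CO-O-CH3
    ("C", None, []), ("H", None, [0]), ("H", None, [0]), ("H", None, [0]),
    ("C", None, [0]), ("O", None, [4]),           # carbonyl C, =O
    ("O", None, [4]),                             # bridging O
    ("C", None, [6]), ("H", None, [7]), ("H", None, [7]), ("H", None, [7]),
]
ACETIC_ACID = [  # CH3-COOH
    ("C", None, []), ("H", None, [0]), ("H", None, [0]), ("H", None, [0]),
    ("C", None, [0]), ("O", None, [4]), ("O", None, [4]), ("H", None, [6]),
]
ETHANOL = [
    ("C", None, []), ("H", None, [0]), ("H", None, [0]), ("H", None, [0]),
    ("C", None, [0]), ("H", None, [4]), ("H", None, [4]),
    ("O", None, [4]), ("H", None, [7]),
]
ACETALDEHYDE = [  # CH3-CHO
    ("C", None, []), ("H", None, [0]), ("H", None, [0]), ("H", None, [0]),
    ("C", None, [0]), ("O", None, [4]), ("H", None, [4]),
]
ACETONE = [  # CH3-CO-CH3
    ("C", None, []), ("H", None, [0]), ("H", None, [0]), ("H", None, [0]),
    ("C", None, [0]), ("O", None, [4]),
    ("C", None, [4]), ("H", None, [6]), ("H", None, [6]), ("H", None, [6]),
]
OXIRANE = [  # c(CH2-CH2-O) three-ring
    ("C", None, []), ("H", None, [0]), ("H", None, [0]),
    ("C", None, [0]), ("H", None, [3]), ("H", None, [3]),
    ("O", None, [0, 3]),
]


class TestGroupPerception:
    @pytest.mark.parametrize("spec, expected", [
        (METHYL_ACETATE, {"EST": 1}),
        (ACETIC_ACID, {"COOH": 1, "OH": 0}),
        (ETHANOL, {"OH": 1}),
        (ACETALDEHYDE, {"CHO": 1}),
        (ACETONE, {"CO": 1}),
        (OXIRANE, {"R3": 1}),
    ], ids=["ester", "carboxyl", "hydroxyl", "aldehyde", "ketone",
            "epoxide"])
    def test_textbook_groups(self, spec, expected):
        report = census(make_molecule(spec)).as_dict()
        for key, value in expected.items():
            assert report[key] == value, key
        # everything else is zero
        for key in ("EST", "OH", "CHO", "COOH", "CO", "R3", "R4", "R5",
                    "R6", "N_Ow"):
            if key not in expected:
                assert report[key] == 0, key

    def test_census_matches_exhaustive_oracle_on_random_molecules(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            mol = random_molecule(rng)
            expected = oracle_census(mol)
            got = census(mol).as_dict()
            for key, value in expected.items():
                assert got[key] == value, (key, expected, got)

    def test_empty_system_rejected(self):
        with pytest.raises(ValueError):
            census(MolecularSystem())


class TestAlt:
    def test_identity_is_zero(self):
        mol = make_molecule(ETHANOL)
        assert count_alt(mol, mol) == 0

    def test_deleting_one_bond_alters_both_endpoints(self):
        mol = make_molecule(ETHANOL)
        edited = mol.copy()
        edited.remove_bond(4, 7)   # the C-O bond
        assert count_alt(edited, mol) == 2

    def test_random_edit_script_matches_recomputation(self):
        rng = np.random.default_rng(3)
        mol = random_molecule(rng, max_heavy=10)
        edited = mol.copy()
        edges = list(edited.graph.edges)
        rng.shuffle(edges)
        for edge in edges[:3]:
            edited.remove_bond(*edge)
        expected = sum(
            1 for i in edited.ids()
            if edited.neighbor_elements(i) != mol.neighbor_elements(i))
        assert count_alt(edited, mol) == expected


class TestComponentsMetrics:
    def test_heaviest_component_mass_composition(self, chain100):
        assert heaviest_component_mass(chain100) == pytest.approx(
            molar_mass(connected_components(chain100)[0], chain100))

    def test_detaching_fragment_decreases_mass(self):
        mol = make_molecule(METHYL_ACETATE)
        before = heaviest_component_mass(mol)
        mol.remove_bond(6, 7)  # split off the methoxy methyl
        assert heaviest_component_mass(mol) < before

    def test_main_particle_keeps_equal_chains(self, particle_small):
        assert main_particle_ids(particle_small) == set(particle_small.ids())


class TestGyrationRadius:
    def test_single_atom_zero(self):
        one = MolecularSystem([Atom(0, "C", np.array([1.0, 2.0, 3.0]))])
        assert gyration_radius(one) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses(self):
        pair = MolecularSystem([Atom(0, "C", np.zeros(3)),
                                Atom(1, "C", np.array([1.0, 0, 0]))])
        assert gyration_radius(pair) == pytest.approx(0.5)

    def test_random_cloud_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        atoms = [Atom(i, rng.choice(["C", "O", "H"]), rng.normal(size=3))
                 for i in range(50)]
        system = MolecularSystem(atoms)
        coords = system.positions()
        masses = system.masses()
        com = (coords * masses[:, None]).sum(0) / masses.sum()
        expected = math.sqrt(
            (masses * ((coords - com) ** 2).sum(1)).sum() / masses.sum())
        assert gyration_radius(system) == pytest.approx(expected)


class TestSasa:
    @pytest.mark.parametrize("element", ["C", "O", "H"])
    def test_isolated_sphere_closed_form(self, element):
        system = MolecularSystem([Atom(0, element, np.zeros(3))])
        r = VDW_RADII[element] + 0.14
        expected = 4 * math.pi * r * r * 100.0
        assert sasa(system) == pytest.approx(expected, rel=0.01)

    def test_distant_spheres_are_additive(self):
        a = MolecularSystem([Atom(0, "C", np.zeros(3))])
        pair = MolecularSystem([Atom(0, "C", np.zeros(3)),
                                Atom(1, "C", np.array([5.0, 0, 0]))])
        assert sasa(pair) == pytest.approx(2 * sasa(a), rel=1e-9)

    def test_fused_dimer_converges_with_resolution(self):
        pair = MolecularSystem([Atom(0, "C", np.zeros(3)),
                                Atom(1, "C", np.array([0.25, 0, 0]))])
        coarse = sasa(pair, n_points=960)
        fine = sasa(pair, n_points=9600)
        assert coarse == pytest.approx(fine, rel=0.01)


class TestHydrogenBonds:
    def test_ideal_water_dimer(self):
        donor = water()
        acceptor = water(offset=(0.29, 0.0, 0.0), start_id=10)
        assert count_hbonds(donor, acceptor) == 1

    def test_long_distance_no_bond(self):
        donor = water()
        acceptor = water(offset=(0.40, 0.0, 0.0), start_id=10)
        assert count_hbonds(donor, acceptor) == 0

    def test_random_box_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(17)
        solute = water()
        waters = MolecularSystem()
        for k in range(12):
            w = water(offset=rng.uniform(-0.5, 0.5, 3), start_id=10 * k)
            for atom in w:
                waters.add_atom(atom)
            for i, j in w.graph.edges:
                waters.add_bond(i, j)
        expected = _brute_force_hbonds(solute, waters)
        assert count_hbonds(solute, waters) == expected


def _brute_force_hbonds(a, b, cutoff=0.35, angle=30.0):
    count = 0
    for donor_sys, acc_sys in ((a, b), (b, a)):
        for d, atom in donor_sys.atoms.items():
            if atom.element != "O":
                continue
            hs = [j for j in donor_sys.neighbors(d)
                  if donor_sys.atoms[j].element == "H"]
            for acc, acc_atom in acc_sys.atoms.items():
                if acc_atom.element != "O":
                    continue
                da = acc_atom.position - atom.position
                if np.linalg.norm(da) > cutoff or np.linalg.norm(da) < 1e-9:
                    continue
                for h in hs:
                    dh = donor_sys.atoms[h].position - atom.position
                    cos = dh @ da / (np.linalg.norm(dh) * np.linalg.norm(da))
                    if math.degrees(math.acos(np.clip(cos, -1, 1))) <= angle:
                        count += 1
    return count


class TestHydrophilicity:
    def test_zero_energy_gives_zero_index(self):
        metrics = hydrophilicity(water(), 0.0, 100.0, 5)
        assert metrics.energy_per_area == 0.0
        assert metrics.hbonds_per_area == pytest.approx(0.05)

    def test_doubling_area_halves_indices(self):
        m1 = hydrophilicity(water(), -500.0, 100.0, 10)
        m2 = hydrophilicity(water(), -500.0, 200.0, 10)
        assert m2.energy_per_area == pytest.approx(m1.energy_per_area / 2)
        assert m2.hbonds_per_area == pytest.approx(m1.hbonds_per_area / 2)

    def test_fixture_values_hand_checked(self):
        metrics = hydrophilicity(water(), -16398.0, 13121.0, 250)
        assert metrics.energy_per_area == pytest.approx(-1.2498, abs=1e-3)
        assert metrics.hbonds_per_area == pytest.approx(0.01905, abs=1e-4)
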