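"""Structure records, bond perception, components, masses and file I/O."""

import numpy as np
import pytest

from petnano.constants import COVALENT_RADII
from petnano.core import (Atom, MolecularSystem, connected_components,
                          molar_mass, perceive_bonds)
from petnano.io import (read_pdb, read_pdb_header, read_reax_bonds,
                        read_system, write_pdb, write_system)

from conftest import make_molecule, water


class TestAtomsAndSystems:
    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="element"):
            Atom(0, "Xx", np.zeros(3))

    def test_duplicate_ids_rejected(self):
        system = MolecularSystem()
        system.add_atom(Atom(0, "C", np.zeros(3)))
        with pytest.raises(ValueError, match="duplicate"):
            system.add_atom(Atom(0, "O", np.ones(3)))

    def test_self_bond_rejected(self):
        system = water()
        with pytest.raises(ValueError, match="self"):
            system.add_bond(0, 0)

    def test_bond_to_missing_atom_rejected(self):
        system = water()
        with pytest.raises(ValueError, match="unknown"):
            system.add_bond(0, 99)


class TestBondPerception:
    def test_oh_bonded_cc_not(self):
        sys_oh = make_molecule([("O", (0, 0, 0), []),
                                ("H", (0.096, 0, 0), [])])
        assert perceive_bonds(sys_oh).has_edge(0, 1)
        sys_cc = make_molecule([("C", (0, 0, 0), []),
                                ("C", (0.5, 0, 0), [])])
        assert perceive_bonds(sys_cc).number_of_edges() == 0

    def test_overlapping_atoms_error(self):
        bad = make_molecule([("C", (0, 0, 0), []), ("C", (0.01, 0, 0), [])])
        with pytest.raises(ValueError, match="overlap"):
            perceive_bonds(bad)

    def test_ethanol_has_eight_bonds(self):
        # CH3-CH2-OH with idealised coordinates, 9 atoms
        coords = [
            ("C", (0.000, 0.000, 0.000)),
            ("C", (0.152, 0.000, 0.000)),
            ("O", (0.210, 0.130, 0.000)),
            ("H", (-0.040, -0.060, 0.085)),
            ("H", (-0.040, -0.060, -0.085)),
            ("H", (-0.040, 0.100, 0.000)),
            ("H", (0.195, -0.055, 0.087)),
            ("H", (0.195, -0.055, -0.087)),
            ("H", (0.300, 0.128, 0.030)),
        ]
        system = make_molecule([(e, p, []) for e, p in coords])
        graph = perceive_bonds(system)
        assert graph.number_of_edges() == 8
        assert graph.number_of_edges() == _brute_force_bonds(system)

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(5, 40)
            elements = rng.choice(["C", "H", "O", "N"], size=n)
            coords = rng.uniform(0, 1.0, size=(n, 3))
            system = MolecularSystem(
                Atom(i, e, c) for i, (e, c) in enumerate(zip(elements, coords)))
            try:
                graph = perceive_bonds(system)
            except ValueError:
                continue  # overlapping random pair
            assert graph.number_of_edges() == _brute_force_bonds(system)


def _brute_force_bonds(system, tolerance=1.2):
    ids = system.ids()
    count = 0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            d = np.linalg.norm(system.atoms[i].position
                               - system.atoms[j].position)
            cut = tolerance * (COVALENT_RADII[system.atoms[i].element]
                               + COVALENT_RADII[system.atoms[j].element])
            count += d <= cut
    return count


class TestComponentsAndMass:
    def test_two_waters_two_components(self):
        system = water()
        far = water(offset=(5, 5, 5), start_id=3)
        for atom in far:
            system.add_atom(atom)
        for i, j in far.graph.edges:
            system.add_bond(i, j)
        comps = connected_components(system)
        assert [len(c) for c in comps] == [3, 3]

    def test_bonded_chain_single_component(self):
        chain = make_molecule([("C", None, []), ("C", None, [0]),
                               ("C", None, [1]), ("C", None, [2])])
        assert len(connected_components(chain)) == 1

    def test_partition_and_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        system = MolecularSystem(
            Atom(i, "C", rng.normal(size=3)) for i in range(30))
        for _ in range(25):
            i, j = rng.integers(0, 30, size=2)
            if i != j:
                system.add_bond(int(i), int(j))
        comps = connected_components(system)
        assert sorted(i for c in comps for i in c) == system.ids()
        # flood-fill oracle
        seen = {}
        for start in system.ids():
            if start in seen:
                continue
            stack, group = [start], set()
            while stack:
                node = stack.pop()
                if node in group:
                    continue
                group.add(node)
                stack.extend(system.neighbors(node))
            for i in group:
                seen[i] = frozenset(group)
        assert {frozenset(c) for c in comps} == set(seen.values())
        assert sum(molar_mass(c, system) for c in comps) == pytest.approx(
            molar_mass(system.ids(), system))

    @pytest.mark.parametrize("formula, expected", [
        ({"H": 2, "O": 1}, 18.015),
        ({"C": 1, "O": 2}, 44.009),
    ])
    def test_molar_mass_small_molecules(self, formula, expected):
        atoms = []
        i = 0
        for element, count in formula.items():
            for _ in range(count):
                atoms.append(Atom(i, element, np.zeros(3)))
                i += 1
        system = MolecularSystem(atoms)
        assert molar_mass(system.ids(), system) == pytest.approx(expected,
                                                                 abs=1e-3)


class TestPdbIO:
    def test_minimal_single_atom_record(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1      11.000  22.000  33.000"
            "  1.00  0.00           C\n")
        system = read_pdb(path)
        assert len(system) == 1
        atom = system.atoms[0]
        assert atom.element == "C"
        assert atom.residue_index == 1
        np.testing.assert_allclose(atom.position, [1.1, 2.2, 3.3])

    def test_roundtrip_preserves_atoms_and_residues(self, tmp_path):
        system = water()
        for atom in system:
            atom.residue_index = 7
            atom.residue_name = "HOH"
        path = tmp_path / "w.pdb"
        write_pdb(system, path)
        back = read_pdb(path)
        assert len(back) == 3
        for a, b in zip(system, back):
            assert a.element == b.element
            assert b.residue_index == 7
            np.testing.assert_allclose(a.position, b.position, atol=5e-5)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  CA  ALA A   1      xx.000  22.000"
                        "  33.000  1.00  0.00           C\n")
        with pytest.raises(ValueError, match="line 1"):
            read_pdb(path)

    def test_empty_system_gives_header_only_file(self, tmp_path):
        path = tmp_path / "empty.pdb"
        write_pdb(MolecularSystem(), path)
        lines = path.read_text().splitlines()
        assert not any(ln.startswith(("ATOM", "HETATM")) for ln in lines)

    def test_synthetic_header_counts(self, synthetic_hsa_pdb):
        header = read_pdb_header(synthetic_hsa_pdb)
        assert header.seqres_residue_count == 585
        assert header.n_ssbond == 17
        system = read_pdb(synthetic_hsa_pdb)
        assert system.header.seqres_residue_count == 585


class TestNativeFormat:
    def test_roundtrip_with_charges_and_origins(self, tmp_path):
        system = water()
        system.atoms[0].charge = -0.8
        system.atoms[0].origin = "water"
        path = tmp_path / "sys.txt"
        write_system(system, path)
        back = read_system(path)
        assert back.atoms[0].charge == pytest.approx(-0.8)
        assert back.atoms[0].origin == "water"
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, system.graph.edges))


class TestReaxBonds:
    def _write(self, tmp_path, body):
        path = tmp_path / "bonds.reaxff"
        path.write_text(body)
        return path

    def test_two_atom_bond_above_threshold(self, tmp_path):
        path = self._write(tmp_path, (
            "# Timestep 0\n"
            "1 1 1 2 1 0.5 0.5 0 -0.2\n"
            "2 1 1 1 1 0.5 0.5 0 0.2\n"))
        frames = read_reax_bonds(path)
        assert len(frames) == 1
        graph, charges = frames[0]
        assert graph.has_edge(1, 2)
        assert charges[1] == pytest.approx(-0.2)

    def test_low_order_bond_dropped(self, tmp_path):
        path = self._write(tmp_path, (
            "# Timestep 0\n"
            "1 1 1 2 1 0.2 0.2 0 0.0\n"
            "2 1 1 1 1 0.2 0.2 0 0.0\n"))
        graph, _ = read_reax_bonds(path)[0]
        assert graph.number_of_edges() == 0

    def test_water_box_two_bonds_per_molecule(self, tmp_path):
        # two waters: atoms 1-3 and 4-6
        lines = ["# Timestep 100"]
        for o, h1, h2 in ((1, 2, 3), (4, 5, 6)):
            lines.append(f"{o} 2 2 {h1} {h2} 1 0.9 0.9 1.8 0 -0.7")
            lines.append(f"{h1} 1 1 {o} 1 0.9 0.9 0 0.35")
            lines.append(f"{h2} 1 1 {o} 1 0.9 0.9 0 0.35")
        path = self._write(tmp_path, "\n".join(lines) + "\n")
        graph, charges = read_reax_bonds(path)[0]
        assert graph.number_of_edges() == 4
        assert charges[1] == pytest.approx(-0.7)

    def test_asymmetric_listing_kept_with_warning(self, tmp_path, caplog):
        path = self._write(tmp_path, (
            "# Timestep 0\n"
            "1 1 1 2 1 0.6 0.6 0 0.0\n"
            "2 1 0 1 0 0.0\n"))
        with caplog.at_level("WARNING"):
            graph, _ = read_reax_bonds(path)[0]
        assert graph.has_edge(1, 2)
        assert any("asymmetric" in rec.message for rec in caplog.records)
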