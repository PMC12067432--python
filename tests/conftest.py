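"""Shared fixtures: small molecules, pristine particles, synthetic PDB."""

from __future__ import annotations

import numpy as np
import pytest

from petnano.builder import ChainSpec, assemble_nanoparticle, build_pet_chain
from petnano.core import Atom, MolecularSystem

# twenty standard residue names, reused cyclically for the synthetic header
_RESIDUES = ("ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
             "LEU LYS MET PHE PRO SER THR TRP TYR VAL").split()


def make_molecule(spec):
    """Build a MolecularSystem from a compact spec.

    ``spec`` is a list of (element, position, bonded-to-indices) tuples;
    positions may be None for graph-only molecules.
    """
    system = MolecularSystem()
    for i, (element, pos, bonds) in enumerate(spec):
        system.add_atom(Atom(id=i, element=element,
                             position=np.zeros(3) if pos is None
                             else np.asarray(pos, dtype=float)))
    for i, (_e, _p, bonds) in enumerate(spec):
        for j in bonds:
            if not system.graph.has_edge(i, j):
                system.add_bond(i, j)
    return system


def water(offset=(0.0, 0.0, 0.0), start_id=0):
    """One water molecule (O-H 0.096 nm)."""
    system = MolecularSystem()
    off = np.asarray(offset, dtype=float)
    system.add_atom(Atom(start_id, "O", off))
    system.add_atom(Atom(start_id + 1, "H", off + [0.096, 0.0, 0.0]))
    system.add_atom(Atom(start_id + 2, "H", off + [-0.024, 0.093, 0.0]))
    system.add_bond(start_id, start_id + 1)
    system.add_bond(start_id, start_id + 2)
    return system


@pytest.fixture(scope="session")
def chain100():
    return build_pet_chain(ChainSpec(100))


@pytest.fixture(scope="session")
def particle_small(chain100):
    return assemble_nanoparticle(
        [build_pet_chain(ChainSpec(100)) for _ in range(2)], seed=7)


@pytest.fixture(scope="session")
def particle_large():
    return assemble_nanoparticle(
        [build_pet_chain(ChainSpec(100)) for _ in range(4)], seed=7)


@pytest.fixture()
def synthetic_hsa_pdb(tmp_path):
    """Synthetic albumin-like PDB header: 585 SEQRES residues, 17 SSBOND.

    A stand-in for the real deposited albumin entry (not downloadable in
    this offline environment): realistic SEQRES/SSBOND/ATOM record layout
    with a synthetic residue sequence.
    """
    n_res = 585
    residues = [_RESIDUES[i % len(_RESIDUES)] for i in range(n_res)]
    lines = ["HEADER    TRANSPORT PROTEIN (SYNTHETIC STAND-IN)"]
    for serial, start in enumerate(range(0, n_res, 13), start=1):
        chunk = residues[start:start + 13]
        lines.append(f"SEQRES {serial:>3} A {n_res:>4}  " + " ".join(chunk))
    for k in range(17):
        r1, r2 = 50 + 30 * k, 60 + 30 * k
        lines.append(
            f"SSBOND {k + 1:>3} CYS A {r1:>4}    CYS A {r2:>4}")
    for i in range(5):
        x = 1.0 + 0.5 * i
        lines.append(
            f"ATOM  {i + 1:>5}  CA {residues[i]:>4} A{i + 1:>4}    "
            f"{x:8.3f}{2.0:8.3f}{3.0:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {'C':>2}")
    lines.append("END")
    path = tmp_path / "synthetic_hsa_header.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
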