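"""File I/O: PDB, the package-native system format, and ReaxFF bond tables.

Only the fixed-column subset of PDB needed here (ATOM/HETATM, SEQRES,
SSBOND) is handled; coordinates are converted from Angstrom to nm at this
boundary. The native format is a plain-text atom list plus a bond section,
so degraded systems with charges and provenance survive a round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np

from .constants import SUPPORTED_ELEMENTS
from .core import Atom, MolecularSystem

log = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0


@dataclass
class PDBHeader:
    """Header facts parsed from SEQRES and SSBOND records."""

    seqres_counts: Dict[str, int]
    n_ssbond: int

    @property
    def seqres_residue_count(self) -> int:
        return sum(self.seqres_counts.values())


def _element_from_record(line: str, lineno: int) -> str:
    symbol = line[76:78].strip() if len(line) >= 78 else ""
    if not symbol:
        # fall back on the atom-name column
        name = line[12:16].strip()
        symbol = "".join(c for c in name if c.isalpha())[:1]
    symbol = symbol.capitalize()
    if symbol not in SUPPORTED_ELEMENTS:
        raise ValueError(f"line {lineno}: unknown element {symbol!r}")
    return symbol


def read_pdb_header(path) -> PDBHeader:
    """Parse SEQRES residue counts per chain and the SSBOND record count."""
    counts: Dict[str, int] = {}
    n_ssbond = 0
    with open(path) as handle:
        for line in handle:
            record = line[:6].strip()
            if record == "SEQRES":
                chain = line[11].strip() or "_"
                if chain not in counts:
                    counts[chain] = int(line[13:17])
            elif record == "SSBOND":
                n_ssbond += 1
    return PDBHeader(seqres_counts=counts, n_ssbond=n_ssbond)


def read_pdb(path) -> MolecularSystem:
    """Read ATOM/HETATM records into a :class:`MolecularSystem`.

    Atoms receive ``origin='protein'``, zero charge, residue index and
    name, and coordinates in nm. The returned system carries the parsed
    :class:`PDBHeader` as ``system.header``.
    """
    system = MolecularSystem()
    next_id = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"line {lineno}: truncated {record} record")
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                res_index = int(line[22:26])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: malformed {record} record: {exc}") from None
            element = _element_from_record(line, lineno)
            system.add_atom(Atom(
                id=next_id,
                element=element,
                position=np.array([x, y, z]) / ANGSTROM_PER_NM,
                charge=0.0,
                origin="protein",
                residue_index=res_index,
                residue_name=line[17:20].strip() or None,
            ))
            next_id += 1
    system.header = read_pdb_header(path)
    return system


def write_pdb(system: MolecularSystem, path) -> None:
    """Write a system as PDB ATOM records (3-decimal Angstrom)."""
    with open(path, "w") as handle:
        handle.write("REMARK generated by petnano\n")
        for serial, i in enumerate(system.ids(), start=1):
            atom = system.atoms[i]
            x, y, z = atom.position * ANGSTROM_PER_NM
            name = atom.element
            resname = (atom.residue_name or "UNK")[:3]
            resid = atom.residue_index if atom.residue_index is not None else 1
            record = "ATOM" if atom.origin == "protein" else "HETATM"
            handle.write(
                f"{record:<6}{serial % 100000:>5} {name:<4}{resname:>4} A"
                f"{resid % 10000:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2}\n")
        handle.write("END\n")


# -- native system format -------------------------------------------------


def write_system(system: MolecularSystem, path) -> None:
    """Write the native text format: one atom per line plus a bond section."""
    with open(path, "w") as handle:
        handle.write("# petnano system v1\n")
        if system.box is not None:
            handle.write("box %.6f %.6f %.6f\n" % tuple(system.box))
        ids = system.ids()
        handle.write(f"atoms {len(ids)}\n")
        for i in ids:
            a = system.atoms[i]
            line = (f"{i} {a.element} {a.position[0]:.6f} {a.position[1]:.6f} "
                    f"{a.position[2]:.6f} {a.charge:.6f} {a.origin}")
            if a.residue_index is not None:
                line += f" {a.residue_index} {a.residue_name or 'UNK'}"
            handle.write(line + "\n")
        edges = list(system.graph.edges(data=True))
        handle.write(f"bonds {len(edges)}\n")
        for i, j, data in edges:
            if data.get("order") is not None:
                handle.write(f"{i} {j} {data['order']:.4f}\n")
            else:
                handle.write(f"{i} {j}\n")


def read_system(path) -> MolecularSystem:
    """Read the native text format written by :func:`write_system`."""
    system = MolecularSystem()
    with open(path) as handle:
        lines = [ln.strip() for ln in handle
                 if ln.strip() and not ln.startswith("#")]
    pos = 0
    if lines and lines[0].startswith("box "):
        system.box = np.array([float(v) for v in lines[0].split()[1:4]])
        pos += 1
    if pos >= len(lines) or not lines[pos].startswith("atoms "):
        raise ValueError(f"{path}: missing 'atoms' section")
    n_atoms = int(lines[pos].split()[1])
    pos += 1
    for line in lines[pos:pos + n_atoms]:
        parts = line.split()
        atom = Atom(
            id=int(parts[0]),
            element=parts[1],
            position=np.array([float(parts[2]), float(parts[3]), float(parts[4])]),
            charge=float(parts[5]),
            origin=parts[6],
            residue_index=int(parts[7]) if len(parts) > 7 else None,
            residue_name=parts[8] if len(parts) > 8 else None,
        )
        system.add_atom(atom)
    pos += n_atoms
    if pos >= len(lines) or not lines[pos].startswith("bonds "):
        raise ValueError(f"{path}: missing 'bonds' section")
    n_bonds = int(lines[pos].split()[1])
    pos += 1
    for line in lines[pos:pos + n_bonds]:
        parts = line.split()
        order = float(parts[2]) if len(parts) > 2 else None
        system.add_bond(int(parts[0]), int(parts[1]), order)
    return system


# -- LAMMPS ReaxFF bond tables --------------------------------------------


def read_reax_bonds(path, bond_order_threshold: float = 0.3
                    ) -> List[Tuple[nx.Graph, Dict[int, float]]]:
    """Read a LAMMPS ``reaxff/bonds`` file into per-frame bond graphs.

    Each per-atom line lists ``id type nb`` followed by ``nb`` neighbour
    ids, a molecule id, ``nb`` bond orders, then abo, nlp and the charge.
    An edge is kept when the bond order reaches the threshold on either
    side; an asymmetric neighbour listing is kept with a warning.

    Returns a list of ``(graph, charges)`` pairs, one per timestep.
    """
    frames: List[Tuple[nx.Graph, Dict[int, float]]] = []
    records: Dict[int, Tuple[List[int], List[float], float]] = {}

    def close_frame() -> None:
        if not records:
            return
        graph = nx.Graph()
        graph.add_nodes_from(records)
        charges = {i: rec[2] for i, rec in records.items()}
        passing: Dict[Tuple[int, int], float] = {}
        listed: set = set()
        for i, (nbrs, orders, _q) in records.items():
            for j, bo in zip(nbrs, orders):
                key = (min(i, j), max(i, j))
                listed.add((i, j))
                if bo >= bond_order_threshold:
                    passing[key] = max(passing.get(key, 0.0), bo)
        for (i, j), bo in passing.items():
            if (j, i) not in listed or (i, j) not in listed:
                log.warning("asymmetric neighbour listing for bond (%d, %d); "
                            "kept (order %.3f)", i, j, bo)
            graph.add_edge(i, j, order=bo)
        frames.append((graph, charges))
        records.clear()

    with open(path) as handle:
        for line in handle:
            if line.startswith("#"):
                if "Timestep" in line:
                    close_frame()
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            atom_id, _atype, nb = int(parts[0]), parts[1], int(parts[2])
            nbrs = [int(v) for v in parts[3:3 + nb]]
            orders = [float(v) for v in parts[4 + nb:4 + 2 * nb]]
            charge = float(parts[-1])
            records[atom_id] = (nbrs, orders, charge)
    close_frame()
    return frames
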