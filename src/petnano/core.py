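"""Core structure records: atoms, bond graphs, molecular systems, trajectories.

A :class:`MolecularSystem` couples a list of :class:`Atom` records with an
undirected bond graph (a :class:`networkx.Graph` over persistent atom ids).
Atom ids are never reindexed by edits; provenance (``origin``) and the
altered-neighbourhood counter depend on that stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .constants import (ATOMIC_WEIGHTS, BOND_TOLERANCE, COVALENT_RADII,
                        OVERLAP_DISTANCE, SUPPORTED_ELEMENTS)

ORIGINS = ("polymer", "water", "protein", "other")


@dataclass
class Atom:
    """A single atom with persistent id and provenance.

    Positions are in nm, charges in elementary-charge units. ``origin``
    records where the atom came from (e.g. water-derived oxygens on a
    degraded nanoparticle surface) and is treated as immutable.
    """

    id: int
    element: str
    position: np.ndarray
    charge: float = 0.0
    origin: str = "other"
    residue_index: Optional[int] = None
    residue_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")

    @property
    def mass(self) -> float:
        return ATOMIC_WEIGHTS[self.element]


class MolecularSystem:
    """Atoms plus an undirected bond graph over their ids."""

    def __init__(self, atoms: Iterable[Atom] = (),
                 bonds: Optional[nx.Graph] = None,
                 box: Optional[Sequence[float]] = None):
        self.atoms: Dict[int, Atom] = {}
        for atom in atoms:
            if atom.id in self.atoms:
                raise ValueError(f"duplicate atom id {atom.id}")
            self.atoms[atom.id] = atom
        self.graph: nx.Graph = nx.Graph()
        self.graph.add_nodes_from(self.atoms)
        if bonds is not None:
            for i, j, data in bonds.edges(data=True):
                self.add_bond(i, j, data.get("order"))
        self.box = None if box is None else np.asarray(box, dtype=float)

    # -- construction ---------------------------------------------------

    def add_atom(self, atom: Atom) -> None:
        if atom.id in self.atoms:
            raise ValueError(f"duplicate atom id {atom.id}")
        self.atoms[atom.id] = atom
        self.graph.add_node(atom.id)

    def add_bond(self, i: int, j: int, order: Optional[float] = None) -> None:
        if i == j:
            raise ValueError("self-bonds are not allowed")
        if i not in self.atoms or j not in self.atoms:
            raise ValueError(f"bond ({i}, {j}) references unknown atom ids")
        if order is None:
            self.graph.add_edge(i, j)
        else:
            self.graph.add_edge(i, j, order=float(order))

    def remove_bond(self, i: int, j: int) -> None:
        self.graph.remove_edge(i, j)

    def remove_atom(self, i: int) -> None:
        self.graph.remove_node(i)
        del self.atoms[i]

    def next_id(self) -> int:
        return max(self.atoms, default=-1) + 1

    # -- views -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms.values())

    def ids(self) -> List[int]:
        return sorted(self.atoms)

    def positions(self, ids: Optional[Sequence[int]] = None) -> np.ndarray:
        sel = self.ids() if ids is None else list(ids)
        return np.array([self.atoms[i].position for i in sel], dtype=float)

    def set_positions(self, coords: np.ndarray,
                      ids: Optional[Sequence[int]] = None) -> None:
        sel = self.ids() if ids is None else list(ids)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(sel), 3):
            raise ValueError("coordinate array shape mismatch")
        for i, xyz in zip(sel, coords):
            self.atoms[i].position = xyz.copy()

    def elements(self, ids: Optional[Sequence[int]] = None) -> List[str]:
        sel = self.ids() if ids is None else list(ids)
        return [self.atoms[i].element for i in sel]

    def charges(self, ids: Optional[Sequence[int]] = None) -> np.ndarray:
        sel = self.ids() if ids is None else list(ids)
        return np.array([self.atoms[i].charge for i in sel], dtype=float)

    def masses(self, ids: Optional[Sequence[int]] = None) -> np.ndarray:
        sel = self.ids() if ids is None else list(ids)
        return np.array([self.atoms[i].mass for i in sel], dtype=float)

    def neighbors(self, i: int) -> List[int]:
        return list(self.graph.neighbors(i))

    def neighbor_elements(self, i: int) -> Tuple[str, ...]:
        """Sorted multiset of neighbour element symbols of atom ``i``."""
        return tuple(sorted(self.atoms[j].element for j in self.graph.neighbors(i)))

    def degree(self, i: int) -> int:
        return self.graph.degree(i)

    def copy(self) -> "MolecularSystem":
        new = MolecularSystem()
        for atom in self.atoms.values():
            new.add_atom(replace(atom, position=atom.position.copy()))
        for i, j, data in self.graph.edges(data=True):
            new.add_bond(i, j, data.get("order"))
        new.box = None if self.box is None else self.box.copy()
        return new

    def subsystem(self, ids: Iterable[int]) -> "MolecularSystem":
        keep = set(ids)
        new = MolecularSystem()
        for i in sorted(keep):
            atom = self.atoms[i]
            new.add_atom(replace(atom, position=atom.position.copy()))
        for i, j, data in self.graph.edges(data=True):
            if i in keep and j in keep:
                new.add_bond(i, j, data.get("order"))
        return new

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        for i in self.graph.nodes:
            if i not in self.atoms:
                raise ValueError(f"graph node {i} has no atom record")
        for i, j in self.graph.edges:
            if i == j:
                raise ValueError("self-bond found")
        coords = self.positions()
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed set of persistent atom ids."""

    atom_ids: List[int]
    frames: List[np.ndarray] = field(default_factory=list)
    metadata: List[dict] = field(default_factory=list)

    def append(self, coords: np.ndarray, **meta) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atom_ids), 3):
            raise ValueError("frame shape does not match atom id set")
        self.frames.append(coords)
        self.metadata.append(meta)

    def __len__(self) -> int:
        return len(self.frames)


# -- graph-level operations ----------------------------------------------


def perceive_bonds(system: MolecularSystem,
                   tolerance: float = BOND_TOLERANCE) -> nx.Graph:
    """Distance-based bond perception.

    Two atoms are bonded iff their separation is at most ``tolerance``
    times the sum of their covalent radii. Overlapping atoms (closer than
    0.03 nm) are rejected as a malformed geometry.
    """
    ids = system.ids()
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    if len(ids) < 2:
        return graph
    coords = system.positions(ids)
    radii = np.array([COVALENT_RADII[system.atoms[i].element] for i in ids])
    max_cut = tolerance * 2.0 * radii.max()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    if pairs.size:
        dist = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        if (dist < OVERLAP_DISTANCE).any():
            a, b = pairs[dist.argmin()]
            raise ValueError(
                f"overlapping atoms {ids[a]} and {ids[b]} at {dist.min():.4f} nm")
        cut = tolerance * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
        for (a, b), ok in zip(pairs, dist <= cut):
            if ok:
                graph.add_edge(ids[a], ids[b])
    return graph


def connected_components(system: MolecularSystem) -> List[Set[int]]:
    """Connected components of the bond graph, heaviest first."""
    comps = [set(c) for c in nx.connected_components(system.graph)]
    comps.sort(key=lambda c: (-sum(system.atoms[i].mass for i in c), min(c)))
    return comps


def molar_mass(ids: Iterable[int], system: MolecularSystem) -> float:
    """Sum of standard atomic weights over ``ids``, g/mol."""
    return float(sum(system.atoms[i].mass for i in ids))
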