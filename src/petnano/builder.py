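"""Pristine PET chains and multi-chain nanoparticles.

A chain is grown monomer by monomer from an idealized repeat-unit
template (-O-CH2-CH2-O-CO-C6H4-CO-), giving an extended, clash-free
geometry and an explicit bond graph. Nanoparticle assembly replaces the
MD folding step with a deterministic geometric collapse: monomers are
placed on a boustrophedon walk through a sphere-clipped grid and residual
clashes are removed by an iterative push-apart. The collapsed geometry
feeds only geometric observables (gyration radius, SASA, the rigid-body
scan); the chemistry lives in the bond graph, which assembly never touches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import Atom, MolecularSystem

TERMINATIONS = ("bis_glycol", "acid_glycol")

#: Repeat-unit period along the chain axis, nm.
MONOMER_PERIOD = 1.00

#: Minimum interatomic separation enforced after assembly, nm.
MIN_SEPARATION = 0.15

# Idealized repeat-unit template: (name, element, xyz in nm).
# Backbone runs along +x; the benzene ring lies in the xz plane.
_UNIT_TEMPLATE: List[Tuple[str, str, Tuple[float, float, float]]] = [
    ("O_a", "O", (0.00, 0.00, 0.000)),
    ("C1", "C", (0.10, 0.10, 0.000)),
    ("H1a", "H", (0.10, 0.145, 0.095)),
    ("H1b", "H", (0.10, 0.145, -0.095)),
    ("C2", "C", (0.21, 0.00, 0.000)),
    ("H2a", "H", (0.21, -0.045, 0.095)),
    ("H2b", "H", (0.21, -0.045, -0.095)),
    ("O_b", "O", (0.31, 0.10, 0.000)),
    ("C3", "C", (0.44, 0.10, 0.000)),
    ("O_c", "O", (0.50, 0.21, 0.000)),
    ("Car1", "C", (0.53, -0.02, 0.000)),
    ("Car2", "C", (0.60, -0.02, 0.120)),
    ("Har2", "H", (0.545, -0.02, 0.214)),
    ("Car3", "C", (0.74, -0.02, 0.120)),
    ("Har3", "H", (0.795, -0.02, 0.214)),
    ("Car4", "C", (0.81, -0.02, 0.000)),
    ("Car5", "C", (0.74, -0.02, -0.120)),
    ("Har5", "H", (0.795, -0.02, -0.214)),
    ("Car6", "C", (0.60, -0.02, -0.120)),
    ("Har6", "H", (0.545, -0.02, -0.214)),
    ("C4", "C", (0.90, 0.09, 0.000)),
    ("O_d", "O", (0.84, 0.20, 0.000)),
]

_UNIT_BONDS = [
    ("O_a", "C1"), ("C1", "H1a"), ("C1", "H1b"), ("C1", "C2"),
    ("C2", "H2a"), ("C2", "H2b"), ("C2", "O_b"), ("O_b", "C3"),
    ("C3", "O_c"), ("C3", "Car1"),
    ("Car1", "Car2"), ("Car2", "Har2"), ("Car2", "Car3"), ("Car3", "Har3"),
    ("Car3", "Car4"), ("Car4", "Car5"), ("Car5", "Har5"), ("Car5", "Car6"),
    ("Car6", "Har6"), ("Car6", "Car1"), ("Car4", "C4"), ("C4", "O_d"),
]

ATOMS_PER_UNIT = len(_UNIT_TEMPLATE)


@dataclass(frozen=True)
class ChainSpec:
    """Repeat-unit count and end-group convention for one PET chain.

    ``bis_glycol`` caps both ends with hydroxyethyl groups (2n ester
    groups, two terminal hydroxyls); ``acid_glycol`` leaves one carboxylic
    end (2n - 1 esters, one hydroxyl, one carboxyl).
    """

    n_units: int = 100
    termination: str = "bis_glycol"

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.termination not in TERMINATIONS:
            raise ValueError(f"unknown termination {self.termination!r}")


def build_pet_chain(spec: ChainSpec) -> MolecularSystem:
    """Build one extended PET chain with explicit bonds and origin=polymer."""
    system = MolecularSystem()
    next_id = 0

    def add(element: str, xyz: Sequence[float]) -> int:
        nonlocal next_id
        system.add_atom(Atom(id=next_id, element=element,
                             position=np.asarray(xyz, dtype=float),
                             origin="polymer"))
        next_id += 1
        return next_id - 1

    prev_c4 = None
    name_to_id: Dict[str, int] = {}
    for unit in range(spec.n_units):
        shift = np.array([unit * MONOMER_PERIOD, 0.0, 0.0])
        name_to_id = {}
        for name, element, xyz in _UNIT_TEMPLATE:
            name_to_id[name] = add(element, np.asarray(xyz) + shift)
        for a, b in _UNIT_BONDS:
            system.add_bond(name_to_id[a], name_to_id[b])
        if unit == 0:
            # hydroxyl cap on the first glycol oxygen
            h_cap = add("H", shift + np.array([-0.068, 0.068, 0.0]))
            system.add_bond(h_cap, name_to_id["O_a"])
        else:
            system.add_bond(prev_c4, name_to_id["O_a"])
        prev_c4 = name_to_id["C4"]

    end = np.array([spec.n_units * MONOMER_PERIOD, 0.0, 0.0])
    if spec.termination == "bis_glycol":
        o_t1 = add("O", end)
        c_t1 = add("C", end + np.array([0.10, 0.10, 0.0]))
        h1a = add("H", end + np.array([0.10, 0.145, 0.095]))
        h1b = add("H", end + np.array([0.10, 0.145, -0.095]))
        c_t2 = add("C", end + np.array([0.21, 0.00, 0.0]))
        h2a = add("H", end + np.array([0.21, -0.045, 0.095]))
        h2b = add("H", end + np.array([0.21, -0.045, -0.095]))
        o_t2 = add("O", end + np.array([0.31, 0.10, 0.0]))
        h_t = add("H", end + np.array([0.378, 0.168, 0.0]))
        system.add_bond(prev_c4, o_t1)
        system.add_bond(o_t1, c_t1)
        for h in (h1a, h1b):
            system.add_bond(c_t1, h)
        system.add_bond(c_t1, c_t2)
        for h in (h2a, h2b):
            system.add_bond(c_t2, h)
        system.add_bond(c_t2, o_t2)
        system.add_bond(o_t2, h_t)
    else:  # acid_glycol: carboxylic end
        o_t = add("O", end)
        h_t = add("H", end + np.array([0.068, 0.068, 0.0]))
        system.add_bond(prev_c4, o_t)
        system.add_bond(o_t, h_t)
    return system


def _grid_walk(n_points: int, spacing: float) -> np.ndarray:
    """Boustrophedon walk over a sphere-clipped cubic grid.

    Returns at least ``n_points`` cell centers ordered so that consecutive
    cells are (mostly) adjacent, keeping consecutive monomers of a chain
    near each other.
    """
    radius = spacing
    while True:
        half = int(np.ceil(radius / spacing))
        axis = np.arange(-half, half + 1) * spacing
        points = []
        for iz, z in enumerate(axis):
            ys = axis if iz % 2 == 0 else axis[::-1]
            for iy, y in enumerate(ys):
                xs = axis if iy % 2 == 0 else axis[::-1]
                for x in xs:
                    if x * x + y * y + z * z <= radius * radius:
                        points.append((x, y, z))
        if len(points) >= n_points:
            return np.array(points)
        radius *= 1.15


def _push_apart(coords: np.ndarray, min_dist: float = MIN_SEPARATION,
                max_iter: int = 500, rng: np.random.Generator | None = None
                ) -> np.ndarray:
    """Iteratively separate any atom pair closer than ``min_dist``."""
    if rng is None:
        rng = np.random.default_rng(0)
    target = min_dist * 1.05
    coords = coords.copy()
    for _ in range(max_iter):
        tree = cKDTree(coords)
        pairs = tree.query_pairs(min_dist, output_type="ndarray")
        if pairs.size == 0:
            return coords
        delta = coords[pairs[:, 1]] - coords[pairs[:, 0]]
        dist = np.linalg.norm(delta, axis=1)
        degenerate = dist < 1e-9
        if degenerate.any():
            delta[degenerate] = rng.normal(size=(degenerate.sum(), 3))
            dist[degenerate] = np.linalg.norm(delta[degenerate], axis=1)
        push = (target - dist) / (2.0 * dist)
        disp = np.zeros_like(coords)
        np.add.at(disp, pairs[:, 0], -delta * push[:, None])
        np.add.at(disp, pairs[:, 1], delta * push[:, None])
        coords += disp
    raise RuntimeError(
        f"clashes not resolved after {max_iter} push-apart iterations")


def gyration_radius_of(coords: np.ndarray, masses: np.ndarray) -> float:
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def assemble_nanoparticle(chains: Sequence[MolecularSystem],
                          seed: int = 0,
                          cell_spacing: float = 0.72) -> MolecularSystem:
    """Fold one or more chains into a compact, roughly spherical particle.

    Chains are merged (atom ids offset to stay unique, no new bonds);
    consecutive monomer-sized atom groups are dropped onto a space-filling
    walk through a sphere, each with a seeded random orientation, and a
    push-apart relaxation enforces a 0.15 nm minimum separation.
    Deterministic for a given seed.
    """
    if not chains:
        raise ValueError("need at least one chain")
    rng = np.random.default_rng(seed)

    merged = MolecularSystem()
    offset = 0
    groups: List[List[int]] = []
    for chain in chains:
        ids = chain.ids()
        id_map = {i: i + offset for i in ids}
        for i in ids:
            atom = chain.atoms[i]
            merged.add_atom(Atom(id=id_map[i], element=atom.element,
                                 position=atom.position.copy(),
                                 charge=atom.charge, origin=atom.origin,
                                 residue_index=atom.residue_index,
                                 residue_name=atom.residue_name))
        for a, b, data in chain.graph.edges(data=True):
            merged.add_bond(id_map[a], id_map[b], data.get("order"))
        chunk: List[int] = []
        chain_groups: List[List[int]] = []
        for i in ids:
            chunk.append(id_map[i])
            if len(chunk) == ATOMS_PER_UNIT:
                chain_groups.append(chunk)
                chunk = []
        if chunk:  # fold the end caps into the final group
            if chain_groups:
                chain_groups[-1].extend(chunk)
            else:
                chain_groups.append(chunk)
        groups.extend(chain_groups)
        offset = merged.next_id()

    cells = _grid_walk(len(groups), cell_spacing)
    for group, center in zip(groups, cells):
        local = merged.positions(group)
        local -= local.mean(axis=0)
        rot = Rotation.random(random_state=rng).as_matrix()
        merged.set_positions(local @ rot.T + center, group)

    coords = _push_apart(merged.positions(), rng=rng)
    merged.set_positions(coords)
    return merged
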