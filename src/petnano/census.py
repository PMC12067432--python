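"""Functional-group census and surface metrics on molecular bond graphs.

The census counts the degradation-chemistry observables of a nanoparticle:
ester (EST), hydroxyl (OH), aldehyde (CHO), carboxyl (COOH) and ketone-type
carbonyl (CO) groups, oxygen-containing small rings (R3-R6), the number of
atoms with altered bonded neighbourhoods relative to a pristine reference
(ALT), and the number of water-derived oxygens incorporated into the
particle (N_Ow). Counts are computed on the main particle: every connected
component whose mass reaches half that of the heaviest component. Pristine
multi-chain particles are held together by dispersion forces, not covalent
bonds, so their equal-mass chains all belong to the particle, while small
detached fragments (well under half the particle mass) are excluded and
reported separately by the degradation emulator.

Group perception is connectivity-based with a fixed precedence
EST > COOH > CHO > CO > OH, so each carbonyl carbon contributes to at most
one counter and carboxyl O-H oxygens are not double-counted as hydroxyls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .constants import VDW_RADII
from .core import MolecularSystem, connected_components, molar_mass

log = logging.getLogger(__name__)


@dataclass
class FunctionalGroupCensus:
    EST: int = 0
    OH: int = 0
    CHO: int = 0
    COOH: int = 0
    CO: int = 0
    R3: int = 0
    R4: int = 0
    R5: int = 0
    R6: int = 0
    ALT: int = 0
    N_Ow: int = 0

    def as_dict(self) -> Dict[str, int]:
        return asdict(self)


@dataclass
class SurfaceMetrics:
    R_g: float
    SASA: float
    hbond_count: int
    energy_per_area: float
    hbonds_per_area: float


# -- group perception ------------------------------------------------------


def _carbonyl_class(system: MolecularSystem, c: int) -> Optional[str]:
    """Classify carbon ``c`` as EST/COOH/CHO/CO, or None."""
    if system.atoms[c].element != "C":
        return None
    nbrs = system.neighbors(c)
    oxygens = [j for j in nbrs if system.atoms[j].element == "O"]
    terminal = [j for j in oxygens if system.degree(j) == 1]
    if not terminal:
        return None
    bridging = [j for j in oxygens if system.degree(j) == 2]
    carbons = [j for j in nbrs if system.atoms[j].element == "C"]
    hydrogens = [j for j in nbrs if system.atoms[j].element == "H"]
    if len(oxygens) == 2 and len(terminal) == 1 and len(bridging) == 1:
        other = [k for k in system.neighbors(bridging[0]) if k != c][0]
        if system.atoms[other].element == "C":
            return "EST"
        if system.atoms[other].element == "H":
            return "COOH"
    if len(terminal) == 1 and len(oxygens) == 1:
        if hydrogens and len(carbons) == 1:
            return "CHO"
        if len(carbons) == 2 and not hydrogens:
            return "CO"
    return None


def _hydroxyl_oxygens(system: MolecularSystem,
                      carbonyl: Dict[int, str]) -> List[int]:
    """Degree-2 O bonded to one H and one C, excluding carboxyl O-H."""
    found = []
    for i, atom in system.atoms.items():
        if atom.element != "O" or system.degree(i) != 2:
            continue
        nbrs = system.neighbors(i)
        elems = sorted(system.atoms[j].element for j in nbrs)
        if elems != ["C", "H"]:
            continue
        carbon = next(j for j in nbrs if system.atoms[j].element == "C")
        if carbonyl.get(carbon) in ("COOH",):
            continue
        found.append(i)
    return found


def small_ring_basis(graph: nx.Graph, max_size: int = 6,
                     tie_key=None) -> List[List[int]]:
    """Independent small rings: the <=max_size members of a minimum cycle
    basis (smallest-set-of-smallest-rings convention).

    Candidate cycles up to ``max_size`` are enumerated locally and added
    shortest-first while linearly independent over GF(2) on edge space
    (Horton's greedy construction), so ring perception stays fast even
    when long-range cross-links create huge cycles. Among equal-length
    candidates, all-carbon cycles are preferred, matching the chemical
    convention that benzene is the canonical ring of a fused system.
    """
    cycles = [c for c in nx.simple_cycles(graph, length_bound=max_size)
              if len(c) >= 3]
    if tie_key is None:
        tie_key = lambda c: 0  # noqa: E731
    cycles.sort(key=lambda c: (len(c), tie_key(c), tuple(sorted(c))))
    edge_index: Dict[Tuple[int, int], int] = {}

    def edge_vector(cycle: Sequence[int]) -> int:
        vec = 0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            key = (a, b) if a <= b else (b, a)
            if key not in edge_index:
                edge_index[key] = len(edge_index)
            vec |= 1 << edge_index[key]
        return vec

    pivots: Dict[int, int] = {}
    chosen: List[List[int]] = []
    for cycle in cycles:
        vec = edge_vector(cycle)
        while vec:
            low = vec & -vec
            if low in pivots:
                vec ^= pivots[low]
            else:
                pivots[low] = vec
                chosen.append(cycle)
                break
    return chosen


def oxygen_rings(system: MolecularSystem,
                 nodes: Optional[Set[int]] = None) -> Dict[int, int]:
    """Count independent rings of size 3-6 containing at least one oxygen.

    Rings follow the smallest-set-of-smallest-rings convention via
    :func:`small_ring_basis`, computed per biconnected component so
    benzene-fused oxygen rings are counted once. All-carbon rings
    (benzene) are never counted.
    """
    graph = system.graph if nodes is None else system.graph.subgraph(nodes)
    counts = {3: 0, 4: 0, 5: 0, 6: 0}
    for comp in nx.biconnected_components(graph):
        if len(comp) < 3:
            continue
        if not any(system.atoms[v].element == "O" for v in comp):
            continue  # all-carbon ring system
        sub = nx.Graph(graph.subgraph(comp))
        prefer_all_carbon = lambda c: sum(  # noqa: E731
            1 for v in c if system.atoms[v].element == "O")
        for cycle in small_ring_basis(sub, tie_key=prefer_all_carbon):
            if any(system.atoms[v].element == "O" for v in cycle):
                counts[len(cycle)] += 1
    return counts


def count_alt(system: MolecularSystem, reference: MolecularSystem,
              ids: Optional[Sequence[int]] = None) -> int:
    """Number of atoms whose bonded-neighbour element multiset changed.

    Atoms absent from the reference (e.g. inserted water oxygens) count as
    altered and are logged.
    """
    sel = system.ids() if ids is None else list(ids)
    altered = 0
    novel = 0
    for i in sel:
        if i not in reference.atoms:
            altered += 1
            novel += 1
            continue
        if system.neighbor_elements(i) != reference.neighbor_elements(i):
            altered += 1
    if novel:
        log.info("%d atoms absent from reference counted as altered", novel)
    return altered


def main_particle_ids(system: MolecularSystem) -> Set[int]:
    """Atom ids of the main particle.

    The particle is the union of connected components whose molar mass is
    at least half that of the heaviest component; this keeps the
    non-covalently associated chains of a pristine assembly together while
    excluding small detached fragments.
    """
    comps = connected_components(system)
    heaviest = molar_mass(comps[0], system)
    ids: Set[int] = set()
    for comp in comps:
        if molar_mass(comp, system) >= 0.5 * heaviest:
            ids |= comp
    return ids


def census(system: MolecularSystem,
           reference: Optional[MolecularSystem] = None
           ) -> FunctionalGroupCensus:
    """Run the full functional-group census on the main particle."""
    if not system.atoms:
        raise ValueError("empty system")
    component = main_particle_ids(system)
    sub = system.subsystem(component)

    carbonyl: Dict[int, str] = {}
    for i in sub.ids():
        cls = _carbonyl_class(sub, i)
        if cls:
            carbonyl[i] = cls
    result = FunctionalGroupCensus()
    for cls in carbonyl.values():
        setattr(result, cls, getattr(result, cls) + 1)
    result.OH = len(_hydroxyl_oxygens(sub, carbonyl))
    rings = oxygen_rings(sub)
    result.R3, result.R4 = rings[3], rings[4]
    result.R5, result.R6 = rings[5], rings[6]
    result.N_Ow = sum(1 for i in component
                      if system.atoms[i].element == "O"
                      and system.atoms[i].origin == "water")
    if reference is not None:
        result.ALT = count_alt(system, reference, ids=sorted(component))
    return result


# -- geometric metrics -----------------------------------------------------


def heaviest_component_mass(system: MolecularSystem) -> float:
    """Molar mass (g/mol) of the largest connected component."""
    if not system.atoms:
        raise ValueError("empty system")
    return molar_mass(connected_components(system)[0], system)


def gyration_radius(system: MolecularSystem,
                    ids: Optional[Sequence[int]] = None) -> float:
    """Mass-weighted RMS distance from the mass-weighted centroid, nm."""
    sel = system.ids() if ids is None else list(ids)
    if not sel:
        raise ValueError("empty selection")
    coords = system.positions(sel)
    masses = system.masses(sel)
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(system: MolecularSystem, probe_radius: float = 0.14,
         n_points: int = 960,
         ids: Optional[Sequence[int]] = None) -> float:
    """Shrake-Rupley solvent-accessible surface area, in A^2.

    Quadrature points are placed on each atom's solvent-expanded sphere
    (van der Waals radius + probe) and a point is accessible when it lies
    outside every other atom's expanded sphere.
    """
    sel = system.ids() if ids is None else list(ids)
    if not sel:
        raise ValueError("empty selection")
    for i in sel:
        if system.atoms[i].element not in VDW_RADII:
            raise ValueError(f"no vdW radius for {system.atoms[i].element}")
    coords = system.positions(sel)
    radii = np.array([VDW_RADII[system.atoms[i].element] for i in sel])
    expanded = radii + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    total = 0.0
    for idx in range(len(sel)):
        r = expanded[idx]
        points = coords[idx] + unit * r
        nbrs = [j for j in tree.query_ball_point(coords[idx], r + max_r)
                if j != idx]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        total += 4.0 * np.pi * r * r * accessible.mean()
    return float(total * 100.0)  # nm^2 -> A^2


def count_hbonds(solute: MolecularSystem, waters: MolecularSystem,
                 distance_cutoff: float = 0.35,
                 angle_cutoff_deg: float = 30.0) -> int:
    """Geometric hydrogen-bond count between a solute and water molecules.

    A bond requires donor-acceptor O-O distance <= 0.35 nm and an
    H-donor-acceptor angle <= 30 degrees; O atoms carrying an H act as
    donors and every O acts as acceptor. Both donation directions are
    counted.
    """
    def oxygens_with_h(sys_: MolecularSystem):
        out = []
        for i, atom in sys_.atoms.items():
            if atom.element != "O":
                continue
            hs = [j for j in sys_.neighbors(i) if sys_.atoms[j].element == "H"]
            out.append((i, hs))
        return out

    def count_direction(donors_sys, donors, acceptors_sys, acceptors):
        if not donors or not acceptors:
            return 0
        acc_coords = np.array([acceptors_sys.atoms[i].position
                               for i in acceptors])
        tree = cKDTree(acc_coords)
        n = 0
        cos_cut = math.cos(math.radians(angle_cutoff_deg))
        for d, hs in donors:
            if not hs:
                continue
            dpos = donors_sys.atoms[d].position
            for a_idx in tree.query_ball_point(dpos, distance_cutoff):
                apos = acc_coords[a_idx]
                da = apos - dpos
                norm_da = np.linalg.norm(da)
                if norm_da < 1e-9:
                    continue
                for h in hs:
                    dh = donors_sys.atoms[h].position - dpos
                    cos_angle = float(dh @ da / (np.linalg.norm(dh) * norm_da))
                    if cos_angle >= cos_cut:
                        n += 1
        return n

    solute_o = oxygens_with_h(solute)
    water_o = oxygens_with_h(waters)
    total = count_direction(solute, solute_o, waters, [i for i, _ in water_o])
    total += count_direction(waters, water_o, solute, [i for i, _ in solute_o])
    return total


def hydrophilicity(system: MolecularSystem, water_energy: float,
                   surface_area: float, hbonds: int) -> SurfaceMetrics:
    """Per-area hydrophilicity indices from a water pair energy and SASA."""
    if surface_area <= 0:
        raise ValueError("SASA must be positive")
    return SurfaceMetrics(
        R_g=gyration_radius(system),
        SASA=surface_area,
        hbond_count=hbonds,
        energy_per_area=water_energy / surface_area,
        hbonds_per_area=hbonds / surface_area,
    )
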