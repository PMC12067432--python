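"""Graph-edit emulator of shock-compression degradation in water.

Reactive MD degradation of a PET particle is emulated statistically: a
:class:`DegradationSchedule` fixes the final functional-group census of the
main particle (hydroxyl, carboxyl, aldehyde, ketone carbonyl, oxygen
heterocycles), the number of destroyed ester linkages, the number of
chain-fusing cross-links, the number of released 2-18 carbon fragments and
the number of water-derived oxygens incorporated into the particle (N_Ow).
The packaged schedules encode the printed degradation outcomes for the
small and large particles at 10-30 GPa.

An integer planner first decomposes the schedule into concrete edit
budgets. Ester scissions are capped in one of five chemistries, chosen so
that group counts and the water-oxygen tally close exactly:

* hydrolysis          acyl side -> COOH (one water O), alkoxy O -> OH
* H-capping           acyl side -> CHO, alkoxy O -> OH
* decarbonylation     acyl C leaves as CO, alkoxy O -> OH
* acid cleavage       O-alkyl cut, acyl side -> COOH (polymer O only)
* decarboxylation     O-alkyl cut, acyl side leaves as CO2

Remaining group targets are met by attachments (OH at C-H sites; COOH and
CHO by benzene-ring opening; in-ring ketones), and ring targets by oxygen
heterocycle closures that either recruit an existing backbone oxygen
(census-neutral for N_Ow) or insert a water oxygen (epoxides always do).
Cross-links are census-neutral C-C bonds that fuse the cut segments into a
single molecule; detached fragments are mono-(2-hydroxyethyl)
terephthalate-like hydroxy-acids plus the CO/CO2 released by the
decarbonylation/decarboxylation caps. Every edit draws its site uniformly
from the eligible ones with a seeded generator, so a (schedule, seed) pair
is bit-reproducible, and the resulting census reproduces the planted
counts exactly (verified after editing).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import yaml

from .census import _carbonyl_class, census, oxygen_rings
from .constants import ATOMIC_WEIGHTS
from .core import Atom, MolecularSystem, molar_mass

#: Chains per particle size class (S = small, L = large).
SIZE_CLASS_CHAINS = {"S": 2, "L": 4}


@dataclass(frozen=True)
class DegradationSchedule:
    """Edit budget applied by :func:`degrade`; see the module docstring."""

    size_class: str
    pressure: int
    n_OH: int = 0
    n_COOH: int = 0
    n_CHO: int = 0
    n_CO: int = 0
    n_R3: int = 0
    n_R4: int = 0
    n_R5: int = 0
    n_R6: int = 0
    n_scission: int = 0
    n_crosslink: int = 0
    n_detach_fragments: int = 0
    n_Ow: int = 0
    seed: int = 42

    def __post_init__(self):
        for name, value in asdict(self).items():
            if name.startswith("n_") and value < 0:
                raise ValueError(f"{name} must be non-negative")


def load_schedules() -> Dict[str, DegradationSchedule]:
    """The packaged pressure-indexed schedules (S10 ... L30)."""
    text = (importlib.resources.files("petnano") / "data" / "schedules.yaml"
            ).read_text()
    raw = yaml.safe_load(text)
    return {name: DegradationSchedule(**entry) for name, entry in raw.items()}


def get_schedule(name: str) -> DegradationSchedule:
    schedules = load_schedules()
    if name not in schedules:
        raise KeyError(f"unknown schedule {name!r}; have {sorted(schedules)}")
    return schedules[name]


@dataclass
class EditPlan:
    """Concrete edit budgets derived from a schedule by the planner."""

    m_hydrolysis: int = 0      # acyl cut -> COOH(water O) + OH
    m_aldehyde: int = 0        # acyl cut -> CHO + OH
    m_acid: int = 0            # O-alkyl cut -> COOH (polymer O)
    m_decarbonyl: int = 0      # acyl cut -> CO released + OH
    m_decarboxyl: int = 0      # O-alkyl cut -> CO2 released
    att_OH: int = 0
    att_COOH: int = 0
    att_CHO: int = 0
    att_CO: int = 0
    rings_existing: Dict[int, int] = field(default_factory=dict)
    rings_water: Dict[int, int] = field(default_factory=dict)
    n_ether: int = 0
    n_fragments: int = 0


def plan_edits(schedule: DegradationSchedule) -> EditPlan:
    """Solve the integer budget that realises the schedule exactly.

    The water-oxygen tally closes as

        N_Ow = m_hydrolysis + att_OH + 2 att_COOH + att_CHO + att_CO
             + n_R3 + (water-mode 4/5/6 rings) + n_ether

    with each scission-derived group replacing an attachment and therefore
    reducing the tally; infeasible schedules raise with the deficit.
    """
    s = schedule
    plan = EditPlan(n_fragments=s.n_detach_fragments)
    base = s.n_OH + 2 * s.n_COOH + s.n_CHO + s.n_CO
    r_total = s.n_R3 + s.n_R4 + s.n_R5 + s.n_R6
    r456 = s.n_R4 + s.n_R5 + s.n_R6
    need = base + r_total - s.n_Ow - s.n_detach_fragments
    if need < 0:
        plan.n_ether = -need
        r_exist = 0
    else:
        r_exist = min(r456, need)
        rem = need - r_exist
        plan.m_aldehyde = min(s.n_CHO, rem // 2)
        rem -= 2 * plan.m_aldehyde
        plan.m_hydrolysis = min(s.n_COOH, rem // 2)
        rem -= 2 * plan.m_hydrolysis
        plan.m_acid = min(s.n_COOH - plan.m_hydrolysis, rem // 2)
        rem -= 2 * plan.m_acid
        plan.m_decarbonyl = rem
    # distribute existing-oxygen ring closures largest size first
    remaining = r_exist
    for size, target in ((6, s.n_R6), (5, s.n_R5), (4, s.n_R4)):
        take = min(target, remaining)
        plan.rings_existing[size] = take
        plan.rings_water[size] = target - take
        remaining -= take
    plan.rings_water[3] = s.n_R3  # epoxides always insert a water oxygen

    plan.att_OH = (s.n_OH - plan.m_hydrolysis - plan.m_aldehyde
                   - plan.m_decarbonyl - s.n_detach_fragments)
    plan.att_COOH = s.n_COOH - plan.m_hydrolysis - plan.m_acid
    plan.att_CHO = s.n_CHO - plan.m_aldehyde
    plan.att_CO = s.n_CO
    # each detached fragment destroys two esters at its boundaries and
    # carries one intact ester away, so it accounts for 3 of n_scission
    mode_cuts = (plan.m_hydrolysis + plan.m_aldehyde + plan.m_acid
                 + plan.m_decarbonyl)
    plan.m_decarboxyl = s.n_scission - mode_cuts - 3 * s.n_detach_fragments

    problems = []
    if plan.att_OH < 0:
        problems.append(f"OH target short by {-plan.att_OH}")
    if plan.m_decarboxyl < 0:
        problems.append(
            f"n_scission short by {-plan.m_decarboxyl} for the planned cuts")
    if need >= 0 and remaining > 0:
        problems.append(f"{remaining} unplaceable oxygen-budget reductions")
    if problems:
        raise ValueError("infeasible schedule: " + "; ".join(problems))
    return plan


@dataclass
class DegradationResult:
    system: MolecularSystem
    fragments: List[MolecularSystem]
    ledger: Dict[str, float]

    def __iter__(self):  # allow tuple unpacking (system, fragments)
        return iter((self.system, self.fragments))


# -- executor --------------------------------------------------------------


class _Ester:
    __slots__ = ("c_acyl", "o_term", "o_bridge", "c_alkoxy", "c_aryl")

    def __init__(self, c_acyl, o_term, o_bridge, c_alkoxy, c_aryl):
        self.c_acyl = c_acyl
        self.o_term = o_term
        self.o_bridge = o_bridge
        self.c_alkoxy = c_alkoxy
        self.c_aryl = c_aryl

    @property
    def atoms(self) -> Tuple[int, ...]:
        return (self.c_acyl, self.o_term, self.o_bridge,
                self.c_alkoxy, self.c_aryl)


class _Degrader:
    def __init__(self, system: MolecularSystem,
                 schedule: DegradationSchedule,
                 site_class_weights: Tuple[float, float, float]):
        self.sys = system.copy()
        self.schedule = schedule
        self.rng = np.random.default_rng(schedule.seed)
        self.blocked: Set[int] = set()
        self.dearomatized: Set[int] = set()
        self.fragments: List[MolecularSystem] = []
        self.mass_added = 0.0
        self.mass_removed = 0.0
        self.site_class_weights = site_class_weights
        self.aromatic: Set[int] = set()
        for comp in nx.biconnected_components(self.sys.graph):
            if len(comp) == 6 and all(
                    self.sys.atoms[i].element == "C" for i in comp):
                self.aromatic |= comp

    # -- primitives -----------------------------------------------------

    def _shuffled(self, items: Sequence) -> List:
        items = list(items)
        self.rng.shuffle(items)
        return items

    def _new_atom(self, element: str, near: int) -> int:
        direction = self.rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        atom = Atom(id=self.sys.next_id(), element=element,
                    position=self.sys.atoms[near].position + 0.1 * direction,
                    origin="water")
        self.sys.add_atom(atom)
        self.mass_added += atom.mass
        return atom.id

    def _delete_h(self, c: int) -> None:
        hs = sorted(j for j in self.sys.neighbors(c)
                    if self.sys.atoms[j].element == "H")
        if not hs:
            raise RuntimeError(f"atom {c} has no hydrogen to remove")
        h = hs[0]
        self.mass_removed += self.sys.atoms[h].mass
        self.sys.remove_atom(h)

    def dehydroxylate_ends(self) -> int:
        """Strip the pristine chain-end hydroxyls (C-OH -> C-H).

        The printed group counts are *formed* groups, so the handful of
        glycol end hydroxyls present before degradation are consumed first
        (their oxygen returns to the solvent).
        """
        targets = []
        for i in self.sys.ids():
            atom = self.sys.atoms[i]
            if atom.element != "O" or atom.origin != "polymer":
                continue
            if self.sys.degree(i) != 2:
                continue
            elems = sorted(self.sys.atoms[j].element
                           for j in self.sys.neighbors(i))
            if elems == ["C", "H"]:
                targets.append(i)
        for o in targets:
            nbrs = self.sys.neighbors(o)
            c = next(j for j in nbrs if self.sys.atoms[j].element == "C")
            h = next(j for j in nbrs if self.sys.atoms[j].element == "H")
            self.mass_removed += self.sys.atoms[o].mass
            self.sys.remove_atom(o)
            self.sys.add_bond(c, h)
            self._block((c,), radius=0)
        return len(targets)

    def _release(self, ids: Sequence[int]) -> None:
        """Move atoms out of the main system into a detached fragment."""
        frag = self.sys.subsystem(ids)
        for i in ids:
            self.sys.remove_atom(i)
        self.fragments.append(frag)

    def _block(self, ids: Sequence[int], radius: int = 1) -> None:
        layer = set(ids)
        self.blocked |= layer
        for _ in range(radius):
            nxt = set()
            for i in layer:
                if i in self.sys.atoms:
                    nxt.update(self.sys.neighbors(i))
            self.blocked |= nxt
            layer = nxt

    def _hydrogens(self, c: int) -> List[int]:
        return [j for j in self.sys.neighbors(c)
                if self.sys.atoms[j].element == "H"]

    # -- ester bookkeeping ----------------------------------------------

    def find_esters(self) -> List[_Ester]:
        esters = []
        for i in self.sys.ids():
            if _carbonyl_class(self.sys, i) != "EST":
                continue
            nbrs = self.sys.neighbors(i)
            o_term = next(j for j in nbrs if self.sys.atoms[j].element == "O"
                          and self.sys.degree(j) == 1)
            o_bridge = next(j for j in nbrs if self.sys.atoms[j].element == "O"
                            and self.sys.degree(j) == 2)
            carbons = [j for j in nbrs if self.sys.atoms[j].element == "C"]
            if len(carbons) != 1:
                continue  # only the PET acyl topology is editable
            c_alkoxy = next(k for k in self.sys.neighbors(o_bridge) if k != i)
            esters.append(_Ester(i, o_term, o_bridge, c_alkoxy, carbons[0]))
        return esters

    def _usable(self, ester: _Ester) -> bool:
        return all(a in self.sys.atoms and a not in self.blocked
                   for a in ester.atoms)

    # -- scission chemistries -------------------------------------------

    def cut_hydrolysis(self, e: _Ester) -> None:
        self.sys.remove_bond(e.c_acyl, e.o_bridge)
        o_w = self._new_atom("O", e.c_acyl)
        self.sys.add_bond(e.c_acyl, o_w)
        self.sys.add_bond(o_w, self._new_atom("H", o_w))
        self.sys.add_bond(e.o_bridge, self._new_atom("H", e.o_bridge))
        self._block(e.atoms + (o_w,), radius=0)

    def cut_aldehyde(self, e: _Ester) -> None:
        self.sys.remove_bond(e.c_acyl, e.o_bridge)
        self.sys.add_bond(e.c_acyl, self._new_atom("H", e.c_acyl))
        self.sys.add_bond(e.o_bridge, self._new_atom("H", e.o_bridge))
        self._block(e.atoms, radius=0)

    def cut_decarbonyl(self, e: _Ester) -> None:
        self.sys.remove_bond(e.c_acyl, e.o_bridge)
        self.sys.add_bond(e.c_aryl, self._new_atom("H", e.c_aryl))
        self.sys.add_bond(e.o_bridge, self._new_atom("H", e.o_bridge))
        self._release([e.c_acyl, e.o_term])
        self._block((e.o_bridge, e.c_alkoxy, e.c_aryl), radius=0)

    def cut_acid(self, e: _Ester) -> None:
        self.sys.remove_bond(e.o_bridge, e.c_alkoxy)
        self.sys.add_bond(e.o_bridge, self._new_atom("H", e.o_bridge))
        self.sys.add_bond(e.c_alkoxy, self._new_atom("H", e.c_alkoxy))
        self._block(e.atoms, radius=0)

    def cut_decarboxyl(self, e: _Ester) -> None:
        self.sys.remove_bond(e.o_bridge, e.c_alkoxy)
        self.sys.add_bond(e.c_aryl, self._new_atom("H", e.c_aryl))
        self.sys.add_bond(e.c_alkoxy, self._new_atom("H", e.c_alkoxy))
        self._release([e.c_acyl, e.o_term, e.o_bridge])
        self._block((e.c_alkoxy, e.c_aryl), radius=0)

    # -- fragment detachment ---------------------------------------------

    def detach_fragment(self, esters: List[_Ester]) -> bool:
        """Cut out a hydroxy-acid fragment between two ester linkages.

        The upstream acyl carbon leaves as CO, the fragment is capped as a
        mono-(2-hydroxyethyl) terephthalate-like acid, and the downstream
        bridge oxygen becomes a main-particle hydroxyl.
        """
        by_acyl = {e.c_acyl: e for e in esters if self._usable(e)}
        for e1 in self._shuffled(sorted(by_acyl.values(),
                                        key=lambda e: e.c_acyl)):
            # provisional first cut
            self.sys.remove_bond(e1.c_acyl, e1.o_bridge)
            lengths = nx.single_source_shortest_path_length(
                self.sys.graph, e1.o_bridge, cutoff=16)
            candidates = [by_acyl[c] for c in lengths
                          if c in by_acyl and by_acyl[c] is not e1
                          and lengths.get(by_acyl[c].o_bridge, 99)
                          == lengths[c] + 1]
            for e2 in sorted(candidates, key=lambda e: lengths[e.c_acyl]):
                self.sys.remove_bond(e2.c_acyl, e2.o_bridge)
                frag_ids = nx.node_connected_component(
                    self.sys.graph, e1.o_bridge)
                n_carbon = sum(1 for i in frag_ids
                               if self.sys.atoms[i].element == "C")
                if 2 <= n_carbon <= 18 and e1.c_acyl not in frag_ids:
                    # fragment caps: hydroxyl + carboxylic acid
                    self.sys.add_bond(e1.o_bridge,
                                      self._new_atom("H", e1.o_bridge))
                    o_w = self._new_atom("O", e2.c_acyl)
                    self.sys.add_bond(e2.c_acyl, o_w)
                    self.sys.add_bond(o_w, self._new_atom("H", o_w))
                    # main-side caps: CO release + hydroxyl
                    self.sys.add_bond(e1.c_aryl,
                                      self._new_atom("H", e1.c_aryl))
                    self.sys.add_bond(e2.o_bridge,
                                      self._new_atom("H", e2.o_bridge))
                    self._block((e1.c_aryl, e2.o_bridge, e2.c_alkoxy), radius=0)
                    self._release([e1.c_acyl, e1.o_term])
                    self._release(sorted(
                        nx.node_connected_component(self.sys.graph,
                                                    e1.o_bridge)))
                    return True
                self.sys.add_bond(e2.c_acyl, e2.o_bridge)
            self.sys.add_bond(e1.c_acyl, e1.o_bridge)
        return False

    # -- attachments ------------------------------------------------------

    def _site_class(self, c: int) -> str:
        if c in self.aromatic:
            return "dearomatized" if c in self.dearomatized else "aromatic"
        return "aliphatic"

    def _ch_sites(self, strict: bool = True) -> Dict[str, List[int]]:
        sites: Dict[str, List[int]] = {"aliphatic": [], "dearomatized": [],
                                       "aromatic": []}
        for i in self.sys.ids():
            atom = self.sys.atoms[i]
            if atom.element != "C" or i in self.blocked:
                continue
            if strict and any(j in self.blocked for j in self.sys.neighbors(i)):
                continue
            if self._hydrogens(i):
                sites[self._site_class(i)].append(i)
        return sites

    def _pick_ch_site(self) -> int:
        for strict in (True, False):
            sites = self._ch_sites(strict)
            classes = [c for c in ("aliphatic", "dearomatized", "aromatic")
                       if sites[c]]
            if not classes:
                continue
            weights = np.array([self.site_class_weights[
                ("aliphatic", "dearomatized", "aromatic").index(c)]
                for c in classes], dtype=float)
            weights /= weights.sum()
            cls = classes[self.rng.choice(len(classes), p=weights)]
            return sites[cls][self.rng.integers(len(sites[cls]))]
        raise RuntimeError("no eligible C-H attachment sites remain")

    def attach_oh(self) -> None:
        c = self._pick_ch_site()
        h = sorted(self._hydrogens(c))[0]
        self.sys.remove_bond(c, h)
        o_w = self._new_atom("O", c)
        self.sys.add_bond(c, o_w)
        self.sys.add_bond(o_w, h)
        self._block((c, o_w))

    def _open_ring_bond(self) -> Optional[Tuple[int, int]]:
        """Pick an intact aromatic C-C bond with hydrogens on both carbons."""
        for strict in (True, False):
            edges = []
            for i, j in self.sys.graph.edges:
                if (i in self.aromatic and j in self.aromatic
                        and i not in self.dearomatized
                        and j not in self.dearomatized
                        and self._hydrogens(i) and self._hydrogens(j)
                        and (not strict
                             or (i not in self.blocked
                                 and j not in self.blocked))):
                    edges.append((min(i, j), max(i, j)))
            if edges:
                edges.sort()
                return edges[self.rng.integers(len(edges))]
        return None

    def attach_cooh(self) -> None:
        pair = self._open_ring_bond()
        if pair is None:
            raise RuntimeError("no aromatic bond available for COOH formation")
        ca, cb = pair
        self.sys.remove_bond(ca, cb)
        self.sys.add_bond(cb, self._new_atom("H", cb))
        o_term = self._new_atom("O", ca)
        self.sys.add_bond(ca, o_term)
        o_bridge = self._new_atom("O", ca)
        self.sys.add_bond(ca, o_bridge)
        self.sys.add_bond(o_bridge, self._new_atom("H", o_bridge))
        ring = self._ring_of(ca)
        self.dearomatized |= ring
        self._block((ca, cb, o_term, o_bridge))

    def attach_cho(self) -> None:
        pair = self._open_ring_bond()
        if pair is None:
            raise RuntimeError("no aromatic bond available for CHO formation")
        ca, cb = pair
        self.sys.remove_bond(ca, cb)
        self.sys.add_bond(cb, self._new_atom("H", cb))
        o_term = self._new_atom("O", ca)
        self.sys.add_bond(ca, o_term)
        ring = self._ring_of(ca)
        self.dearomatized |= ring
        self._block((ca, cb, o_term))

    def attach_co(self) -> None:
        candidates = []
        for strict in (True, False):
            candidates = [i for i in sorted(self.aromatic)
                          if i in self.sys.atoms
                          and i not in self.dearomatized
                          and self._hydrogens(i)
                          and (i not in self.blocked if not strict else
                               i not in self.blocked
                               and not any(j in self.blocked
                                           for j in self.sys.neighbors(i)))]
            if candidates:
                break
        if not candidates:
            raise RuntimeError("no aromatic C-H site for carbonyl formation")
        c = candidates[self.rng.integers(len(candidates))]
        self._delete_h(c)
        o_term = self._new_atom("O", c)
        self.sys.add_bond(c, o_term)
        self.dearomatized |= self._ring_of(c)
        self._block((c, o_term))

    def _ring_of(self, c: int) -> Set[int]:
        near = nx.single_source_shortest_path_length(self.sys.graph, c,
                                                     cutoff=3)
        return {i for i in near if i in self.aromatic}

    # -- ring closures -----------------------------------------------------

    def close_epoxide(self, pair: Tuple[int, int]) -> None:
        i, j = pair
        self._delete_h(i)
        self._delete_h(j)
        o_w = self._new_atom("O", i)
        self.sys.add_bond(i, o_w)
        self.sys.add_bond(j, o_w)
        self._block((i, j, o_w))

    def reserve_ring_site(self, size: int,
                          esters: List[_Ester]) -> Tuple[_Ester, int, int]:
        """Reserve an ester site for a size-4/5/6 oxygen-ring closure.

        Sites are reserved right after scission so that attachments do not
        consume the atoms the closure needs; the closure itself is applied
        later, in the ring phase.
        """
        for e in self._shuffled(sorted((e for e in esters if self._usable(e)),
                                       key=lambda e: e.c_acyl)):
            if e.c_aryl not in self.aromatic or e.c_aryl in self.dearomatized:
                continue
            ortho = [j for j in self.sys.neighbors(e.c_aryl)
                     if j in self.aromatic and self._hydrogens(j)
                     and j not in self.blocked]
            if not ortho:
                continue
            y = sorted(ortho)[0]
            if size in (4, 5):
                if not self._hydrogens(e.c_alkoxy):
                    continue
                self._block(e.atoms + (y,), radius=0)
                return (e, e.c_alkoxy, y)
            xs = [k for k in self.sys.neighbors(e.c_alkoxy)
                  if self.sys.atoms[k].element == "C"
                  and self._hydrogens(k) and k not in self.blocked]
            if not xs:
                continue
            x = sorted(xs)[0]
            self._block(e.atoms + (x, y), radius=0)
            return (e, x, y)
        raise RuntimeError(f"no ester site available for a {size}-ring closure")

    def close_ring_existing(self, size: int,
                            site: Tuple[_Ester, int, int]) -> None:
        """Close a size-4/5/6 ring recruiting an existing ester oxygen.

        size 4: open one aromatic bond at the acyl ring carbon, then bond
        the alkoxy carbon to it (ring C-O-C(=O)-C).
        size 5: bond the alkoxy carbon to the ring carbon ortho to the
        acyl attachment.
        size 6: bond the carbon next to the alkoxy carbon to that ortho
        ring carbon.
        """
        e, x, y = site
        if size == 4:
            self.sys.remove_bond(e.c_aryl, y)
            self.sys.add_bond(y, self._new_atom("H", y))
            self._delete_h(e.c_alkoxy)
            self.sys.add_bond(e.c_alkoxy, e.c_aryl)
            self.dearomatized |= self._ring_of(y)
        else:
            self._delete_h(x)
            self._delete_h(y)
            self.sys.add_bond(x, y)

    def reserve_epoxide_pair(self) -> Tuple[int, int]:
        pairs = []
        for i, j in self.sys.graph.edges:
            ai, aj = self.sys.atoms[i], self.sys.atoms[j]
            if (ai.element == "C" and aj.element == "C"
                    and i not in self.blocked and j not in self.blocked
                    and i not in self.aromatic and j not in self.aromatic
                    and self._hydrogens(i) and self._hydrogens(j)):
                pairs.append((min(i, j), max(i, j)))
        if not pairs:
            raise RuntimeError("no aliphatic C-C pair for epoxide closure")
        pairs.sort()
        pair = pairs[self.rng.integers(len(pairs))]
        self._block(pair, radius=0)
        return pair

    def close_ring_water(self, size: int) -> None:
        """Bridge a geodesic carbon path of size-1 atoms with a water oxygen."""
        for _ in range(200):
            starts = [i for i in self.sys.ids()
                      if self.sys.atoms[i].element == "C"
                      and i not in self.blocked and self._hydrogens(i)]
            if not starts:
                break
            a = starts[self.rng.integers(len(starts))]
            lengths = nx.single_source_shortest_path_length(
                self.sys.graph, a, cutoff=size - 2)
            ends = [b for b, d in lengths.items() if d == size - 2
                    and self.sys.atoms[b].element == "C"
                    and b not in self.blocked and self._hydrogens(b)]
            if not ends:
                continue
            b = ends[self.rng.integers(len(ends))]
            path = nx.shortest_path(self.sys.graph, a, b)
            if any(p in self.blocked for p in path):
                continue
            before = oxygen_rings(self.sys)
            self._delete_h(a)
            self._delete_h(b)
            o_w = self._new_atom("O", a)
            self.sys.add_bond(a, o_w)
            self.sys.add_bond(b, o_w)
            after = oxygen_rings(self.sys)
            expected = {k: before[k] + (1 if k == size else 0) for k in before}
            if after == expected:
                self._block(path + [o_w])
                return
            # undo (fresh H caps balance the deleted ones in the ledger)
            self.sys.remove_atom(o_w)
            self.mass_added -= ATOMIC_WEIGHTS["O"]
            for c in (a, b):
                self.sys.add_bond(c, self._new_atom("H", c))
        raise RuntimeError(f"no site found for a water-oxygen {size}-ring")

    def add_ether_crosslink(self) -> None:
        """Insert a water oxygen as a long-range C-O-C bridge."""
        sites = [i for i in self.sys.ids()
                 if self.sys.atoms[i].element == "C"
                 and i not in self.blocked and self._hydrogens(i)]
        for _ in range(200):
            if len(sites) < 2:
                break
            a, b = self.rng.choice(len(sites), size=2, replace=False)
            a, b = sites[a], sites[b]
            try:
                d = nx.shortest_path_length(self.sys.graph, a, b)
            except nx.NetworkXNoPath:
                d = 99
            if d < 8:
                continue
            self._delete_h(a)
            self._delete_h(b)
            o_w = self._new_atom("O", a)
            self.sys.add_bond(a, o_w)
            self.sys.add_bond(b, o_w)
            self._block((a, b, o_w))
            return
        raise RuntimeError("no site pair found for an ether bridge")

    # -- cross-links -------------------------------------------------------

    def crosslink(self, n_total: int) -> None:
        comps = sorted(nx.connected_components(self.sys.graph),
                       key=lambda c: min(c))
        needed = len(comps) - 1
        if n_total < needed:
            raise ValueError(
                f"schedule provides {n_total} cross-links but {needed} are "
                "needed to fuse the particle into one molecule")

        def pick(ids: Sequence[int]) -> int:
            # pass 1: untouched C-H; pass 2: carbons with no O neighbour;
            # pass 3: any CH2/CH3 (losing one H cannot break a counted group)
            tests = (
                lambda i: self._hydrogens(i) and i not in self.blocked,
                lambda i: self._hydrogens(i)
                and not any(self.sys.atoms[j].element == "O"
                            for j in self.sys.neighbors(i)),
                lambda i: len(self._hydrogens(i)) >= 2,
            )
            for test in tests:
                pool = [i for i in ids
                        if i in self.sys.atoms
                        and self.sys.atoms[i].element == "C" and test(i)]
                if pool:
                    return pool[self.rng.integers(len(pool))]
            raise RuntimeError("no carbon with hydrogen left for cross-link")

        cluster = sorted(comps[0])
        for comp in comps[1:]:
            a = pick(cluster)
            b = pick(sorted(comp))
            self._delete_h(a)
            self._delete_h(b)
            self.sys.add_bond(a, b)
            self._block((a, b))
            cluster.extend(sorted(comp))
        for _ in range(n_total - needed):
            for _attempt in range(200):
                a = pick(cluster)
                b = pick(cluster)
                if a == b:
                    continue
                if nx.shortest_path_length(self.sys.graph, a, b) >= 8:
                    self._delete_h(a)
                    self._delete_h(b)
                    self.sys.add_bond(a, b)
                    self._block((a, b))
                    break
            else:
                raise RuntimeError("no distant site pair for extra cross-link")

    def place_fragments(self) -> None:
        """Move detached fragments radially outside the particle."""
        if not self.sys.atoms or not self.fragments:
            return
        coords = self.sys.positions()
        com = coords.mean(axis=0)
        extent = float(np.linalg.norm(coords - com, axis=1).max())
        for k, frag in enumerate(self.fragments):
            direction = self.rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            fc = frag.positions()
            shift = com + direction * (extent + 1.0 + 0.4 * k) - fc.mean(axis=0)
            frag.set_positions(fc + shift)


def degrade(system: MolecularSystem, schedule: DegradationSchedule,
            site_class_weights: Tuple[float, float, float] = (0.6, 0.3, 0.1),
            verify: bool = True) -> DegradationResult:
    """Apply a degradation schedule to a pristine particle.

    Edits run in a fixed order (fragment cuts and scissions, attachments,
    ring closures, cross-links) so feasibility is checkable upfront; the
    final census of the main particle equals the planted counts exactly
    and the mass ledger closes to numerical precision.
    """
    plan = plan_edits(schedule)
    worker = _Degrader(system, schedule, site_class_weights)
    mass_initial = molar_mass(worker.sys.ids(), worker.sys)

    worker.dehydroxylate_ends()
    esters = worker.find_esters()
    est_initial = len(esters)
    needed_esters = (schedule.n_scission
                     + sum(plan.rings_existing.values()))
    if needed_esters > est_initial:
        raise ValueError(
            f"schedule needs {needed_esters} ester sites but only "
            f"{est_initial} exist")

    # ring sites are reserved before scission consumes the esters
    for _ in range(plan.n_fragments):
        if not worker.detach_fragment(esters):
            raise RuntimeError("no fragment site found")
    for mode, op in (("m_hydrolysis", worker.cut_hydrolysis),
                     ("m_aldehyde", worker.cut_aldehyde),
                     ("m_acid", worker.cut_acid),
                     ("m_decarbonyl", worker.cut_decarbonyl),
                     ("m_decarboxyl", worker.cut_decarboxyl)):
        for _ in range(getattr(plan, mode)):
            usable = [e for e in esters if worker._usable(e)]
            if not usable:
                raise RuntimeError(f"ran out of ester sites during {mode}")
            e = usable[worker.rng.integers(len(usable))]
            op(e)
    # ring-closure sites are reserved before attachments can deplete them
    ring_sites = [(size, worker.reserve_ring_site(size, esters))
                  for size in (6, 5, 4)
                  for _ in range(plan.rings_existing.get(size, 0))]
    epoxide_pairs = [worker.reserve_epoxide_pair()
                     for _ in range(plan.rings_water.get(3, 0))]
    # aromatic-site attachments first: their sites are scarcer than C-H ones
    for _ in range(plan.att_COOH):
        worker.attach_cooh()
    for _ in range(plan.att_CHO):
        worker.attach_cho()
    for _ in range(plan.att_CO):
        worker.attach_co()
    for _ in range(plan.att_OH):
        worker.attach_oh()
    for size, site in ring_sites:
        worker.close_ring_existing(size, site)
    for size in (6, 5, 4):
        for _ in range(plan.rings_water.get(size, 0)):
            worker.close_ring_water(size)
    for pair in epoxide_pairs:
        worker.close_epoxide(pair)
    for _ in range(plan.n_ether):
        worker.add_ether_crosslink()
    if schedule.n_crosslink or schedule.n_scission:
        worker.crosslink(schedule.n_crosslink)
    worker.place_fragments()

    mass_main = molar_mass(worker.sys.ids(), worker.sys)
    mass_frag = sum(molar_mass(f.ids(), f) for f in worker.fragments)
    ledger = {
        "mass_initial": mass_initial,
        "mass_main": mass_main,
        "mass_fragments": mass_frag,
        "mass_added": worker.mass_added,
        "mass_removed": worker.mass_removed,
        "balance": (mass_main + mass_frag
                    - mass_initial - worker.mass_added
                    + worker.mass_removed),
    }

    if verify:
        observed = census(worker.sys, reference=system)
        expected = {
            "EST": est_initial - schedule.n_scission,
            "OH": schedule.n_OH,
            "CHO": schedule.n_CHO, "COOH": schedule.n_COOH,
            "CO": schedule.n_CO, "R3": schedule.n_R3, "R4": schedule.n_R4,
            "R5": schedule.n_R5, "R6": schedule.n_R6,
            "N_Ow": schedule.n_Ow,
        }
        mismatches = {k: (getattr(observed, k), v)
                      for k, v in expected.items()
                      if getattr(observed, k) != v}
        if mismatches:
            raise RuntimeError(
                f"degradation did not close the census loop: {mismatches}")
    return DegradationResult(worker.sys, worker.fragments, ledger)

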