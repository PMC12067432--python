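"""Independent brute-force oracles used by the census tests.

These re-derive the functional-group definitions from scratch (different
code path and data structures from the package) so census results can be
checked by exhaustive enumeration on small molecules.
"""

from __future__ import annotations

from typing import Dict

import networkx as nx
import numpy as np

from petnano.core import Atom, MolecularSystem

VALENCE = {"C": 4, "O": 2, "H": 1}


def random_molecule(rng: np.random.Generator,
                    max_heavy: int = 12) -> MolecularSystem:
    """Random valence-legal C/H/O molecule, possibly with small rings.

    A random heavy-atom tree is grown, a few ring-closing edges are added
    between vertex-disjoint sites, and remaining valences are filled with
    hydrogens. Rings never share atoms, so smallest-ring counting is
    unambiguous.
    """
    n_heavy = int(rng.integers(2, max_heavy + 1))
    elements = ["C" if rng.random() < 0.65 else "O" for _ in range(n_heavy)]
    graph = nx.Graph()
    graph.add_node(0)
    free = {0: VALENCE[elements[0]]}
    for i in range(1, n_heavy):
        hosts = [j for j, v in free.items() if v > 0]
        if not hosts:
            break
        host = hosts[rng.integers(len(hosts))]
        graph.add_edge(host, i)
        free[host] -= 1
        free[i] = VALENCE[elements[i]] - 1
    # a few ring closures between atoms in disjoint neighbourhoods
    in_ring = set()
    for _ in range(int(rng.integers(0, 3))):
        candidates = [j for j, v in free.items()
                      if v > 0 and j not in in_ring and j in graph]
        rng.shuffle(candidates)
        done = False
        for a in candidates:
            if done:
                break
            lengths = nx.single_source_shortest_path_length(graph, a,
                                                            cutoff=5)
            for b, dist in lengths.items():
                if (2 <= dist <= 5 and free.get(b, 0) > 0
                        and b not in in_ring and not graph.has_edge(a, b)):
                    path = nx.shortest_path(graph, a, b)
                    if any(p in in_ring for p in path):
                        continue
                    graph.add_edge(a, b)
                    free[a] -= 1
                    free[b] -= 1
                    in_ring.update(path)
                    done = True
                    break
    system = MolecularSystem()
    for i in sorted(graph.nodes):
        system.add_atom(Atom(i, elements[i], np.zeros(3)))
    for a, b in graph.edges:
        system.add_bond(a, b)
    next_id = n_heavy
    for i in sorted(graph.nodes):
        for _ in range(free.get(i, 0)):
            system.add_atom(Atom(next_id, "H", np.zeros(3)))
            system.add_bond(i, next_id)
            next_id += 1
    return system


def oracle_census(system: MolecularSystem) -> Dict[str, int]:
    """Exhaustive group/ring enumeration, independent of the package."""
    g = system.graph
    elem = {i: system.atoms[i].element for i in system.atoms}

    def nbr(i, kind):
        return [j for j in g.neighbors(i) if elem[j] == kind]

    counts = {"EST": 0, "OH": 0, "CHO": 0, "COOH": 0, "CO": 0,
              "R3": 0, "R4": 0, "R5": 0, "R6": 0}
    carboxyl_carbons = set()
    for c in g.nodes:
        if elem[c] != "C":
            continue
        os = nbr(c, "O")
        terminal = [o for o in os if g.degree(o) == 1]
        bridging = [o for o in os if g.degree(o) == 2]
        if len(os) == 2 and len(terminal) == 1 and len(bridging) == 1:
            partner = [x for x in g.neighbors(bridging[0]) if x != c][0]
            if elem[partner] == "C":
                counts["EST"] += 1
                continue
            if elem[partner] == "H":
                counts["COOH"] += 1
                carboxyl_carbons.add(c)
                continue
        if len(os) == 1 and terminal:
            n_c = len(nbr(c, "C"))
            n_h = len(nbr(c, "H"))
            if n_h >= 1 and n_c == 1:
                counts["CHO"] += 1
            elif n_c == 2 and n_h == 0:
                counts["CO"] += 1
    for o in g.nodes:
        if elem[o] != "O" or g.degree(o) != 2:
            continue
        kinds = sorted(elem[x] for x in g.neighbors(o))
        if kinds != ["C", "H"]:
            continue
        carbon = next(x for x in g.neighbors(o) if elem[x] == "C")
        if carbon not in carboxyl_carbons:
            counts["OH"] += 1

    # smallest-set-of-smallest-rings: enumerate ALL simple cycles, then
    # add them shortest-first while independent over GF(2) on edge space
    # (boolean-vector elimination, unlike the implementation's bitmasks)
    cycles = [c for c in nx.simple_cycles(g) if len(c) >= 3]
    cycles.sort(key=lambda c: (len(c),
                               sum(1 for v in c if elem[v] == "O"),
                               tuple(sorted(c))))
    edge_ids = {frozenset(e): k for k, e in enumerate(g.edges)}
    rows = {}  # pivot index -> reduced boolean vector
    for cycle in cycles:
        vec = np.zeros(len(edge_ids), dtype=bool)
        for pair in zip(cycle, cycle[1:] + cycle[:1]):
            vec[edge_ids[frozenset(pair)]] = True
        while vec.any():
            pivot = int(np.argmax(vec))
            if pivot in rows:
                vec = vec ^ rows[pivot]
            else:
                rows[pivot] = vec
                if len(cycle) <= 6 and any(elem[v] == "O" for v in cycle):
                    counts[f"R{len(cycle)}"] += 1
                break
    return counts
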