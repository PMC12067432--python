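"""Close contacts with domain attribution, RMSD/RMSF and energy traces.

Close contacts are protein/nanoparticle heavy-atom pairs within a cutoff
(default 0.4 nm), attributed to the albumin domain of the protein residue;
the canonical domain ranges I = 1-195, II = 196-383, III = 384-585 are the
default. RMSD uses Kabsch superposition; RMSF is the per-residue
fluctuation about a reference after per-frame superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import MolecularSystem, Trajectory
from .energy import EnergyModel, PairEnergy, RigidBody, RigidPose


@dataclass(frozen=True)
class DomainMap:
    """Half-open residue-index ranges of named protein domains."""

    ranges: Tuple[Tuple[str, int, int], ...] = (
        ("I", 1, 196), ("II", 196, 384), ("III", 384, 586))

    def __post_init__(self):
        last = None
        for name, lo, hi in self.ranges:
            if lo >= hi:
                raise ValueError(f"empty domain range {name}")
            if last is not None and lo < last:
                raise ValueError("domain ranges must be ordered and disjoint")
            last = hi

    def assign(self, residue_index: int) -> str:
        for name, lo, hi in self.ranges:
            if lo <= residue_index < hi:
                return name
        raise ValueError(f"residue index {residue_index} outside all domains")


def assign_domains(residue_index: int,
                   domain_map: Optional[DomainMap] = None) -> str:
    """Domain label of a residue (half-open range convention)."""
    return (domain_map or DomainMap()).assign(residue_index)


@dataclass
class ContactReport:
    """Close-contact statistics over frames, in the printed table layout."""

    mean: float
    std: float
    domain_fractions: Dict[str, float]   # percentages summing to 100


def close_contacts(protein: MolecularSystem, nanoparticle: MolecularSystem,
                   frames: Sequence[np.ndarray], cutoff: float = 0.4,
                   domain_map: Optional[DomainMap] = None) -> ContactReport:
    """Count heavy-atom contact pairs per frame with domain attribution.

    ``frames`` holds nanoparticle coordinate arrays (one per frame, in the
    protein frame of reference); the protein is rigid. Every
    protein-heavy-atom / particle-heavy-atom pair within the cutoff counts
    as one contact assigned to the domain of the protein residue.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(frames) == 0:
        raise ValueError("no frames supplied")
    dmap = domain_map or DomainMap()
    p_ids = [i for i in protein.ids() if protein.atoms[i].element != "H"]
    n_idx = [k for k, i in enumerate(nanoparticle.ids())
             if nanoparticle.atoms[i].element != "H"]
    p_coords = protein.positions(p_ids)
    p_domains = [dmap.assign(protein.atoms[i].residue_index or 1)
                 for i in p_ids]
    tree = cKDTree(p_coords)

    totals = []
    by_domain = {name: 0 for name, _, _ in dmap.ranges}
    for frame in frames:
        frame = np.asarray(frame, dtype=float)
        n_coords = frame[n_idx]
        count = 0
        for hits in tree.query_ball_point(n_coords, cutoff):
            for p_k in hits:
                by_domain[p_domains[p_k]] += 1
                count += 1
        totals.append(count)
    grand = sum(by_domain.values())
    fractions = {name: (100.0 * v / grand if grand else 0.0)
                 for name, v in by_domain.items()}
    return ContactReport(mean=float(np.mean(totals)),
                         std=float(np.std(totals)),
                         domain_fractions=fractions)


def kabsch_rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
                return_transform: bool = False):
    """Optimal-superposition RMSD between two coordinate sets, nm."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must share an (N, 3) shape")
    if len(a) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    aligned = a0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - b0) ** 2, axis=1))))
    if return_transform:
        return rmsd, rot, cb - rot @ ca
    return rmsd


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``reference``."""
    _rmsd, rot, shift = kabsch_rmsd(mobile, reference, return_transform=True)
    return np.asarray(mobile) @ rot.T + shift


def rmsf(trajectory: Trajectory, reference: np.ndarray,
         residue_indices: Sequence[int],
         superpose_frames: bool = True) -> Dict[int, float]:
    """Per-residue root-mean-square fluctuation about a reference, nm."""
    if len(trajectory) < 2:
        raise ValueError("need at least two frames")
    reference = np.asarray(reference, dtype=float)
    devs = np.zeros((len(trajectory), len(reference)))
    for t, frame in enumerate(trajectory.frames):
        coords = superpose(frame, reference) if superpose_frames else frame
        devs[t] = np.sum((coords - reference) ** 2, axis=1)
    per_atom = np.sqrt(devs.mean(axis=0))
    result: Dict[int, List[float]] = {}
    for value, res in zip(per_atom, residue_indices):
        result.setdefault(res, []).append(value)
    return {res: float(np.mean(vals)) for res, vals in result.items()}


def pair_energy_trace(protein: MolecularSystem,
                      nanoparticle: MolecularSystem,
                      poses: Sequence[RigidPose],
                      model: Optional[EnergyModel] = None
                      ) -> Dict[str, Tuple[float, float]]:
    """Coulomb and vdW pair-energy statistics over equilibrium poses.

    Returns mean and standard deviation for each component in the printed
    table layout. The vacuum (unscaled) model is the default.
    """
    if len(poses) == 0:
        raise ValueError("no poses supplied")
    model = model or EnergyModel.rescoring_model()
    energy = PairEnergy(RigidBody(protein), RigidBody(nanoparticle), model)
    values = np.array([energy(p) for p in poses])
    return {
        "coulomb": (float(values[:, 0].mean()), float(values[:, 0].std())),
        "vdw": (float(values[:, 1].mean()), float(values[:, 1].std())),
    }
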