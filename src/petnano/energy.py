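"""Implicit-solvent rigid-body interaction energies.

The electrostatic term is a Debye-screened Coulomb interaction,

    E_el = q_i q_j / (4 pi eps_0 eps_r r) * exp(-r / kappa),

with the relative permittivity of water and the Debye length of a
0.15 mol/L 1:1 electrolyte (about 0.78 nm at 300 K). Dispersion is a
per-element Lennard-Jones term with Lorentz-Berthelot mixing; during the
binding-site search the LJ well depths are scaled by 0.1 to smooth the
energy surface, and candidate poses are afterwards rescored with the
unscaled, unscreened vacuum model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import (COULOMB_CONSTANT, LJ_PARAMS,
                        WATER_RELATIVE_PERMITTIVITY, debye_length)
from .core import MolecularSystem

#: Pair distances are clamped at this value to keep energies finite, nm.
MIN_PAIR_DISTANCE = 0.01


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the screened-Coulomb + scaled-LJ pair energy."""

    epsilon_r: float = WATER_RELATIVE_PERMITTIVITY
    kappa: float = field(default_factory=debye_length)  # nm
    lj_scale: float = 0.1
    lj_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(LJ_PARAMS))
    cutoff: Optional[float] = None

    def __post_init__(self):
        if self.kappa <= 0 and not math.isinf(self.kappa):
            raise ValueError("kappa must be positive (or inf for unscreened)")
        if not 0 < self.lj_scale <= 1:
            raise ValueError("lj_scale must lie in (0, 1]")

    @classmethod
    def scan_model(cls) -> "EnergyModel":
        """Screened, LJ-scaled model used during the metadynamics search."""
        return cls()

    @classmethod
    def rescoring_model(cls) -> "EnergyModel":
        """Unscaled vacuum model used to rescore candidate poses."""
        return cls(epsilon_r=1.0, kappa=math.inf, lj_scale=1.0)


def screened_coulomb(q_i: float, q_j: float, r: float,
                     model: EnergyModel) -> float:
    """Debye-screened Coulomb pair energy, kJ/mol."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    energy = COULOMB_CONSTANT * q_i * q_j / (model.epsilon_r * r)
    if math.isfinite(model.kappa):
        energy *= math.exp(-r / model.kappa)
    return energy


def lj_pair(elem_i: str, elem_j: str, r: float, model: EnergyModel) -> float:
    """Scaled 12-6 Lennard-Jones pair energy with Lorentz-Berthelot mixing."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    try:
        sig_i, eps_i = model.lj_params[elem_i]
        sig_j, eps_j = model.lj_params[elem_j]
    except KeyError as exc:
        raise ValueError(f"no LJ parameters for element {exc}") from None
    sigma = 0.5 * (sig_i + sig_j)
    epsilon = math.sqrt(eps_i * eps_j)
    sr6 = (sigma / r) ** 6
    return model.lj_scale * 4.0 * epsilon * (sr6 * sr6 - sr6)


@dataclass
class RigidPose:
    """Orientation (unit quaternion, scalar-last) and translation of the
    nanoparticle frame relative to the protein frame, nm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        norm = np.linalg.norm(self.rotation)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("rotation quaternion must be normalised")

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        rot = Rotation.from_quat(self.rotation)
        return rot.apply(coords) + self.translation

    def copy(self) -> "RigidPose":
        return RigidPose(self.rotation.copy(), self.translation.copy())


class RigidBody:
    """Coordinates (centred on the centre of mass), charges and elements of
    a rigid molecule, pre-extracted for fast pose energies."""

    def __init__(self, system: MolecularSystem):
        ids = system.ids()
        coords = system.positions(ids)
        self.masses = system.masses(ids)
        com = np.average(coords, axis=0, weights=self.masses)
        self.coords = coords - com
        self.charges = system.charges(ids)
        self.elements = system.elements(ids)
        self.ids = ids


def _pair_tables(body_a: RigidBody, body_b: RigidBody,
                 model: EnergyModel) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-mixed charge products and LJ coefficient matrices."""
    for elem in set(body_a.elements) | set(body_b.elements):
        if elem not in model.lj_params:
            raise ValueError(f"no LJ parameters for element {elem}")
    qq = np.outer(body_a.charges, body_b.charges)
    sig_a = np.array([model.lj_params[e][0] for e in body_a.elements])
    sig_b = np.array([model.lj_params[e][0] for e in body_b.elements])
    eps_a = np.array([model.lj_params[e][1] for e in body_a.elements])
    eps_b = np.array([model.lj_params[e][1] for e in body_b.elements])
    sigma = 0.5 * (sig_a[:, None] + sig_b[None, :])
    epsilon = np.sqrt(np.outer(eps_a, eps_b))
    return qq, sigma, epsilon


class PairEnergy:
    """Reusable inter-body energy evaluator for one (protein, NP) pair."""

    def __init__(self, protein: RigidBody, nanoparticle: RigidBody,
                 model: EnergyModel):
        self.protein = protein
        self.np_body = nanoparticle
        self.model = model
        self.qq, self.sigma, self.epsilon = _pair_tables(
            protein, nanoparticle, model)
        self.has_charges = (np.abs(protein.charges).sum() > 0
                            or np.abs(nanoparticle.charges).sum() > 0)

    def __call__(self, pose: RigidPose) -> Tuple[float, float]:
        """(coulomb, vdw) energies of the posed nanoparticle, kJ/mol."""
        moved = pose.apply(self.np_body.coords)
        delta = self.protein.coords[:, None, :] - moved[None, :, :]
        r = np.sqrt(np.maximum(np.sum(delta * delta, axis=-1),
                               MIN_PAIR_DISTANCE ** 2))
        if self.model.cutoff is not None:
            mask = r <= self.model.cutoff
        else:
            mask = None
        coul = COULOMB_CONSTANT * self.qq / (self.model.epsilon_r * r)
        if math.isfinite(self.model.kappa):
            coul = coul * np.exp(-r / self.model.kappa)
        sr6 = (self.sigma / r) ** 6
        vdw = self.model.lj_scale * 4.0 * self.epsilon * (sr6 * sr6 - sr6)
        if mask is not None:
            coul = np.where(mask, coul, 0.0)
            vdw = np.where(mask, vdw, 0.0)
        return float(coul.sum()), float(vdw.sum())


def pose_energy(protein: MolecularSystem, nanoparticle: MolecularSystem,
                pose: RigidPose, model: EnergyModel) -> Tuple[float, float]:
    """(coulomb, vdw) interaction energy between two posed rigid bodies.

    Sums over all inter-body pairs (no cutoff unless the model sets one);
    the nanoparticle is rotated about its centre of mass and translated by
    the pose. Distances are clamped at 0.01 nm to keep energies finite.
    """
    evaluator = PairEnergy(RigidBody(protein), RigidBody(nanoparticle), model)
    return evaluator(pose)
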