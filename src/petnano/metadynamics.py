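"""Well-tempered metadynamics search for nanoparticle binding sites.

The nanoparticle rolls over the rigid protein surface: a seeded Metropolis
rigid-body Monte Carlo walk samples poses under the smoothed (LJ-scaled,
Debye-screened) energy plus a history-dependent bias built from Gaussian
hills over the spherical angles (theta, phi) of the nanoparticle centre of
mass in the protein frame. Hills of base height 0.8 kJ/mol are deposited
every 1000 accepted steps and rescaled well-tempered fashion with bias
factor 20; a reflecting wall keeps the centre-of-mass distance below 7 nm.
The bias is purely a search device: visited poses are afterwards rescored
with the unscaled vacuum energy model and the lowest-energy pose is
selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB
from .core import MolecularSystem
from .energy import EnergyModel, PairEnergy, RigidBody, RigidPose


@dataclass
class HillStore:
    """Deposited metadynamics hills over (theta, phi)."""

    base_height: float = 0.8        # kJ/mol
    stride: int = 1000              # accepted steps between depositions
    bias_factor: float = 20.0
    temperature: float = 300.0      # K
    width: float = 0.1              # rad, both collective variables
    centers: List[Tuple[float, float]] = field(default_factory=list)
    heights: List[float] = field(default_factory=list)

    def deposit(self, theta: float, phi: float) -> float:
        """Add a hill at (theta, phi) with well-tempered height rescaling."""
        delta_t = (self.bias_factor - 1.0) * self.temperature
        height = self.base_height * math.exp(
            -self.potential(theta, phi) / (KB * delta_t))
        self.centers.append((theta, phi))
        self.heights.append(height)
        return height

    def potential(self, theta: float, phi: float) -> float:
        """Accumulated bias at (theta, phi), kJ/mol; periodic in phi."""
        if not self.centers:
            return 0.0
        centers = np.asarray(self.centers)
        heights = np.asarray(self.heights)
        d_theta = theta - centers[:, 0]
        d_phi = np.mod(phi - centers[:, 1] + np.pi, 2.0 * np.pi) - np.pi
        w2 = 2.0 * self.width ** 2
        return float(np.sum(heights * np.exp(-(d_theta ** 2) / w2)
                            * np.exp(-(d_phi ** 2) / w2)))


def bias_potential(hills: HillStore, theta: float, phi: float) -> float:
    return hills.potential(theta, phi)


@dataclass
class ScanConfig:
    """Monte Carlo and wall parameters of the binding-site scan."""

    wall_distance: float = 7.0      # nm, reflecting wall on the COM distance
    n_steps: int = 50000
    translation_step: float = 0.05  # nm
    rotation_step: float = 0.10     # rad
    seed: int = 0
    temperature: float = 300.0      # K

    def __post_init__(self):
        if self.wall_distance <= 0:
            raise ValueError("wall_distance must be positive")


def collective_variables(pose: RigidPose,
                         protein: Optional[MolecularSystem] = None,
                         nanoparticle: Optional[MolecularSystem] = None
                         ) -> Tuple[float, float]:
    """Spherical angles of the NP centre of mass in the protein frame.

    Both bodies are centred on their centres of mass, so the pose
    translation *is* the COM separation vector. theta is the polar angle
    from +z, phi the azimuth wrapped to (-pi, pi].
    """
    x, y, z = pose.translation
    r = math.sqrt(x * x + y * y + z * z)
    if r < 1e-9:
        raise ValueError("coincident centres of mass: angles undefined")
    theta = math.acos(max(-1.0, min(1.0, z / r)))
    phi = math.atan2(y, x)
    if phi <= -math.pi:
        phi = math.pi
    return theta, phi


@dataclass
class ScanTrajectory:
    """Recorded poses of a metadynamics scan with energies and CVs."""

    poses: List[RigidPose] = field(default_factory=list)
    scaled_energy: List[float] = field(default_factory=list)
    bias: List[float] = field(default_factory=list)
    cvs: List[Tuple[float, float]] = field(default_factory=list)
    hill_log: List[Tuple[int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.poses)


def _random_pose(rng: np.random.Generator, r_min: float,
                 r_max: float) -> RigidPose:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = rng.uniform(r_min, r_max)
    quat = Rotation.random(random_state=rng).as_quat()
    return RigidPose(quat, direction * radius)


def metadynamics_scan(protein: MolecularSystem,
                      nanoparticle: MolecularSystem,
                      model: EnergyModel,
                      config: ScanConfig,
                      hills: Optional[HillStore] = None) -> ScanTrajectory:
    """Run the biased rigid-body Monte Carlo scan and record every pose."""
    body_p = RigidBody(protein)
    body_n = RigidBody(nanoparticle)
    energy = PairEnergy(body_p, body_n, model)
    if hills is None:
        hills = HillStore(temperature=config.temperature)
    rng = np.random.default_rng(config.seed)
    beta = 1.0 / (KB * config.temperature)

    # start at a random orientation just inside the wall
    extent_p = float(np.linalg.norm(body_p.coords, axis=1).max())
    extent_n = float(np.linalg.norm(body_n.coords, axis=1).max())
    contact = extent_p + extent_n
    pose = _random_pose(rng, min(contact, config.wall_distance * 0.9),
                        config.wall_distance * 0.95)

    traj = ScanTrajectory()
    e_c, e_v = energy(pose)
    e_scaled = e_c + e_v
    theta, phi = collective_variables(pose)
    v_bias = hills.potential(theta, phi)
    accepted = 0
    attempts_without_acceptance = 0

    for step in range(config.n_steps):
        trial = pose.copy()
        trial.translation = (trial.translation
                             + rng.normal(scale=config.translation_step,
                                          size=3))
        rot_vec = rng.normal(scale=config.rotation_step, size=3)
        quat = (Rotation.from_rotvec(rot_vec)
                * Rotation.from_quat(trial.rotation)).as_quat()
        trial.rotation = quat / np.linalg.norm(quat)

        # reflecting wall on the COM separation
        dist = float(np.linalg.norm(trial.translation))
        if dist > config.wall_distance:
            trial.translation *= (2.0 * config.wall_distance - dist) / dist
            dist = float(np.linalg.norm(trial.translation))
        if dist < 1e-6:
            continue

        te_c, te_v = energy(trial)
        te_scaled = te_c + te_v
        t_theta, t_phi = collective_variables(trial)
        tv_bias = hills.potential(t_theta, t_phi)
        delta = (te_scaled + tv_bias) - (e_scaled + v_bias)
        if delta <= 0 or rng.random() < math.exp(-beta * delta):
            pose = trial
            e_scaled, theta, phi, v_bias = te_scaled, t_theta, t_phi, tv_bias
            accepted += 1
            attempts_without_acceptance = 0
            if accepted % hills.stride == 0:
                height = hills.deposit(theta, phi)
                traj.hill_log.append((step, height))
                v_bias = hills.potential(theta, phi)
        else:
            attempts_without_acceptance += 1
            if attempts_without_acceptance >= 10000:
                raise RuntimeError(
                    "no accepted move in 10000 attempts; reduce "
                    "translation_step/rotation_step")
        traj.poses.append(pose.copy())
        traj.scaled_energy.append(e_scaled)
        traj.bias.append(v_bias)
        traj.cvs.append((theta, phi))
    return traj


def rescore_and_select(trajectory: ScanTrajectory,
                       protein: MolecularSystem,
                       nanoparticle: MolecularSystem,
                       model_unscaled: Optional[EnergyModel] = None
                       ) -> Tuple[RigidPose, "np.ndarray"]:
    """Rescore all visited poses with the unscaled vacuum model.

    Returns the lowest-energy pose and the full energy table with columns
    (coulomb, vdw, total), one row per trajectory pose.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if model_unscaled is None:
        model_unscaled = EnergyModel.rescoring_model()
    energy = PairEnergy(RigidBody(protein), RigidBody(nanoparticle),
                        model_unscaled)
    table = np.empty((len(trajectory), 3))
    for k, pose in enumerate(trajectory.poses):
        e_c, e_v = energy(pose)
        table[k] = (e_c, e_v, e_c + e_v)
    best = int(np.argmin(table[:, 2]))
    return trajectory.poses[best].copy(), table
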