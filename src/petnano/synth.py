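"""Synthetic umbrella-sampling datasets and toy rigid-body complexes.

Umbrella windows are drawn i.i.d. from the exact biased density
rho_i(x) ~ exp(-beta [F(x) + k/2 (x - x_i)^2]) by grid inverse-CDF
sampling, so the WHAM stage can be validated against a known generating
free-energy profile without running any dynamics. The default window
layout matches the production protocol: 17-24 windows spaced 0.2 nm with
k = 1000 kJ mol^-1 nm^-2 at 310 K.

The toy complex generator builds small rigid charge-patched bodies (a
protein stand-in with three labelled domains and a compact nanoparticle)
for exercising the binding-site scan against brute-force grid oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import KB
from .core import Atom, MolecularSystem
from .wham import UmbrellaWindow


@dataclass(frozen=True)
class GaussianWellPMF:
    """Single-well profile F(x) = -depth * exp(-(x-center)^2 / 2 width^2).

    Rises to a flat plateau at zero on separation; the adsorption free
    energy of the well is -depth.
    """

    depth: float              # kJ/mol
    center: float = 1.0       # nm
    width: float = 0.5        # nm

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return -self.depth * np.exp(-((x - self.center) ** 2)
                                    / (2.0 * self.width ** 2))


@dataclass
class UmbrellaDataset:
    windows: List[UmbrellaWindow]
    pmf: Callable[[np.ndarray], np.ndarray]
    temperature: float
    seed: int


def generate_umbrella_dataset(pmf: Callable[[np.ndarray], np.ndarray],
                              n_windows: int = 20,
                              spacing: float = 0.2,
                              force_constant: float = 1000.0,
                              n_samples: int = 5000,
                              temperature: float = 310.0,
                              first_center: float = 0.8,
                              seed: int = 0,
                              grid_points: int = 4000) -> UmbrellaDataset:
    """Draw exact samples from every biased window density.

    Window i is centred at ``first_center + i * spacing``; each holds
    ``n_samples`` i.i.d. draws obtained by inverting the discretised CDF
    of exp(-beta [F(x) + k/2 (x - x_i)^2]) on a fine grid.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    beta = 1.0 / (KB * temperature)
    centers = first_center + spacing * np.arange(n_windows)
    sigma_free = math.sqrt(1.0 / (beta * force_constant))
    lo = centers.min() - 8 * sigma_free - spacing
    hi = centers.max() + 8 * sigma_free + spacing
    grid = np.linspace(lo, hi, grid_points)
    f_grid = np.asarray(pmf(grid), dtype=float)
    if not np.isfinite(f_grid).all():
        raise ValueError("generating PMF is not finite on the sampling grid")

    rng = np.random.default_rng(seed)
    windows = []
    for center in centers:
        energy = f_grid + 0.5 * force_constant * (grid - center) ** 2
        log_density = -beta * (energy - energy.min())
        density = np.exp(log_density)
        # trapezoidal CDF: a raw cumsum would shift every draw by half a
        # grid step, which the stiff umbrella springs would misread as a
        # spurious tilt of the recovered profile
        cdf = cumulative_trapezoid(density, grid, initial=0.0)
        cdf /= cdf[-1]
        u = rng.random(n_samples)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(center=float(center),
                                      force_constant=force_constant,
                                      samples=samples))
    return UmbrellaDataset(windows=windows, pmf=pmf,
                           temperature=temperature, seed=seed)


# -- toy rigid bodies ------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def generate_toy_complex(seed: int = 0,
                         n_protein: int = 60,
                         n_np: int = 8,
                         protein_radius: float = 0.8,
                         np_radius: float = 0.25,
                         domain_charges: Tuple[float, float, float]
                         = (2.0, 0.0, -2.0),
                         np_charge: float = -1.0
                         ) -> Tuple[MolecularSystem, MolecularSystem]:
    """Build a charge-patched protein stand-in and a small nanoparticle.

    The protein body is a spherical shell of carbon atoms split into three
    latitude bands ("domains" I/II/III, residue indices 1-3) carrying the
    requested net charges; the nanoparticle is a compact carbon cluster
    with ``np_charge`` spread uniformly. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    shell = _fibonacci_sphere(n_protein) * protein_radius
    shell += rng.normal(scale=0.01, size=shell.shape)
    protein = MolecularSystem()
    z_sorted = np.argsort(shell[:, 2])[::-1]
    bands = np.array_split(z_sorted, 3)
    for domain, (band, q_total) in enumerate(zip(bands, domain_charges),
                                             start=1):
        for i in band:
            protein.add_atom(Atom(
                id=int(i), element="C", position=shell[i],
                charge=q_total / len(band), origin="protein",
                residue_index=domain, residue_name=f"D{domain}"))

    cluster = _fibonacci_sphere(n_np) * np_radius
    cluster += rng.normal(scale=0.01, size=cluster.shape)
    nanoparticle = MolecularSystem()
    for i in range(n_np):
        nanoparticle.add_atom(Atom(
            id=i, element="C", position=cluster[i],
            charge=np_charge / n_np, origin="polymer"))
    return protein, nanoparticle
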