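"""Close contacts by domain, pair-energy traces and RMSD/RMSF on the toy
complex.

Takes the tail of a metadynamics scan as a stand-in equilibrium ensemble,
counts protein-particle close contacts attributed to the three labelled
domains, traces the vacuum Coulomb/vdW pair energies over those poses, and
demonstrates RMSD/RMSF on a jittered copy of the protein body.
"""

import json
import time
from pathlib import Path

import numpy as np

from petnano.core import Trajectory
from petnano.energy import EnergyModel, RigidBody
from petnano.metadynamics import ScanConfig, metadynamics_scan
from petnano.metrics import (DomainMap, close_contacts, kabsch_rmsd,
                             pair_energy_trace, rmsf)
from petnano.synth import generate_toy_complex

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    t0 = time.time()
    protein, nano = generate_toy_complex(
        seed=0, domain_charges=(6.0, 0.0, -6.0), np_charge=-3.0)
    config = ScanConfig(wall_distance=2.5, n_steps=20000, seed=1)
    traj = metadynamics_scan(protein, nano, EnergyModel.scan_model(), config)
    poses = traj.poses[-500:]

    body = RigidBody(nano)
    frames = [pose.apply(body.coords) for pose in poses]
    domain_map = DomainMap((("I", 1, 2), ("II", 2, 3), ("III", 3, 4)))
    contacts = close_contacts(protein, nano, frames, cutoff=0.5,
                              domain_map=domain_map)
    trace = pair_energy_trace(protein, nano, poses)

    rng = np.random.default_rng(0)
    ref = protein.positions()
    jitter_traj = Trajectory(atom_ids=protein.ids())
    for _ in range(20):
        jitter_traj.append(ref + rng.normal(scale=0.01, size=ref.shape))
    residues = [protein.atoms[i].residue_index for i in protein.ids()]
    fluct = rmsf(jitter_traj, ref, residues)
    rmsd_still = kabsch_rmsd(jitter_traj.frames[0], ref)

    payload = {
        "contacts_mean": contacts.mean,
        "contacts_std": contacts.std,
        "domain_fractions_percent": contacts.domain_fractions,
        "pair_energy_kJ_mol": {k: {"mean": v[0], "std": v[1]}
                               for k, v in trace.items()},
        "rmsf_nm_by_domain": {str(k): v for k, v in sorted(fluct.items())},
        "rmsd_jittered_frame_nm": rmsd_still,
    }
    (OUT / "structure_metrics.json").write_text(
        json.dumps(payload, indent=2))
    print(json.dumps(payload, indent=2))
    print(f"\nContacts concentrate on the attractive domain; the jittered "
          f"protein shows ~0.01 nm fluctuations, as constructed. "
          f"Done in {time.time() - t0:.1f} s.")


if __name__ == "__main__":
    main()
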