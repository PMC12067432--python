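"""Umbrella-sampling/WHAM free-energy recovery on synthetic windows.

Draws exact samples from harmonically biased windows over single-well
profiles with known depths spanning the adsorption regime of the
protein-particle systems (10-260 kJ/mol), reconstructs the PMF with WHAM
and reads the adsorption free energy off the plateau; one depth also gets
the full 200-iteration bootstrap error analysis.
"""

import time
from pathlib import Path

import pandas as pd

from petnano.synth import GaussianWellPMF, generate_umbrella_dataset
from petnano.wham import bootstrap_errors, delta_g, wham

OUT = Path(__file__).resolve().parents[1] / "results"
DEPTHS = (10.0, 55.0, 145.0, 260.0)
SEED = 3


def main():
    OUT.mkdir(exist_ok=True)
    t0 = time.time()
    rows = []
    for depth in DEPTHS:
        dataset = generate_umbrella_dataset(GaussianWellPMF(depth),
                                            seed=SEED)
        profile = wham(dataset.windows)
        dg = delta_g(profile)
        rows.append({"depth_kJ_mol": depth, "recovered_dG_kJ_mol": dg,
                     "abs_error_kJ_mol": abs(abs(dg) - depth),
                     "n_windows": len(dataset.windows)})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "pmf_recovery.csv", index=False)
    print(table.to_string(index=False))

    dataset = generate_umbrella_dataset(GaussianWellPMF(145.0), seed=SEED)
    boot = bootstrap_errors(dataset.windows, n_boot=200, seed=SEED)
    pmf = pd.DataFrame({"xi_nm": boot.bin_centers,
                        "F_kJ_mol": boot.free_energy,
                        "std_kJ_mol": boot.errors})
    pmf.to_csv(OUT / "pmf_145_profile.tsv", sep="\t", index=False)
    print(f"\n145 kJ/mol well with 200 bootstrap iterations: "
          f"dG = {boot.delta_g:.1f} +- {boot.delta_g_error:.2f} kJ/mol; "
          f"profile written to pmf_145_profile.tsv. "
          f"Done in {time.time() - t0:.1f} s.")


if __name__ == "__main__":
    main()
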