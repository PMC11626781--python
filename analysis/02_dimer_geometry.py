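#!/usr/bin/env python
"""Coiled-coil geometry of the synthetic dimers: recovery and stammer effects.

Measures the TWISTER-style per-residue profile of the ideal, stammer and
noisy dimers; confirms that the generator parameters (pitch, interhelical
radius, handedness, heptad register) are recovered, that the stammer is
detected at its construction site with a local pitch dip, and that an
ideal C2 dimer has zero asymmetry RMSD.

Writes results/dimer_geometry.tsv (per-structure summary) and
results/dimer_profile.tsv (per-residue profile of the ideal dimer).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from coilgeom import (CrickParams, assign_heptad, build_ideal_dimer, chirality,
                      coiled_coil_profile, insert_register_discontinuity,
                      perturb, pitch_summary, symmetry_rmsd)
from coilgeom.crick import dimer_traces

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 2024


def summarize(name, model):
    ta, tb = dimer_traces(model)
    prof = coiled_coil_profile(ta, tb)
    s = pitch_summary(prof)
    letters, disc = assign_heptad(prof)
    return prof, {
        "structure": name,
        "pitch_A": round(s["pitch_A"], 2),
        "residues_per_pitch": round(s["residues_per_pitch"], 2),
        "interhelical_radius_A": round(s["mean_interhelical_radius_A"], 3),
        "chirality": chirality(prof),
        "symmetry_rmsd_A": round(symmetry_rmsd(ta, tb), 3),
        "register_discontinuities": ",".join(map(str, disc)) or "none",
    }


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = CrickParams()
    ideal = build_ideal_dimer(params, 161)
    rows = []

    prof, row = summarize("ideal_dimer", ideal)
    rows.append(row)
    prof.to_dataframe().to_csv(RESULTS / "dimer_profile.tsv", sep="\t",
                               index=False, float_format="%.4f")

    _, row = summarize("stammer_dimer", insert_register_discontinuity(ideal, 80))
    rows.append(row)

    _, row = summarize("noisy_dimer_sigma0.3", perturb(ideal, 0.3, SEED))
    rows.append(row)

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "dimer_geometry.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    ideal_row = rows[0]
    target = abs(params.superhelical_pitch)
    err = abs(ideal_row["pitch_A"] - target) / target
    print(f"\npitch recovered to {100 * err:.2f}% of the generator value "
          f"({ideal_row['pitch_A']} vs {target} Å); "
          f"radius {ideal_row['interhelical_radius_A']} vs {params.superhelical_radius} Å")
    print(f"ideal dimer symmetry RMSD {ideal_row['symmetry_rmsd_A']} Å (C2 by construction); "
          f"stammer detected at residue {rows[1]['register_discontinuities']} "
          "(built at residue 80)")
    if err > 0.01:
        print("WARNING: pitch recovery outside 1%", file=sys.stderr)
        sys.exit(1)


if __name__ == "__main__":
    main()
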