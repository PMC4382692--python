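#!/usr/bin/env python
"""Water-oxygen mean-squared displacement across population mixes.

Generates free-space trajectories in which waters are split between
immobile (harmonic jitter), rotor (rigid rotation at the H-O radius) and
translator (Brownian walk) populations, and tabulates the oxygen MSD at a
100 ps lag.  For pure translators the Einstein relation MSD = 6 D t is
recovered; immobile and rotor oxygens contribute only their bounded
jitter, so the mixture MSD scales with the translating fraction."""

from pathlib import Path

import pandas as pd

from aquadyn import synthetic as syn
from aquadyn.hbonds import hb_timeseries, water_msd

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260106


def main() -> None:
    rows = []
    mixes = [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
             (0.4, 0.2, 0.4)]
    for i, fractions in enumerate(mixes):
        pop = syn.PopulationSpec(fractions=fractions, D_t=0.01)
        traj, topo, _ = syn.generate_water_trajectory(
            pop, n_waters=300, n_frames=301, dt=1.0, seed=SEED + i)
        msd = water_msd(traj, topo.water_oxygens, lag=100.0)
        rows.append({"f_immobile": fractions[0], "f_rotor": fractions[1],
                     "f_translator": fractions[2], "msd_100ps_A2": msd})
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "water_msd.tsv", sep="\t", index=False,
                 float_format="%.5g")
    print(table.to_string(index=False, float_format="%.4f".__mod__))
    print("\nPure translators: Einstein relation predicts 6 D t = 6.0 A^2 "
          "at 100 ps; the oxygen MSD of mixtures scales with the "
          "translating fraction.")


if __name__ == "__main__":
    main()
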