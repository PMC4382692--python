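#!/usr/bin/env python
"""Dynamical-transition detection from elastic scans.

Generates hydrated and dry elastic scans whose relative mean-squared
displacement differs by a hinge programmed at 240 K (the onset of
large-amplitude motion), extracts the MSDs by weighted ln I versus q^2
regression, forms the hydrated-minus-dry difference, and locates the
transition as the peak of the smoothed second derivative."""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from aquadyn import synthetic as syn
from aquadyn.elastic import msd_difference, msd_from_elastic, \
    transition_temperature

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260104


def main() -> None:
    T = np.arange(20.0, 310.0, 10.0)
    q = np.linspace(0.46, 1.4, 10)
    hydrated = syn.generate_elastic_scan(
        syn.hinge_msd_profile(T_star=240.0, slope_low=0.001,
                              slope_high=0.005),
        T, q, noise_c=0.01, seed=SEED)
    dry = syn.generate_elastic_scan(
        syn.hinge_msd_profile(T_star=1e9, slope_low=0.001),
        T, q, noise_c=0.01, seed=SEED + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        msd_h = msd_from_elastic(hydrated)
        msd_d = msd_from_elastic(dry)
        diff = msd_difference(msd_h, msd_d)
        result = transition_temperature(diff)

    table = pd.DataFrame({"T": T, "msd_hydrated": msd_h.msd,
                          "msd_dry": msd_d.msd, "delta_msd": diff.msd,
                          "delta_msd_err": diff.error})
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "elastic_msd.tsv", sep="\t", index=False,
                 float_format="%.5g")
    print(table.iloc[::4].to_string(index=False, float_format="%.4f".__mod__))
    if result.detected:
        print(f"\nTransition detected at T_d = {result.temperature:.0f} "
              f"+- {result.uncertainty:.0f} K (programmed hinge: 240 K).")
    else:
        print("\nNo transition detected.")


if __name__ == "__main__":
    main()
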