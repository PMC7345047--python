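#!/usr/bin/env python
"""Worked-example recovery of single catalogue signals.

Simulates every resolved (s/d/t/q) catalogue signal in isolation at zero
noise, runs the full processing chain (TSP referencing, peak picking,
multiplet grouping) and tabulates the recovered centre and multiplicity
against the printed values.  The headline example is the alanine methyl
doublet at 1.483 ppm; a centre is counted as recovered when it lands within
one grid step (~0.00015 ppm on the 20 ppm / 128k grid).
"""

from pathlib import Path

import pandas as pd

from nmrannotate.library import ReferenceLibrary, load_packaged_library
from nmrannotate.processing import group_multiplets, pick_peaks, reference_to_tsp
from nmrannotate.simulate import SimulationParams, simulate_spectrum

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lib = load_packaged_library()
    params = SimulationParams(rng_seed=1)
    rows = []
    for sig in lib.signals:
        if sig.multiplicity not in ("s", "d", "t", "q"):
            continue
        sub = ReferenceLibrary([sig])
        spec, _ = simulate_spectrum(sub, {sig.metabolite_name: 1.0}, params)
        peaks = pick_peaks(reference_to_tsp(spec))
        ms = group_multiplets(peaks, spectrometer_freq=params.spectrometer_freq)
        m = ms[0]
        rows.append(
            {
                "metabolite": sig.metabolite_name,
                "printed_shift": sig.shift_h1,
                "printed_multiplicity": sig.multiplicity,
                "recovered_centre": round(m.centre, 5),
                "recovered_multiplicity": m.multiplicity,
                "centre_error_ppm": round(abs(m.centre - sig.shift_h1), 6),
                "j_est_hz": None if m.j_est is None else round(m.j_est, 2),
                "recovered": (
                    m.multiplicity == sig.multiplicity
                    and abs(m.centre - sig.shift_h1) <= params.grid_step
                ),
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "worked_examples.tsv", sep="\t", index=False)
    ala = df[(df.metabolite == "Alanine") & (df.printed_shift == 1.483)].iloc[0]
    print(
        f"alanine methyl doublet: recovered centre {ala.recovered_centre} ppm "
        f"({ala.recovered_multiplicity}), error {ala.centre_error_ppm} ppm"
    )
    print(
        f"{int(df.recovered.sum())}/{len(df)} resolved catalogue signals recovered "
        f"at printed multiplicity within one grid step"
    )
    print(f"wrote {OUT/'worked_examples.tsv'}")


if __name__ == "__main__":
    main()
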