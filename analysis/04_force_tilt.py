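#!/usr/bin/env python
"""Desk-scale force-tilt model from the reported tilt moments.

Builds the truncated-Gaussian surrogate for the force-free tilt density
(mean 33.4 deg, SD 8.9 deg), reweights it by exp(f h sin(tau)/kBT) for a
range of transversal forces, and reports mode shifts and the implied
membrane-separation changes h cos(tau).  Writes results/force_tilt/*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tcrtilt.force_model import (
    force_response_table,
    gaussian_surrogate,
    membrane_separation,
    reweight,
)
from tcrtilt.structure_io import write_table

OUT = Path("results/force_tilt")


def main():
    model = gaussian_surrogate(33.4, 8.9)  # h = 13 nm, T = 303 K
    forces = [0.5, 1.0, 2.0, 3.0, 5.0]
    summary = force_response_table(model, forces)
    grid = pd.DataFrame({"tau_deg": np.degrees(model.tau), "P0": model.p0})
    for f in forces:
        grid[f"Pf_{f}pN"] = reweight(model, f)
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(summary, OUT / "mode_shifts.csv")
    write_table(grid, OUT / "densities.csv")

    for _, r in summary.iterrows():
        print(f"f = {r.force_pN:>3.1f} pN: mode {r.mode0_deg:.1f} -> "
              f"{r.mode_f_deg:.1f} deg")
    sep34, sep49 = membrane_separation(13, 34), membrane_separation(13, 49)
    print(f"separation h cos(tau): {sep34:.2f} nm at 34 deg, "
          f"{sep49:.2f} nm at 49 deg (decrease {sep34 - sep49:.2f} nm)")


if __name__ == "__main__":
    main()
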