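#!/usr/bin/env python
"""Fit the exponential acetylation gradient for control and kinesin conditions.

For each condition, simulates cells, extracts max-normalized AcTub/αTub
profiles, pools them in 0.005 distance bins, and fits Y(x) = Y0·exp(-x/λ)
with the plateau constrained to 0.  Writes the fitted parameters and the
binned master curves under results/gradient/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import acetograd as ag  # noqa: E402
from acetograd.gradient import bin_and_average, cell_radial_profile, fit_exponential
from acetograd.recovery import cell_seeds

OUT = Path(__file__).resolve().parents[1] / "results" / "gradient"
SEED = 1
N_CELLS = {"control": 42, "kinesin_low": 19, "kinesin_high": 19}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, n in N_CELLS.items():
        p = ag.preset(name)
        profiles = []
        for s in cell_seeds(SEED, n, stream=1):
            cell, _ = ag.generate_cell(p, s)
            profiles.append(cell_radial_profile(cell))
        binned = bin_and_average(profiles)
        fit = fit_exponential(binned)
        ok = binned.populated
        pd.DataFrame(
            {
                "bin_center": binned.bin_center[ok],
                "mean": binned.mean[ok],
                "sd": binned.sd[ok],
                "n": binned.n[ok],
            }
        ).to_csv(OUT / f"{name}_master_curve.csv", index=False)
        summary[name] = {
            "lambda": round(fit.lambda_, 4),
            "Y0": round(fit.Y0, 4),
            "generative_lambda": p.gradient_lambda,
            "n_cells": n,
        }
        print(
            f"{name:>12}: fitted λ = {fit.lambda_:.3f} "
            f"(condition encodes {p.gradient_lambda}), n = {n} cells"
        )
    (OUT / "fits.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {OUT}/fits.json - the gradient steepens as the motor spreads out")


if __name__ == "__main__":
    main()
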