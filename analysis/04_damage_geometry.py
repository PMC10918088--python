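#!/usr/bin/env python
"""Damage/repair-site vs deacetylated-stretch geometry from line-scan fixtures.

Draws 65 two-channel line scans from the damage-site statistics, applies
the 50 a.u. classifier, and measures stretch lengths, the
stretch-to-site length ratio, and the center-to-center displacement
(excluding center-colocalized sites).  Writes the per-site table and a
summary under results/damage/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import acetograd as ag  # noqa: E402
from acetograd.damage import measure_fixture
from acetograd.recovery import recover_damage_geometry
from acetograd.simulate import sample_damage_fixtures

OUT = Path(__file__).resolve().parents[1] / "results" / "damage"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (h, a, truth) in enumerate(
        sample_damage_fixtures(ag.preset("control"), 65, seed=SEED)
    ):
        m = measure_fixture(h, a)
        if m is None:
            continue
        rows.append(
            {
                "site_id": k,
                "L_dr_um": round(m.L_dr, 4),
                "L_deac_um": round(m.L_deac, 4),
                "displacement_um": round(m.center_displacement, 4),
                "formula_displacement_um": round(m.formula_displacement, 4),
                "ext_plus_um": round(m.ext_plus, 4),
                "ext_minus_um": round(m.ext_minus, 4),
                "embedded": m.embedded,
                "true_offset_um": round(truth["offset_um"], 4),
            }
        )
    pd.DataFrame(rows).to_csv(OUT / "sites.csv", index=False)
    summary = recover_damage_geometry(65, base_seed=SEED)
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"{summary['n_sites']} sites: stretches {summary['L_deac_mean_um']:.2f} µm, "
        f"{summary['ratio']:.2f}-fold longer than damage sites; "
        f"center offset {summary['offset_mean_nm']:.0f} nm among non-colocalized sites "
        f"({100 * summary['coloc_fraction']:.0f}% colocalized); "
        f"mean signed displacement {1000 * summary['mean_signed_displacement_um']:.0f} nm "
        "(no plus/minus polarity)"
    )
    print(f"wrote {OUT}/sites.csv and summary.json")


if __name__ == "__main__":
    main()
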