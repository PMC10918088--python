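"""End-to-end parameter-recovery runs on synthetic cells.

Each function generates cells for a named condition, pushes them through
the measurement pipeline, and returns summary statistics with standard
errors - the bridge between the simulator's known ground truth and the
image-analysis estimates.
"""

from __future__ import annotations

import numpy as np

from .colocalization import coloc_analysis
from .damage import measure_fixture
from .gradient import bin_and_average, cell_radial_profile, fit_exponential
from .metrics import acetylated_area_fraction, analyze_cell, segment_length_stats
from .presets import preset as get_preset
from .segmentation import trace_network
from .simulate import generate_cell, sample_damage_fixtures

__all__ = [
    "cell_seeds",
    "recover_gradient_lambda",
    "recover_metrics",
    "recover_segment_lengths",
    "recover_colocalization",
    "recover_area_fraction",
    "recover_damage_geometry",
]

_MOD = 2**31 - 1


def cell_seeds(base_seed: int, n: int, stream: int = 0):
    """Distinct per-cell seeds derived from one base seed."""
    return [(int(base_seed) * 100003 + stream * 7919 + i) % _MOD for i in range(1, n + 1)]


def _se(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")


def recover_gradient_lambda(
    preset_name: str, n_cells: int, base_seed: int, plateau_fixed: bool = True
) -> dict:
    """Pooled-bin exponential fit of the acetylation gradient over many cells."""
    p = get_preset(preset_name)
    profiles = []
    for s in cell_seeds(base_seed, n_cells, stream=1):
        cell, _ = generate_cell(p, s)
        profiles.append(cell_radial_profile(cell))
    fit = fit_exponential(bin_and_average(profiles), plateau_fixed=plateau_fixed)
    return {
        "lambda": fit.lambda_,
        "Y0": fit.Y0,
        "n_cells": n_cells,
        "n_bins": fit.n_bins,
    }


def recover_metrics(preset_name: str, n_cells: int, base_seed: int) -> dict:
    """Per-cell acetylated fraction and segment statistics via full tracing."""
    p = get_preset(preset_name)
    fracs, seg_means = [], []
    for s in cell_seeds(base_seed, n_cells, stream=2):
        cell, _ = generate_cell(p, s)
        summ = analyze_cell(cell)
        fracs.append(summ.ac_fraction)
        if np.isfinite(summ.mean_segment_um):
            seg_means.append(summ.mean_segment_um)
    return {
        "ac_fraction_mean": float(np.mean(fracs)),
        "ac_fraction_se": _se(fracs),
        "segment_mean_um": float(np.mean(seg_means)),
        "segment_se_um": _se(seg_means),
        "n_cells": n_cells,
    }


def recover_segment_lengths(preset_name: str, n_cells: int, base_seed: int) -> dict:
    """Grand mean of per-cell acetylated-segment lengths (acetylation channel only)."""
    p = get_preset(preset_name)
    means = []
    for s in cell_seeds(base_seed, n_cells, stream=3):
        cell, _ = generate_cell(p, s, channels=("ac_tubulin",))
        seg = trace_network(
            cell.channels["ac_tubulin"], cell.cell_roi, cell.pixel_size_um,
            channel="ac_tubulin",
        )
        st = segment_length_stats(seg)
        if np.isfinite(st.mean_segment_um):
            means.append(st.mean_segment_um)
    return {
        "segment_mean_um": float(np.mean(means)),
        "segment_se_um": _se(means),
        "n_cells": n_cells,
    }


def recover_colocalization(n_cells: int, base_seed: int, preset_name: str = "hdac6_oe") -> dict:
    p = get_preset(preset_name)
    vals = []
    for s in cell_seeds(base_seed, n_cells, stream=4):
        cell, _ = generate_cell(p, s, channels=("alpha_tubulin", "ac_tubulin", "hdac6"))
        vals.append(coloc_analysis(cell).M_hdac6_on_ac)
    return {"M_mean": float(np.mean(vals)), "M_se": _se(vals), "n_cells": n_cells}


def recover_area_fraction(n_cells: int, base_seed: int, preset_name: str = "nocodazole") -> dict:
    p = get_preset(preset_name)
    vals = []
    for s in cell_seeds(base_seed, n_cells, stream=5):
        cell, _ = generate_cell(p, s, channels=("ac_tubulin",))
        vals.append(acetylated_area_fraction(cell.channels["ac_tubulin"], cell.cell_roi))
    return {"area_mean": float(np.mean(vals)), "area_se": _se(vals), "n_cells": n_cells}


def recover_damage_geometry(
    n_fixtures: int, base_seed: int, preset_name: str = "control", noise_sd: float = 5.0
) -> dict:
    """Classify line-scan fixtures with the 50 a.u. rule and measure geometry.

    Sites whose measured center displacement is below one pixel count as
    center-colocalized and are excluded from the offset statistics.
    """
    p = get_preset(preset_name)
    fixtures = sample_damage_fixtures(p, n_fixtures, seed=base_seed, noise_sd=noise_sd)
    l_deac, l_dr, disp = [], [], []
    for h, a, _ in fixtures:
        m = measure_fixture(h, a)
        if m is None:
            continue
        l_deac.append(m.L_deac)
        l_dr.append(m.L_dr)
        disp.append(m.center_displacement)
    l_deac = np.array(l_deac)
    l_dr = np.array(l_dr)
    disp = np.array(disp)
    noncoloc = np.abs(disp) >= p.pixel_size_um
    offsets_nm = 1000.0 * np.abs(disp[noncoloc])
    ratio = float(l_deac.mean() / l_dr.mean())
    # delta-method standard error of the ratio of means
    n = len(l_deac)
    ratio_se = ratio * np.sqrt(
        (l_deac.std(ddof=1) / l_deac.mean()) ** 2 + (l_dr.std(ddof=1) / l_dr.mean()) ** 2
    ) / np.sqrt(n)
    return {
        "n_sites": n,
        "L_deac_mean_um": float(l_deac.mean()),
        "L_deac_se_um": _se(l_deac),
        "L_dr_mean_um": float(l_dr.mean()),
        "ratio": ratio,
        "ratio_se": float(ratio_se),
        "offset_mean_nm": float(offsets_nm.mean()),
        "offset_se_nm": _se(offsets_nm),
        "coloc_fraction": float(1.0 - noncoloc.mean()),
        "mean_signed_displacement_um": float(disp.mean()),
        "signed_displacement_se_um": _se(disp),
    }
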