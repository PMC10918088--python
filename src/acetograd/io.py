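"""File I/O, run configuration and pipeline orchestration.

Cells travel as a multi-page TIFF (one page per channel) plus a JSON
sidecar holding channel names, pixel calibration, the cell ROI polygon,
and - for simulated cells - the full ground truth.  Every pipeline run
writes its resolved configuration next to its outputs, so results are
reproducible from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import damage as _damage
from . import gradient as _gradient
from . import metrics as _metrics
from .colocalization import coloc_analysis
from .presets import GeneratorPreset
from .segmentation import Polyline
from .simulate import RENDER_CHANNELS, CellImage, DamageSite, GroundTruth, Punctum

__all__ = ["RunConfig", "read_cell", "write_cell", "run_pipeline"]

log = logging.getLogger("acetograd")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; JSON round-trips losslessly."""

    input_dir: str = "."
    output_dir: str = "out"
    pixel_size_um: float = 0.065
    sigma_px: float = 1.5
    low_contrast: float = 0.08
    high_contrast: float = 0.2
    bin_width: float = 0.005
    scan_width_px: int = 45
    threshold_au: float = 50.0
    expression_threshold_au: float = 60.0
    min_segment_um: float | None = None
    tip_exclusion_um: float = 0.5
    plateau_fixed: bool = True
    sparse_quantile: float = 0.5
    preset_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Cell serialization
# ---------------------------------------------------------------------------


def write_cell(cell: CellImage, gt: GroundTruth | None, out_dir) -> Path:
    """Write ``cell.tif`` + ``cell.json`` into ``out_dir``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(cell.channels)
    stack = np.stack([cell.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(out / "cell.tif", stack, photometric="minisblack")
    sidecar = {
        "channels": names,
        "pixel_size_um": cell.pixel_size_um,
        "cell_roi": np.asarray(cell.cell_roi, float).tolist(),
        "nucleus_center": list(map(float, cell.nucleus_center)),
        "metadata": cell.metadata,
    }
    if gt is not None:
        sidecar["ground_truth"] = _gt_to_dict(gt)
    (out / "cell.json").write_text(json.dumps(sidecar))
    return out


def read_cell(path) -> tuple:
    """Read a cell directory; returns ``(CellImage, GroundTruth | None)``."""
    p = Path(path)
    tif, sidecar_path = p / "cell.tif", p / "cell.json"
    if not tif.exists() or not sidecar_path.exists():
        raise FileNotFoundError(f"no cell.tif/cell.json pair under {p}")
    sidecar = json.loads(sidecar_path.read_text())
    if "pixel_size_um" not in sidecar or not sidecar["pixel_size_um"]:
        raise ValueError(
            f"{sidecar_path}: missing pixel_size_um calibration; add the pixel size "
            "in µm to the JSON sidecar"
        )
    names = sidecar["channels"]
    unknown = [n for n in names if n not in RENDER_CHANNELS]
    if unknown:
        raise ValueError(f"unknown channel names {unknown}; expected {RENDER_CHANNELS}")
    pages = tifffile.imread(tif)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3 or pages.shape[0] != len(names):
        raise ValueError(f"{tif}: page count/shape mismatch with sidecar channels")
    cell = CellImage(
        channels={n: pages[i].astype(float) for i, n in enumerate(names)},
        pixel_size_um=float(sidecar["pixel_size_um"]),
        cell_roi=np.asarray(sidecar["cell_roi"], float),
        nucleus_center=tuple(sidecar["nucleus_center"]),
        metadata=sidecar.get("metadata", {}),
    )
    gt = _gt_from_dict(sidecar["ground_truth"]) if "ground_truth" in sidecar else None
    return cell, gt


def _gt_to_dict(gt: GroundTruth) -> dict:
    return {
        "seed": gt.seed,
        "preset": dataclasses.asdict(gt.preset),
        "filaments": [f.points.tolist() for f in gt.filaments],
        "ac_segments": [[list(iv) for iv in segs] for segs in gt.ac_segments],
        "damage_sites": [
            [
                {
                    "dr": list(s.dr),
                    "deac": list(s.deac),
                    "offset_um": s.offset_um,
                    "colocalized": s.colocalized,
                }
                for s in sites
            ]
            for sites in gt.damage_sites
        ],
        "hdac6_puncta": [
            {
                "filament": int(q.filament),
                "arc_um": q.arc_um,
                "xy_um": list(map(float, q.xy_um)),
                "on_ac": q.on_ac,
                "amplitude": q.amplitude,
            }
            for q in gt.hdac6_puncta
        ],
    }


def _gt_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        filaments=[Polyline(np.asarray(p)) for p in d["filaments"]],
        ac_segments=[[tuple(iv) for iv in segs] for segs in d["ac_segments"]],
        damage_sites=[
            [
                DamageSite(
                    dr=tuple(s["dr"]),
                    deac=tuple(s["deac"]),
                    offset_um=s["offset_um"],
                    colocalized=s["colocalized"],
                )
                for s in sites
            ]
            for sites in d["damage_sites"]
        ],
        hdac6_puncta=[
            Punctum(
                q["filament"], q["arc_um"], np.asarray(q["xy_um"]), q["on_ac"], q["amplitude"]
            )
            for q in d["hdac6_puncta"]
        ],
        preset=GeneratorPreset(**d["preset"]),
        seed=d["seed"],
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

ANALYSES = ("gradient", "damage", "coloc", "metrics")


def _iter_cells(input_dir: Path):
    dirs = sorted(d for d in Path(input_dir).iterdir() if (d / "cell.tif").exists())
    for d in dirs:
        yield d.name, *read_cell(d)


def run_pipeline(config: RunConfig, analysis: str) -> dict:
    """Run one analysis over every cell in ``config.input_dir``.

    Writes a per-cell CSV table, a pooled JSON summary and a log file into
    ``config.output_dir``; returns the summary dict.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; choose from {ANALYSES}")
    in_dir, out_dir = Path(config.input_dir), Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = list(_iter_cells(in_dir))
    if not cells:
        raise ValueError(f"no cells found under {in_dir}")

    t0 = time.time()
    rows, summary, warnings_log = [], {}, []
    profiles = []
    for cell_id, cell, gt in cells:
        t_cell = time.time()
        try:
            if analysis == "gradient":
                prof = _gradient.cell_radial_profile(cell)
                profiles.append(prof)
                rows.append({"cell_id": cell_id, "n_samples": len(prof.distance)})
            elif analysis == "metrics":
                summ = _metrics.analyze_cell(
                    cell, min_len_um=config.min_segment_um, sigma_px=config.sigma_px,
                    with_area=True,
                )
                rows.append(
                    {
                        "cell_id": cell_id,
                        "ac_fraction": summ.ac_fraction,
                        "segment_count": summ.segment_count,
                        "mean_segment_um": summ.mean_segment_um,
                        "sd_segment_um": summ.sd_segment_um,
                        "area_fraction": summ.area_fraction,
                    }
                )
            elif analysis == "coloc":
                if "hdac6" not in cell.channels:
                    raise ValueError("colocalization needs an hdac6 channel")
                res = coloc_analysis(cell, sparse_quantile=config.sparse_quantile)
                rows.append(
                    {
                        "cell_id": cell_id,
                        "M_hdac6_on_ac": res.M_hdac6_on_ac,
                        "M_ac_on_hdac6": res.M_ac_on_hdac6,
                        "n_network_px": res.n_network_px,
                    }
                )
            elif analysis == "damage":
                if "hmb11" not in cell.channels:
                    raise ValueError("damage analysis needs an hmb11 channel")
                if gt is None:
                    raise ValueError(
                        "damage analysis needs filament paths/polarity (ground-truth "
                        "sidecar or annotation)"
                    )
                for meas in _damage_measurements(cell, gt, config):
                    row = dataclasses.asdict(meas)
                    row["cell_id"] = cell_id
                    rows.append(row)
        except Exception as err:
            raise RuntimeError(f"{analysis} failed on cell {cell_id}: {err}") from err
        log.info("%s: cell %s done in %.2fs", analysis, cell_id, time.time() - t_cell)

    table = pd.DataFrame(rows)
    table.to_csv(out_dir / f"{analysis}_cells.csv", index=False)

    if analysis == "gradient":
        fit = _gradient.pooled_lambda(
            profiles, bin_width=config.bin_width, plateau_fixed=config.plateau_fixed
        )
        binned = _gradient.bin_and_average(profiles, config.bin_width)
        pd.DataFrame(
            {
                "bin_center": binned.bin_center[binned.populated],
                "mean": binned.mean[binned.populated],
                "sd": binned.sd[binned.populated],
                "n": binned.n[binned.populated],
            }
        ).to_csv(out_dir / "gradient_bins.csv", index=False)
        summary = {
            "lambda": fit.lambda_,
            "Y0": fit.Y0,
            "plateau": fit.plateau,
            "sse": fit.residual_sse,
            "n_cells": len(profiles),
        }
    elif analysis == "metrics":
        summary = {
            k: float(np.nanmean(table[k]))
            for k in ("ac_fraction", "mean_segment_um", "area_fraction")
        }
        summary["n_cells"] = len(table)
    elif analysis == "coloc":
        summary = {
            "M_hdac6_on_ac": float(table["M_hdac6_on_ac"].mean()),
            "M_ac_on_hdac6": float(table["M_ac_on_hdac6"].mean()),
            "n_cells": len(table),
        }
    elif analysis == "damage":
        paired = table.dropna(subset=["L_deac"]) if len(table) else table
        summary = {
            "n_sites": len(paired),
            "mean_L_dr_um": float(paired["L_dr"].mean()) if len(paired) else np.nan,
            "mean_L_deac_um": float(paired["L_deac"].mean()) if len(paired) else np.nan,
        }

    summary["warnings"] = warnings_log
    summary["config_hash"] = config.config_hash
    summary["seed"] = config.seed
    summary["elapsed_s"] = round(time.time() - t0, 2)
    from . import __version__

    summary["version"] = __version__
    (out_dir / f"{analysis}_summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "config.json").write_text(config.to_json())
    return summary


def _damage_measurements(cell, gt: GroundTruth, config: RunConfig):
    """Image-level damage geometry: line scans along known filament paths."""
    from scipy.ndimage import map_coordinates

    from .segmentation import subtract_background

    px = cell.pixel_size_um
    h_img = subtract_background(cell.channels["hmb11"], cell.cell_roi)
    a_img = subtract_background(cell.channels["ac_tubulin"], cell.cell_roi)
    h_peak = h_img.max()
    out = []
    sites = [
        (fi, s.dr) for fi, lst in enumerate(gt.damage_sites) for s in lst
    ]
    sites = _damage.filter_shaft_sites(
        sites, gt.filaments, config.tip_exclusion_um,
        image_shape=cell.shape, pixel_size_um=px,
    )
    for fi, (sa, sb) in sites:
        f = gt.filaments[fi]
        lo = max(0.0, sa - 2.0)
        hi = min(f.length_um, sb + 2.0)
        s = np.arange(lo, hi, 0.5 * px)
        pts = f.point_at(s) / px
        hv = map_coordinates(h_img, [pts[:, 1], pts[:, 0]], order=1)
        av = map_coordinates(a_img, [pts[:, 1], pts[:, 0]], order=1)
        if hv.max() < 0.25 * h_peak:
            continue
        meas = _damage.measure_fixture(
            _damage.LineScan(s, hv), _damage.LineScan(s, av), config.threshold_au
        )
        if meas is not None:
            out.append(meas)
    return out
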