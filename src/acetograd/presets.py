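"""Named generator presets encoding the measured experimental conditions.

Each preset bundles the generative parameters of one imaging condition:
cell geometry, filament count, the exponential acetylation gradient
(characteristic length ``gradient_lambda`` as a fraction of the
nucleus-to-membrane distance), the acetylated-segment length distribution,
damage-site geometry, HDAC6 puncta statistics, the kinesin distribution
shape, and the imaging model (PSF, noise, pixel size).

Length statistics are reproduced by moment-matched truncated normals, so
the simulated population mean equals the condition value even though the
underlying support is strictly positive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneratorPreset", "preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class GeneratorPreset:
    """Full parameter set for :func:`acetograd.simulate.generate_cell`."""

    name: str
    # cell geometry (circular ROI; circular nucleus at the image center)
    cell_radius_um: float = 20.0
    nucleus_radius_um: float = 6.0
    image_size_px: int = 1024
    pixel_size_um: float = 0.065  # 100x objective + sCMOS
    # filament network
    n_filaments: int = 60
    filament_persistence: float = 150.0  # µm; angular diffusion scale of growth
    reach_min: float = 0.3  # filament length as fraction of nucleus-to-membrane run
    reach_max: float = 1.0
    # acetylation gradient: coverage(x) ~ amplitude * exp(-x / lambda)
    gradient_lambda: float = 0.33
    gradient_amplitude: float | None = None  # None -> calibrated from ac_fraction_target
    ac_fraction_target: float = 0.36
    ac_segment_mean_um: float = 2.5
    ac_segment_sd_um: float = 0.71
    ac_gap_mean_um: float = 0.5  # kept well above the PSF width so segment identity is resolvable
    ac_gap_sd_um: float = 0.15
    # damage/repair sites and their deacetylated stretches
    damage_density_per_um: float = 0.02  # per µm of eligible (non-acetylated) run
    damage_len_mean_um: float = 0.5067  # 0.76 µm / 1.5-fold
    damage_len_sd_um: float = 0.20
    deac_len_mean_um: float = 0.76
    deac_len_sd_um: float = 0.38
    center_offset_mean_nm: float = 240.0
    center_offset_sd_nm: float = 239.0
    center_coloc_prob: float = 0.12
    # HDAC6 puncta
    hdac6_puncta_density: float = 0.08  # puncta per µm of network
    hdac6_on_ac_fraction: float = 0.20  # on-acetylated-segment placement probability
    # kinesin channel shape: peripheral_gradient | uniform | none
    kinesin_profile: str = "none"
    # imaging model
    psf_sigma_um: float = 0.13
    noise_gaussian_sd: float = 2.0
    noise_poisson_scale: float = 0.5  # photons per intensity unit
    background_level: float = 8.0  # diffuse cytoplasmic level inside the ROI
    brightness: dict = field(
        default_factory=lambda: {
            "alpha_tubulin": 220.0,
            "ac_tubulin": 300.0,
            "hmb11": 350.0,
            "hdac6": 3000.0,  # integrated intensity per punctum
            "kinesin": 80.0,
        }
    )
    tip_label_um: float = 0.3  # hMB11 also marks filament plus-end tips
    # nocodazole-style conditions target an area fraction instead
    area_fraction_target: float | None = None

    def __post_init__(self):
        if not (0 < self.nucleus_radius_um < self.cell_radius_um):
            raise ValueError("nucleus radius must be positive and smaller than cell radius")
        for name in ("pixel_size_um", "psf_sigma_um", "ac_segment_mean_um", "gradient_lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("ac_fraction_target", "center_coloc_prob", "hdac6_on_ac_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ac_segment_mean_um < self.pixel_size_um:
            raise ValueError("ac_segment_mean_um must be at least one pixel")
        if self.kinesin_profile not in ("peripheral_gradient", "uniform", "none"):
            raise ValueError("unknown kinesin_profile")

    def replace(self, **kw) -> "GeneratorPreset":
        return dataclasses.replace(self, **kw)

    @property
    def run_um(self) -> float:
        """Nucleus-edge-to-membrane distance (the gradient's unit length)."""
        return self.cell_radius_um - self.nucleus_radius_um


def _nocodazole_filament_count(
    area_target: float,
    cell_radius_um: float,
    nucleus_radius_um: float,
    psf_sigma_um: float,
    pixel_size_um: float,
    mean_reach: float,
    ac_coverage: float,
) -> int:
    """Filament count whose rendered acetylation mask covers ``area_target`` of the cell.

    Poisson-coverage calibration: a blurred line reads out at roughly its
    full width at half maximum (iterative-intermeans thresholding converges
    near the background/peak midpoint), so the covered fraction is
    1 - exp(-L * FWHM / A_cell).
    """
    sigma_eff = float(np.hypot(psf_sigma_um, 0.4 * pixel_size_um))
    fwhm = 2.3548 * sigma_eff
    a_cell = np.pi * cell_radius_um**2
    l_needed = -np.log(1.0 - area_target) * a_cell / fwhm
    mean_len = mean_reach * (cell_radius_um - nucleus_radius_um) * 1.03  # tortuosity
    return int(round(l_needed / (ac_coverage * mean_len)))


def _build_presets() -> dict[str, GeneratorPreset]:
    control = GeneratorPreset(name="control")
    presets = {
        "control": control,
        # low overexpression: motor depleted at the cell center, acetylation
        # level like control but segments ~20% shorter
        "kinesin_low": control.replace(
            name="kinesin_low",
            gradient_lambda=0.45,
            ac_fraction_target=0.33,
            ac_segment_mean_um=2.0,
            ac_segment_sd_um=0.5,
            damage_density_per_um=0.05,
            kinesin_profile="peripheral_gradient",
        ),
        # high overexpression: uniform motor, shallow gradient, short segments
        "kinesin_high": control.replace(
            name="kinesin_high",
            gradient_lambda=0.79,
            ac_fraction_target=0.18,
            ac_segment_mean_um=1.2,
            ac_segment_sd_um=0.16,
            damage_density_per_um=0.10,
            kinesin_profile="uniform",
        ),
        # kinesin-1 knockdown: fewer damage sites, more extensive acetylation
        "sikin1": control.replace(
            name="sikin1",
            gradient_lambda=0.42,
            ac_fraction_target=0.45,
            ac_segment_mean_um=2.8,
            ac_segment_sd_um=0.8,
            damage_density_per_um=0.008,
        ),
        # HDAC6 inhibited: near-flat gradient, most of the network acetylated
        "tubacin": control.replace(
            name="tubacin",
            gradient_lambda=3.0,
            ac_fraction_target=0.80,
            ac_segment_mean_um=5.0,
            ac_segment_sd_um=1.2,
            ac_gap_mean_um=0.45,
            ac_gap_sd_um=0.12,
        ),
    }
    # HDAC6 overexpression after cytoplasm extraction (the colocalization
    # condition): sparser network, shallow acetylation field, slightly
    # reduced acetylation level
    presets["hdac6_oe"] = control.replace(
        name="hdac6_oe",
        n_filaments=42,
        gradient_lambda=8.0,  # extraction + overexpression leave no appreciable gradient
        ac_fraction_target=0.30,
        hdac6_puncta_density=0.6,  # overexpressed deacetylase decorates the lattice
        damage_density_per_um=0.0,
    )
    # nocodazole: only the stable, essentially fully acetylated subset of the
    # network remains; filament count calibrated to the covered-area condition
    noc_cov = 0.95
    noc_reach = (0.35, 0.95)
    n_noc = _nocodazole_filament_count(
        area_target=0.167,
        cell_radius_um=control.cell_radius_um,
        nucleus_radius_um=control.nucleus_radius_um,
        psf_sigma_um=control.psf_sigma_um,
        pixel_size_um=control.pixel_size_um,
        mean_reach=sum(noc_reach) / 2,
        ac_coverage=noc_cov,
    )
    presets["nocodazole"] = control.replace(
        name="nocodazole",
        n_filaments=n_noc,
        reach_min=noc_reach[0],
        reach_max=noc_reach[1],
        gradient_lambda=1.5,
        ac_fraction_target=noc_cov,
        ac_segment_mean_um=6.0,
        ac_segment_sd_um=1.5,
        ac_gap_mean_um=0.5,
        area_fraction_target=0.167,
        damage_density_per_um=0.0,
    )
    # 10 min of regrowth after depolymerization: short, sparse nascent segments
    presets["regrowth_t10"] = control.replace(
        name="regrowth_t10",
        n_filaments=45,
        reach_min=0.15,
        reach_max=0.6,
        gradient_lambda=0.5,
        ac_fraction_target=0.10,
        ac_segment_mean_um=1.0,
        ac_segment_sd_um=0.4,
        damage_density_per_um=0.0,
    )
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> GeneratorPreset:
    """Look up a named condition preset.

    Raises ``KeyError`` listing the valid names for unknown ones.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
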