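"""Center-to-periphery acetylation profiles and exponential-decay fitting.

A wide line scan is drawn from the perinuclear acetylation maximum to the
plasma membrane; at each step the acetylated-tubulin and α-tubulin
signals are averaged over the perpendicular footprint, the ratio series
is normalized to its own maximum, and the scan position is normalized to
the nucleus-edge-to-membrane distance.  Profiles from many cells are
pooled in 0.005-wide distance bins and the mean profile is fitted with a
one-phase exponential decay Y(x) = Y0 * exp(-x / λ) + plateau, with the
plateau constrained to 0 for acetylation gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import curve_fit

from ._util import roi_mask
from .segmentation import subtract_background, subtract_local_background

__all__ = [
    "RawProfile",
    "IntensityProfile",
    "BinnedProfile",
    "ExpFitResult",
    "extract_profile",
    "normalize_profile",
    "bin_and_average",
    "fit_exponential",
    "relative_amplitude",
    "auto_scan",
    "cell_gradient_profile",
    "cell_gradient_profiles",
    "cell_radial_profile",
    "pooled_lambda",
]


@dataclass
class RawProfile:
    """Footprint-averaged channel pair along one scan line (positions in µm)."""

    position_um: np.ndarray
    num: np.ndarray  # numerator channel (e.g. acetylated tubulin)
    den: np.ndarray  # denominator channel (e.g. α-tubulin)


@dataclass
class IntensityProfile:
    """Max-normalized ratio profile on normalized distance (0 = nucleus edge)."""

    distance: np.ndarray
    value: np.ndarray
    channel_pair: tuple = ("ac_tubulin", "alpha_tubulin")
    cell_id: str = ""

    def __post_init__(self):
        d = np.asarray(self.distance, dtype=float)
        if d.size and (np.any(np.diff(d) <= 0) or d.min() < 0 or d.max() > 1):
            raise ValueError("distance must be strictly increasing within [0, 1]")


@dataclass
class BinnedProfile:
    bin_center: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    @property
    def populated(self) -> np.ndarray:
        return self.n > 0


@dataclass
class ExpFitResult:
    lambda_: float
    Y0: float
    plateau: float
    residual_sse: float
    plateau_fixed: bool
    n_bins: int = 0


def extract_profile(
    num_image: np.ndarray,
    den_image: np.ndarray,
    scan: tuple,
    width_px: int = 45,
    pixel_size_um: float = 0.065,
) -> RawProfile:
    """Wide line scan: mean over the perpendicular footprint at 1-px steps.

    ``scan`` is a pair of (x, y) pixel coordinates.  Inputs are expected to
    be background-subtracted.
    """
    if width_px % 2 != 1:
        raise ValueError("width_px must be odd")
    p0 = np.asarray(scan[0], dtype=float)
    p1 = np.asarray(scan[1], dtype=float)
    vec = p1 - p0
    length = np.linalg.norm(vec)
    if length < 1:
        raise ValueError("degenerate scan line")
    u = vec / length
    n_vec = np.array([-u[1], u[0]])
    steps = np.arange(0.0, length + 0.5, 1.0)
    offs = np.arange(width_px) - width_px // 2
    # sample grid: (n_steps, width) points
    base = p0[None, :] + steps[:, None] * u[None, :]
    pts = base[:, None, :] + offs[None, :, None] * n_vec[None, None, :]
    coords = [pts[..., 1].ravel(), pts[..., 0].ravel()]
    num = map_coordinates(np.asarray(num_image, float), coords, order=1).reshape(pts.shape[:2])
    den = map_coordinates(np.asarray(den_image, float), coords, order=1).reshape(pts.shape[:2])
    return RawProfile(
        position_um=steps * pixel_size_um,
        num=num.mean(axis=1),
        den=den.mean(axis=1),
    )


def normalize_profile(
    raw: RawProfile, den_floor_frac: float = 0.05, cell_id: str = ""
) -> IntensityProfile:
    """Ratio series normalized by its own maximum; distance by scan length.

    Samples whose denominator falls below ``den_floor_frac`` of the
    denominator maximum are masked rather than interpolated.  For long
    scans the normalizing maximum is taken from the smoothed ratio curve:
    a single-sample noise spike in a low-signal region must not set the
    scale of the whole profile.
    """
    from scipy.ndimage import gaussian_filter1d

    num, den = raw.num, raw.den
    if num.size >= 30:
        # light axial smoothing before the ratio: the quotient of noisy
        # footprint means is inflated where the denominator is faint
        num = gaussian_filter1d(num, 4.0)
        den = gaussian_filter1d(den, 4.0)
    den_max = den.max() if den.size else 0.0
    if den_max <= 0:
        raise ValueError("denominator signal is zero along the whole scan")
    ok = den > den_floor_frac * den_max
    ratio = num[ok] / den[ok]
    pos = raw.position_um[ok]
    if ratio.size >= 30:
        vmax = float(gaussian_filter1d(ratio, 8.0).max())
    else:
        vmax = float(ratio.max()) if ratio.size else 0.0
    if vmax <= 0:
        raise ValueError("ratio profile is identically zero")
    total = raw.position_um[-1]
    return IntensityProfile(
        distance=pos / total, value=ratio / vmax, cell_id=cell_id
    )


def bin_and_average(profiles: list, bin_width: float = 0.005) -> BinnedProfile:
    """Pool profiles into fixed distance bins; per-bin mean and SD."""
    if not profiles:
        raise ValueError("no profiles to bin")
    if not (0 < bin_width < 1):
        raise ValueError("bin_width must lie in (0, 1)")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    d = np.concatenate([p.distance for p in profiles])
    v = np.concatenate([p.value for p in profiles])
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    s1 = np.bincount(idx, weights=v, minlength=n_bins)
    s2 = np.bincount(idx, weights=v * v, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / np.maximum(count, 1), np.nan)
        var = np.where(count > 0, s2 / np.maximum(count, 1) - mean**2, np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))
    centers = (edges[:-1] + edges[1:]) / 2
    return BinnedProfile(bin_center=centers, mean=mean, sd=sd, n=count)


def _decay(x, y0, lam, plateau):
    return y0 * np.exp(-x / lam) + plateau


def fit_exponential(profile: BinnedProfile, plateau_fixed: bool = True) -> ExpFitResult:
    """Least-squares one-phase exponential decay over all populated bins.

    Initial guesses: Y0 = first populated value, λ = 0.3, plateau = minimum
    value (0 when fixed).  λ is bounded in (1e-3, 10]; a fit pinned at a
    λ bound or a non-convergent fit raises rather than silently returning.
    """
    ok = profile.populated & np.isfinite(profile.mean)
    x = profile.bin_center[ok]
    y = profile.mean[ok]
    if x.size < 5:
        raise ValueError("need at least 5 populated bins")
    y0_guess = max(float(y[0]), 1e-6)
    try:
        if plateau_fixed:
            popt, _ = curve_fit(
                lambda xx, y0, lam: _decay(xx, y0, lam, 0.0),
                x,
                y,
                p0=[y0_guess, 0.3],
                bounds=([1e-9, 1e-3], [np.inf, 10.0]),
                maxfev=10000,
            )
            y0_hat, lam_hat = popt
            plat = 0.0
        else:
            popt, _ = curve_fit(
                _decay,
                x,
                y,
                p0=[y0_guess, 0.3, max(float(y.min()), 0.0)],
                bounds=([1e-9, 1e-3, -np.inf], [np.inf, 10.0, np.inf]),
                maxfev=10000,
            )
            y0_hat, lam_hat, plat = popt
    except RuntimeError as err:
        raise ValueError(f"exponential fit did not converge: {err}") from None
    if lam_hat >= 10.0 * (1 - 1e-6) or lam_hat <= 1e-3 * (1 + 1e-6):
        raise ValueError(
            f"degenerate fit: characteristic length pinned at bound (λ = {lam_hat:.4g})"
        )
    sse = float(np.sum((_decay(x, y0_hat, lam_hat, plat) - y) ** 2))
    return ExpFitResult(
        lambda_=float(lam_hat),
        Y0=float(y0_hat),
        plateau=float(plat),
        residual_sse=sse,
        plateau_fixed=plateau_fixed,
        n_bins=int(x.size),
    )


def relative_amplitude(
    ac_image: np.ndarray, tub_image: np.ndarray, nucleus_region: np.ndarray
) -> float:
    """Acetylated/α-tubulin intensity ratio over a perinuclear region mask."""
    region = np.asarray(nucleus_region, bool)
    tub = float(np.asarray(tub_image, float)[region].mean())
    if tub <= 0:
        raise ValueError("zero tubulin signal in the nucleus region")
    ac = float(np.asarray(ac_image, float)[region].mean())
    return ac / tub


# ---------------------------------------------------------------------------
# Automated scan placement and per-cell convenience pipeline
# ---------------------------------------------------------------------------


def auto_scan(cell, channel: str = "alpha_tubulin", smooth_px: float = 22.0) -> tuple:
    """Scan line from the densest perinuclear network region radially outward.

    The start point is the brightest pixel of ``channel`` smoothed at the
    scan-footprint scale within a 1-µm annulus outside the nucleus edge;
    the scan runs outward along the radial direction to the cell boundary.
    Anchoring on the denominator (network) channel keeps the start
    selection independent of the acetylation signal, so the ratio profile
    is not inflated at its origin.
    """
    px = cell.pixel_size_um
    img = gaussian_filter(np.asarray(cell.channels[channel], float), smooth_px)
    h, w = img.shape
    cx, cy = cell.nucleus_center
    r_n = cell.metadata.get("nucleus_radius_um", 6.0) / px
    r_c = cell.metadata.get("cell_radius_um", None)
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(xx - cx, yy - cy)
    annulus = (rr >= r_n) & (rr <= r_n + 1.0 / px)
    if not annulus.any():
        raise ValueError("nucleus annulus lies outside the image")
    flat = np.where(annulus, img, -np.inf)
    iy, ix = np.unravel_index(np.argmax(flat), flat.shape)
    ang = np.arctan2(iy - cy, ix - cx)
    start = np.array([cx + r_n * np.cos(ang), cy + r_n * np.sin(ang)])
    if r_c is not None:
        r_edge = r_c / px
    else:
        inside = roi_mask(cell.cell_roi, img.shape)
        r_edge = np.percentile(rr[inside], 99.5)
    end = np.array([cx + r_edge * np.cos(ang), cy + r_edge * np.sin(ang)])
    return tuple(start), tuple(end)


def cell_gradient_profile(
    cell,
    num_channel: str = "ac_tubulin",
    den_channel: str = "alpha_tubulin",
    width_px: int = 45,
    n_rays: int = 1,
) -> IntensityProfile:
    """Background-subtract, place the scan, extract and normalize one cell's profile.

    Uses the local (valley-level) background so that the blur halo around
    dense perinuclear bundles does not flatten the ratio at the scan head
    or push the faint tail negative.
    """
    profs = cell_gradient_profiles(cell, num_channel, den_channel, width_px, n_rays)
    return profs[0]


def cell_gradient_profiles(
    cell,
    num_channel: str = "ac_tubulin",
    den_channel: str = "alpha_tubulin",
    width_px: int = 45,
    n_rays: int = 6,
) -> list:
    """Normalized ratio profiles along ``n_rays`` radial scans of one cell.

    The first ray starts at the densest perinuclear network sector; the
    others are spaced evenly in angle.  Each ray is normalized on its own,
    like an independent line scan.
    """
    roi = cell.cell_roi
    num = subtract_background(
        subtract_local_background(cell.channels[num_channel]), roi, clip=False
    )
    den = subtract_background(
        subtract_local_background(cell.channels[den_channel]), roi, clip=False
    )
    px = cell.pixel_size_um
    start0, end0 = auto_scan(cell, channel=den_channel)
    cx, cy = cell.nucleus_center
    ang0 = np.arctan2(start0[1] - cy, start0[0] - cx)
    r_in = np.hypot(start0[0] - cx, start0[1] - cy)
    r_out = np.hypot(end0[0] - cx, end0[1] - cy)
    from scipy.ndimage import gaussian_filter1d

    cid = str(cell.metadata.get("seed", ""))
    rays = []
    for k in range(n_rays):
        ang = ang0 + 2 * np.pi * k / n_rays
        start = (cx + r_in * np.cos(ang), cy + r_in * np.sin(ang))
        end = (cx + r_out * np.cos(ang), cy + r_out * np.sin(ang))
        raw = extract_profile(num, den, (start, end), width_px=width_px, pixel_size_um=px)
        n_s = gaussian_filter1d(raw.num, 4.0)
        d_s = gaussian_filter1d(raw.den, 4.0)
        dm = d_s.max()
        if dm <= 0:
            continue
        ok = d_s > 0.05 * dm
        if ok.sum() < 10:
            continue
        rays.append((raw.position_um[ok] / raw.position_um[-1], n_s[ok] / d_s[ok]))
    if not rays:
        raise ValueError("no usable scan ray in this cell")
    # one normalization constant per cell: the maximum of the smoothed ratio
    # over all rays, so a faint ray cannot inflate its own tail
    vmax = max(float(gaussian_filter1d(r, 4.0).max()) for _, r in rays)
    if vmax <= 0:
        raise ValueError("ratio profiles are identically zero")
    return [
        IntensityProfile(distance=d, value=r / vmax, cell_id=f"{cid}:{k}")
        for k, (d, r) in enumerate(rays)
    ]


def cell_radial_profile(
    cell,
    num_channel: str = "ac_tubulin",
    den_channel: str = "alpha_tubulin",
    step_px: float = 2.0,
) -> IntensityProfile:
    """Center-to-periphery ratio profile measured on the network in each annulus.

    For every annulus the numerator/denominator intensities are summed
    over network pixels only (a ridge mask of the denominator channel,
    which is independent of the numerator), after subtracting that
    annulus's own off-network background - the background "close to
    microtubules".  Summing before dividing keeps the faint periphery
    unbiased: the quotient of two small noisy means would otherwise
    inflate the tail of the gradient.
    """
    from scipy.ndimage import binary_dilation, gaussian_filter1d

    roi = cell.cell_roi
    num = np.asarray(cell.channels[num_channel], dtype=float)
    den = np.asarray(cell.channels[den_channel], dtype=float)
    px = cell.pixel_size_um
    h, w = num.shape
    cx, cy = cell.nucleus_center
    r_n = cell.metadata.get("nucleus_radius_um", 6.0) / px
    inside = roi_mask(roi, num.shape)

    from .segmentation import _ridge_geometry

    strength, _, _, _ = _ridge_geometry(den, 1.5)
    core = strength >= 0.08 * strength.max()
    net = binary_dilation(core, iterations=3) & inside
    # off-network background: widen the exclusion only while enough
    # background pixels remain (dense small cells leave narrow valleys)
    off = inside & ~binary_dilation(core, iterations=8)
    if off.sum() < 0.05 * inside.sum():
        off = inside & ~binary_dilation(core, iterations=4)
    if off.sum() < 0.05 * inside.sum():
        off = inside & ~core

    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(xx - cx, yy - cy)
    r_max = float(np.max(rr[inside]))
    n_bins = int(np.ceil((r_max - r_n) / step_px))

    def ring_sums(mask, img):
        sel = mask & (rr >= r_n)
        ridx = np.clip(((rr[sel] - r_n) / step_px).astype(int), 0, n_bins - 1)
        s = np.bincount(ridx, weights=img[sel], minlength=n_bins)
        c = np.bincount(ridx, minlength=n_bins)
        return s, c

    s_num_on, c_on = ring_sums(net, num)
    s_den_on, _ = ring_sums(net, den)
    s_num_off, c_off = ring_sums(off, num)
    s_den_off, _ = ring_sums(off, den)

    ok = (c_on >= 20) & (c_off >= 20)
    with np.errstate(invalid="ignore", divide="ignore"):
        num_net = s_num_on - c_on * (s_num_off / np.maximum(c_off, 1))
        den_net = s_den_on - c_on * (s_den_off / np.maximum(c_off, 1))
    ok &= den_net > 0.02 * np.nanmax(np.where(ok, den_net, np.nan))
    if ok.sum() < 5:
        raise ValueError("no usable annuli in this cell")
    ratio = num_net[ok] / den_net[ok]
    dist = ((np.arange(n_bins)[ok] + 0.5) * step_px) / (r_max - r_n)
    keep = dist <= 1.0
    ratio, dist = ratio[keep], dist[keep]
    vmax = float(gaussian_filter1d(ratio, 3.0).max()) if ratio.size >= 12 else float(ratio.max())
    if vmax <= 0:
        raise ValueError("ratio profile is identically zero")
    return IntensityProfile(
        distance=dist, value=ratio / vmax, cell_id=str(cell.metadata.get("seed", ""))
    )


def pooled_lambda(
    profiles: list, bin_width: float = 0.005, plateau_fixed: bool = True
) -> ExpFitResult:
    """Bin many cells' profiles and fit the pooled mean curve."""
    return fit_exponential(bin_and_average(profiles, bin_width), plateau_fixed=plateau_fixed)
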