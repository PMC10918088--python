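"""Shared numerical helpers: seeded RNG streams, truncated-normal sampling, ROI masks."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = [
    "channel_rng",
    "truncnorm_loc_for_mean",
    "sample_truncnorm",
    "roi_mask",
    "circle_polygon",
]

# stable sub-stream ids so that adding a channel never reshuffles the others
_STREAM_IDS = {
    "geometry": 0,
    "alpha_tubulin": 1,
    "ac_tubulin": 2,
    "hmb11": 3,
    "hdac6": 4,
    "kinesin": 5,
    "fixture": 6,
}


def channel_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-purpose RNG derived from one master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _STREAM_IDS[stream]])


@lru_cache(maxsize=256)
def truncnorm_loc_for_mean(mean_target: float, sd: float, lower: float) -> float:
    """Location of a lower-truncated normal whose *truncated* mean equals ``mean_target``.

    Printed summary statistics are means of strictly positive observed
    quantities; naive truncation of N(mean, sd) at ``lower`` inflates the
    mean, so the location is moment-matched instead.
    """
    if sd <= 0:
        return mean_target

    def _mean(loc: float) -> float:
        a = (lower - loc) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    lo, hi = lower - 12 * sd, mean_target + sd
    if _mean(lo) > mean_target:  # target barely above the bound
        return lo
    return float(optimize.brentq(lambda m: _mean(m) - mean_target, lo, hi, xtol=1e-10))


def sample_truncnorm(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float,
    size: int | None = None,
    moment_match: bool = True,
):
    """Draw from a lower-truncated normal, optionally moment-matched to ``mean``."""
    if sd <= 0:
        out = np.full(size if size is not None else 1, float(mean))
        return out if size is not None else float(out[0])
    loc = truncnorm_loc_for_mean(mean, sd, lower) if moment_match else mean
    # inverse-CDF sampling restricted to the upper tail
    p_lo = stats.norm.cdf((lower - loc) / sd)
    u = rng.uniform(p_lo, 1.0, size=size or 1)
    draw = loc + sd * stats.norm.ppf(u)
    draw = np.clip(draw, lower, None)  # guard against fp round-off at the bound
    return draw if size is not None else float(draw[0])


_ROI_CACHE: dict = {}


def roi_mask(roi: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of an (x, y) polygon given in pixel coordinates."""
    roi = np.asarray(roi, dtype=float)
    key = (roi.tobytes(), shape)
    hit = _ROI_CACHE.get(key)
    if hit is not None:
        return hit
    from matplotlib.path import Path as _MplPath

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    mask = _MplPath(roi).contains_points(pts).reshape(shape)
    if len(_ROI_CACHE) > 16:
        _ROI_CACHE.clear()
    _ROI_CACHE[key] = mask
    return mask


def circle_polygon(center_xy: tuple[float, float], radius: float, n: int = 96) -> np.ndarray:
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    cx, cy = center_xy
    return np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
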