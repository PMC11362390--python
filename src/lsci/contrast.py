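"""Windowed spatial speckle contrast and perfusion-unit mapping.

``contrast_map`` computes, per pixel, the ratio of the population standard
deviation to the mean of the intensities in a centred square window
(7 x 7 by default).  ``lspu_map`` converts contrast to laser speckle
perfusion units (LSPU, arbitrary units); the default convention is the
speckle flow index ``LSPU = 1 / K^2`` capped at 200 AU, under which higher
flow (lower contrast) maps to higher perfusion values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import ConfigurationError, UsageError

__all__ = [
    "ContrastMap",
    "PerfusionMap",
    "contrast_map",
    "lspu_map",
    "mean_perfusion_map",
    "region_contrast",
]

MAPPING_INVERSE_SQUARE = "inverse_square"
MAPPING_RAW_CONTRAST = "raw_contrast"
DEFAULT_CAP = 200.0


@dataclass
class ContrastMap:
    """Per-pixel speckle contrast K = sigma / mu with a validity mask."""

    k_values: np.ndarray
    valid_mask: np.ndarray
    window: int

    @property
    def shape(self):
        return self.k_values.shape


@dataclass
class PerfusionMap:
    """Per-pixel perfusion values (AU) with a validity mask and mapping metadata."""

    lspu: np.ndarray
    valid_mask: np.ndarray
    mapping: dict

    @property
    def shape(self):
        return self.lspu.shape


def contrast_map(frame: np.ndarray, window: int = 7) -> ContrastMap:
    """Sliding-window sigma/mu contrast of a single frame.

    Only pixels whose full ``window x window`` neighbourhood lies inside the
    frame are valid; the border of width ``(window - 1) // 2`` and pixels
    with zero window mean are masked out.  The standard deviation is the
    population (divide-by-n) form: the window is treated as the local
    speckle ensemble.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ConfigurationError("frame must be 2-D")
    if not np.all(np.isfinite(frame)):
        raise ConfigurationError("frame must be finite")
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be an odd integer >= 3")
    if min(frame.shape) < window:
        raise ConfigurationError("window larger than frame")

    # centre the frame before the variance pass to limit cancellation error
    offset = frame.mean()
    g = frame - offset
    mu_g = uniform_filter(g, size=window, mode="constant")
    mu_g2 = uniform_filter(g * g, size=window, mode="constant")
    var = np.clip(mu_g2 - mu_g**2, 0.0, None)
    mu = mu_g + offset

    half = (window - 1) // 2
    valid = np.zeros(frame.shape, dtype=bool)
    valid[half : frame.shape[0] - half, half : frame.shape[1] - half] = True
    valid &= mu != 0.0

    k = np.zeros_like(frame)
    np.divide(np.sqrt(var), mu, out=k, where=valid)
    k[~valid] = np.nan
    return ContrastMap(k_values=k, valid_mask=valid, window=window)


def lspu_map(contrast: ContrastMap, mapping: dict | None = None) -> PerfusionMap:
    """Convert a contrast map to perfusion units.

    ``inverse_square`` (default): ``LSPU = min(1 / K^2, cap)`` with K = 0
    mapped to the cap.  ``raw_contrast``: ``LSPU = K`` (diagnostic mode).
    """
    mapping = dict(mapping or {})
    form = mapping.setdefault("form", MAPPING_INVERSE_SQUARE)
    cap = float(mapping.setdefault("cap", DEFAULT_CAP))
    if cap <= 0:
        raise ConfigurationError("cap must be positive")
    if form not in (MAPPING_INVERSE_SQUARE, MAPPING_RAW_CONTRAST):
        raise ConfigurationError(f"unknown mapping form {form!r}")

    k = contrast.k_values
    valid = contrast.valid_mask
    if form == MAPPING_RAW_CONTRAST:
        lspu = np.where(valid, k, np.nan)
    else:
        lspu = np.full(k.shape, np.nan)
        with np.errstate(divide="ignore"):
            inv = 1.0 / np.where(k > 0, k, 1.0) ** 2
        lspu[valid] = np.where(k[valid] > 0, np.minimum(inv[valid], cap), cap)
    return PerfusionMap(lspu=lspu, valid_mask=valid.copy(), mapping=mapping)


def mean_perfusion_map(maps: Sequence[PerfusionMap]) -> PerfusionMap:
    """Per-pixel arithmetic mean of perfusion maps; masks are conjoined."""
    maps = list(maps)
    if not maps:
        raise UsageError("mean_perfusion_map needs at least one map")
    shape = maps[0].shape
    mapping = maps[0].mapping
    for m in maps[1:]:
        if m.shape != shape:
            raise UsageError("perfusion maps have mismatched dimensions")
        if m.mapping != mapping:
            raise UsageError("perfusion maps have mismatched mappings")
    mask = np.logical_and.reduce([m.valid_mask for m in maps])
    stack = np.stack([np.where(m.valid_mask, m.lspu, 0.0) for m in maps])
    mean = np.where(mask, stack.mean(axis=0), np.nan)
    return PerfusionMap(lspu=mean, valid_mask=mask, mapping=dict(mapping))


def region_contrast(frame: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Global sigma/mu (population SD) over a region; the measurement the
    closed-form oracle is compared against on uniform phantoms."""
    frame = np.asarray(frame, dtype=float)
    vals = frame if mask is None else frame[mask]
    mu = vals.mean()
    if mu == 0:
        raise UsageError("region mean is zero")
    return float(vals.std() / mu)
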