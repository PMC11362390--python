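"""Flow phantoms: per-pixel decorrelation-time maps of a bowel-loop scene.

A phantom is the ground truth a synthetic speckle recording is generated
from.  It assigns every pixel a speckle decorrelation time ``tau_c`` (ms;
``inf`` for static background) and a zone label.  The default scene is a
horizontal bowel-loop band with, left to right: a well-perfused zone, a
watershed transition, an ischemic zone, a second watershed, and a second
well-perfused zone -- mirroring an extracorporeal small-bowel loop whose
central mesenteric arteries have been ligated.

Flow is parameterised through the dimensionless ratio ``x = T / tau_c``
(exposure over decorrelation time).  Under the default perfusion-unit
convention ``LSPU = 1 / K^2`` the large-``x`` limit gives ``LSPU ~ x``, so a
zone is assigned ``tau_c = T / target_LSPU``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

ZONE_BACKGROUND = "background"
ZONE_WELL = "well"
ZONE_WATERSHED_LEFT = "watershed_left"
ZONE_WATERSHED_RIGHT = "watershed_right"
ZONE_ISCHEMIC = "ischemic"

#: Loop zones in left-to-right scene order (well zone appears on both ends).
LOOP_ZONES = (ZONE_WELL, ZONE_WATERSHED_LEFT, ZONE_ISCHEMIC, ZONE_WATERSHED_RIGHT)

MIN_ZONE_EXTENT = 60  # every loop zone must hold a standard 60 x 60 px ROI


@dataclass
class FlowPhantom:
    """Ground-truth flow scene.

    Attributes
    ----------
    tau_map : ndarray (rows, cols)
        Per-pixel decorrelation time in ms; strictly positive, ``inf`` = static.
    zone_map : ndarray (rows, cols) of str
        Per-pixel zone label.
    pixel_size : float
        Physical pixel pitch in cm per pixel.
    exposure : float
        Exposure time T (ms) the zone targets were computed for.
    zone_targets : dict
        The target LSPU (AU) per zone the phantom was built from.
    """

    tau_map: np.ndarray
    zone_map: np.ndarray
    pixel_size: float
    exposure: float = 5.0
    zone_targets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tau_map = np.asarray(self.tau_map, dtype=float)
        self.zone_map = np.asarray(self.zone_map)
        if self.tau_map.shape != self.zone_map.shape:
            raise ConfigurationError("tau_map and zone_map dimensions differ")
        if not np.all(self.tau_map > 0):
            raise ConfigurationError("tau_map must be strictly positive (inf allowed)")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau_map.shape

    def zone_mask(self, zone: str) -> np.ndarray:
        return self.zone_map == zone

    def x_map(self) -> np.ndarray:
        """Dimensionless exposure-to-decorrelation ratio T / tau_c per pixel."""
        with np.errstate(divide="ignore"):
            return np.where(np.isinf(self.tau_map), 0.0, self.exposure / self.tau_map)


def _zone_columns(cols: int) -> dict[str, tuple[int, int]]:
    """Left-to-right column spans of the five loop zones.

    Well zones take 1/4 of the width each (split left/right), the ischemic
    centre 1/4, and each watershed 1/8.
    """
    w_well = cols // 4
    w_ws = cols // 8
    w_isch = cols - 2 * w_well - 2 * w_ws
    c0 = 0
    spans = {}
    spans["well_left"] = (c0, c0 + w_well); c0 += w_well
    spans[ZONE_WATERSHED_LEFT] = (c0, c0 + w_ws); c0 += w_ws
    spans[ZONE_ISCHEMIC] = (c0, c0 + w_isch); c0 += w_isch
    spans[ZONE_WATERSHED_RIGHT] = (c0, c0 + w_ws); c0 += w_ws
    spans["well_right"] = (c0, cols)
    return spans


def make_loop_phantom(
    rows: int = 512,
    cols: int = 512,
    exposure: float = 5.0,
    zone_targets: dict | None = None,
    pixel_size: float = 0.02,
    band_height: int | None = None,
) -> FlowPhantom:
    """Build the bowel-loop phantom.

    Parameters
    ----------
    rows, cols : int
        Image dimensions in pixels.
    exposure : float
        Exposure time T in ms used to convert LSPU targets to ``tau_c``.
    zone_targets : dict
        Target LSPU (AU) for ``well`` and ``ischemic``; watershed zones get a
        linear gradient in ``T/tau_c`` between their neighbours.  Defaults to
        ``{"well": 95.0, "ischemic": 50.0}``.
    pixel_size : float
        cm per pixel.
    band_height : int, optional
        Height of the loop band in pixels (default ``max(120, rows // 4)``,
        capped to the image).

    Raises
    ------
    ConfigurationError
        If any loop zone would be smaller than 60 x 60 px, or targets are
        non-positive.
    """
    targets = dict(zone_targets or {})
    targets.setdefault(ZONE_WELL, 95.0)
    targets.setdefault(ZONE_ISCHEMIC, 50.0)
    if any(v <= 0 for v in targets.values()):
        raise ConfigurationError("zone_targets must be positive LSPU values")
    if exposure <= 0:
        raise ConfigurationError("exposure must be positive")

    if band_height is None:
        band_height = min(rows, max(120, rows // 4))
    r0 = (rows - band_height) // 2
    r1 = r0 + band_height
    spans = _zone_columns(cols)

    widths = {z: b - a for z, (a, b) in spans.items()}
    too_small = [z for z, w in widths.items() if w < MIN_ZONE_EXTENT]
    if band_height < MIN_ZONE_EXTENT or too_small:
        raise ConfigurationError(
            f"loop zones must be at least {MIN_ZONE_EXTENT}x{MIN_ZONE_EXTENT} px; "
            f"band_height={band_height}, undersized zones={too_small or 'none'}"
        )

    x_well = float(targets[ZONE_WELL])
    x_isch = float(targets[ZONE_ISCHEMIC])

    x_map = np.zeros((rows, cols), dtype=float)  # x = 0 encodes static background
    zone_map = np.full((rows, cols), ZONE_BACKGROUND, dtype=object)

    for name, (a, b) in spans.items():
        zone = ZONE_WELL if name.startswith("well") else name
        zone_map[r0:r1, a:b] = zone
        if zone == ZONE_WELL:
            x_map[r0:r1, a:b] = x_well
        elif zone == ZONE_ISCHEMIC:
            x_map[r0:r1, a:b] = x_isch
        else:
            # watershed: linear gradient in x between the adjacent zones
            n = b - a
            frac = (np.arange(n) + 0.5) / n
            if zone == ZONE_WATERSHED_LEFT:
                grad = x_well + (x_isch - x_well) * frac
            else:
                grad = x_isch + (x_well - x_isch) * frac
            x_map[r0:r1, a:b] = grad[np.newaxis, :]

    with np.errstate(divide="ignore"):
        tau_map = np.where(x_map > 0, exposure / np.where(x_map > 0, x_map, 1.0), np.inf)

    return FlowPhantom(
        tau_map=tau_map,
        zone_map=zone_map.astype(str),
        pixel_size=pixel_size,
        exposure=exposure,
        zone_targets=targets,
    )
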