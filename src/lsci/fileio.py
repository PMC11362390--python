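"""File formats and rendering.

Recordings travel as multi-page grayscale TIFF stacks with a JSON sidecar
(exposure, frame interval, seed, simulator config); phantoms as single-page
float TIFFs; perfusion maps as 32-bit float TIFFs; tables as CSV with fixed
headers; colormap renders as 8-bit PNG using the Viridis gradient with a
vertical scale bar on the left, as on the surgical monitor.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import numpy as np
import tifffile
from matplotlib import cm

from .contrast import PerfusionMap
from .errors import ConfigurationError
from .phantom import FlowPhantom
from .speckle import SimulationConfig, SpeckleStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_map",
    "read_map",
    "write_phantom",
    "render_colormap",
    "save_png",
]

STACK_TIF = "stack.tif"
STACK_JSON = "stack.json"


def write_stack(stack: SpeckleStack, out_dir, config: SimulationConfig | None = None,
                phantom: FlowPhantom | None = None) -> Path:
    """Write a recording: multi-page TIFF + JSON sidecar (+ phantom TIFFs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / STACK_TIF, stack.frames, photometric="minisblack")
    sidecar = {
        "exposure_ms": stack.exposure,
        "frame_interval_ms": stack.frame_interval,
        "bit_depth": stack.bit_depth,
        "seed": stack.seed,
        "n_frames": stack.n_frames,
    }
    if config is not None:
        sidecar["config"] = {
            "sub_steps": config.sub_steps,
            "grain_radius": config.grain_radius,
            "beta": config.beta,
            "static_fraction": config.static_fraction,
            "shot_noise": config.shot_noise,
            "mean_level": config.mean_level,
            "bit_depth": config.bit_depth,
        }
    (out / STACK_JSON).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    if phantom is not None:
        write_phantom(phantom, out)
    return out / STACK_TIF


def read_stack(path) -> SpeckleStack:
    """Read a recording written by :func:`write_stack` (dir or stack.tif path)."""
    p = Path(path)
    if p.is_dir():
        p = p / STACK_TIF
    frames = tifffile.imread(p)
    meta_path = p.with_name(STACK_JSON)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SpeckleStack(
        frames=frames,
        exposure=meta.get("exposure_ms", 5.0),
        frame_interval=meta.get("frame_interval_ms", meta.get("exposure_ms", 5.0)),
        bit_depth=meta.get("bit_depth", 16),
        seed=meta.get("seed", -1),
    )


def write_phantom(phantom: FlowPhantom, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "tau_map.tif", phantom.tau_map.astype(np.float32))
    zones = sorted(set(phantom.zone_map.ravel().tolist()))
    zone_index = {z: i for i, z in enumerate(zones)}
    coded = np.vectorize(zone_index.get)(phantom.zone_map).astype(np.uint8)
    tifffile.imwrite(out / "zone_map.tif", coded)
    (out / "phantom.json").write_text(
        json.dumps(
            {
                "pixel_size_cm": phantom.pixel_size,
                "exposure_ms": phantom.exposure,
                "zone_targets": phantom.zone_targets,
                "zone_codes": zone_index,
            },
            indent=2,
            sort_keys=True,
        )
    )


def write_map(pmap: PerfusionMap, path) -> Path:
    """Single-page 32-bit float TIFF; invalid pixels stored as NaN."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.where(pmap.valid_mask, pmap.lspu, np.nan).astype(np.float32)
    tifffile.imwrite(path, data)
    return path


def read_map(path, mapping: dict | None = None) -> PerfusionMap:
    data = tifffile.imread(path).astype(float)
    valid = np.isfinite(data)
    return PerfusionMap(lspu=data, valid_mask=valid, mapping=dict(mapping or {}))


def render_colormap(
    pmap: PerfusionMap,
    lo: float = 30.0,
    hi: float = 110.0,
    scale_bar_width: int = 16,
    gap: int = 4,
) -> np.ndarray:
    """Render a perfusion map to an 8-bit RGB image.

    Viridis gradient (blue = low flow, yellow = high flow), linear scaling
    clipped to [lo, hi]; invalid pixels are black; a vertical scale bar
    (hi at the top) is prepended on the left as in the clinical display.
    """
    if lo >= hi:
        raise ConfigurationError("lo must be < hi")
    norm = np.clip((pmap.lspu - lo) / (hi - lo), 0.0, 1.0)
    rgba = cm.viridis(np.where(pmap.valid_mask, norm, 0.0))
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    rgb[~pmap.valid_mask] = 0

    rows = rgb.shape[0]
    bar_vals = np.linspace(1.0, 0.0, rows)[:, np.newaxis].repeat(scale_bar_width, axis=1)
    bar = (cm.viridis(bar_vals)[..., :3] * 255).astype(np.uint8)
    spacer = np.zeros((rows, gap, 3), dtype=np.uint8)
    return np.concatenate([bar, spacer, rgb], axis=1)


def save_png(image: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plt.imsave(path, image)
    return path
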