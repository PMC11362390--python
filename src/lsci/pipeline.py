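"""The umbrella pipeline: simulate -> contrast -> ROI -> study -> cut-off ->
agreement, with a machine-readable run manifest.

Every run is driven by a single JSON-serialisable :class:`PipelineConfig`
whose defaults carry the study constants: 7 x 7 contrast window, middle 96
frames, 60 x 60 px ROIs, inverse-square LSPU mapping capped at 200 AU.
Outputs are CSV/JSON/TIFF/PNG under the configured directory; reruns with
the same seeds are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ._version import __version__
from .agreement import (
    MidlinePath,
    cohens_kappa,
    fraction_within,
    placement_categories,
    signed_midline_distance,
    simulate_placements,
)
from .contrast import contrast_map, lspu_map, mean_perfusion_map
from .cutoff import log_curve_fit, optimal_cutoff
from .errors import LsciError, PipelineStageError
from .fileio import render_colormap, save_png, write_map, write_stack
from .phantom import ZONE_ISCHEMIC, ZONE_WELL, make_loop_phantom
from .roi import ROISpec, roi_series, select_middle_frames
from .speckle import SimulationConfig, generate_speckle_stack
from .study import (
    StudyDesign,
    ZoneDistributions,
    generate_study,
    labeled_values,
    paired_lspu_lactate,
)

__all__ = ["PipelineConfig", "run_pipeline", "default_rois", "loop_midline"]

STAGES = ("simulate", "contrast", "roi", "study", "cutoff", "agreement")


class PipelineConfig(BaseModel):
    """Configuration of a full demonstration run."""

    out_dir: str = "lsci_run"
    seed: int = 0

    # scene + recording
    rows: int = 512
    cols: int = 512
    frames: int = 100
    exposure_ms: float = 5.0
    well_lspu: float = 95.0
    ischemic_lspu: float = 50.0
    pixel_size_cm: float = 0.02
    grain_radius: float = 1.0
    sub_steps: int = 25

    # analysis constants (study-stated defaults)
    window: int = 7
    n_middle_frames: int = 96
    roi_size: tuple[int, int] = (60, 60)
    mapping_form: str = "inverse_square"
    mapping_cap: float = 200.0
    lspu_direction: str = "below_positive"
    lactate_direction: str = "above_positive"

    # tabular study emulation
    study_link_mode: str = "linked"

    # observer model
    n_observer_shift_cm: tuple[float, float] = (0.6, 0.8)
    observer_missing_rate: float = 0.03

    # display
    colormap_lo: float = Field(default=30.0)
    colormap_hi: float = Field(default=110.0)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_rois(phantom, size=(60, 60)) -> list[ROISpec]:
    """One centred ROI per loop zone (well uses the left well segment)."""
    out = []
    for zone in ("well", "watershed_left", "ischemic", "watershed_right"):
        mask = phantom.zone_mask(zone)
        rr, cc = np.nonzero(mask)
        if zone == "well":  # restrict to the left well segment
            keep = cc < phantom.shape[1] // 2
            rr, cc = rr[keep], cc[keep]
        r0 = int(round((rr.min() + rr.max()) / 2 - size[0] / 2))
        c0 = int(round((cc.min() + cc.max()) / 2 - size[1] / 2))
        out.append(ROISpec(roi_id=zone, zone=zone, top_left=(r0, c0), size=size))
    return out


def loop_midline(phantom, side: str = "watershed_left") -> MidlinePath:
    """Horizontal midline through the loop band, left to right.

    The ischemic centre lies in the middle of the band, so the sign
    convention depends on which watershed is assessed: on the left side
    ischemia lies toward increasing arclength, on the right side toward
    decreasing.
    """
    mask = phantom.zone_map != "background"
    rr, cc = np.nonzero(mask)
    row = (rr.min() + rr.max()) / 2
    return MidlinePath(
        points=[(row, float(cc.min())), (row, float(cc.max()))],
        pixel_size=phantom.pixel_size,
        ischemic_direction="end" if side == "watershed_left" else "start",
    )


def _stage(manifest, name, **info):
    manifest["stages"].append({"name": name, **info})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "stages": [],
    }
    mapping = {"form": config.mapping_form, "cap": config.mapping_cap}

    # --- simulate -----------------------------------------------------
    try:
        phantom = make_loop_phantom(
            rows=config.rows,
            cols=config.cols,
            exposure=config.exposure_ms,
            zone_targets={ZONE_WELL: config.well_lspu, ZONE_ISCHEMIC: config.ischemic_lspu},
            pixel_size=config.pixel_size_cm,
        )
        sim_cfg = SimulationConfig(
            sub_steps=config.sub_steps, grain_radius=config.grain_radius
        )
        stack = generate_speckle_stack(
            phantom, config.frames, config.exposure_ms, sim_cfg, seed=config.seed
        )
        write_stack(stack, out / "simulate", config=sim_cfg, phantom=phantom)
    except LsciError as e:
        raise PipelineStageError("simulate", str(e)) from e
    _stage(manifest, "simulate", frames=stack.n_frames, shape=list(stack.shape))

    # --- contrast -----------------------------------------------------
    try:
        maps = [
            lspu_map(contrast_map(f.astype(float), window=config.window), mapping)
            for f in stack.frames
        ]
        mean_map = mean_perfusion_map(maps)
        write_map(mean_map, out / "contrast" / "mean_lspu.tif")
        save_png(
            render_colormap(mean_map, config.colormap_lo, config.colormap_hi),
            out / "contrast" / "mean_lspu.png",
        )
    except LsciError as e:
        raise PipelineStageError("contrast", str(e)) from e
    _stage(manifest, "contrast", maps=len(maps), window=config.window)

    # --- roi (frame selection + ROI statistics) -----------------------
    try:
        selected = select_middle_frames(maps, config.n_middle_frames, name="simulated stack")
        rois = default_rois(phantom, size=tuple(config.roi_size))
        series = roi_series(selected, rois, loop_id="L01", timepoint="T0")
        frame_rows = [
            {
                "loop_id": s.loop_id, "roi_id": s.roi_id, "zone": s.zone,
                "timepoint": s.timepoint, "frame": i, "mean": m,
            }
            for s in series
            for i, m in enumerate(s.frame_means)
        ]
        pd.DataFrame(
            frame_rows,
            columns=["loop_id", "roi_id", "zone", "timepoint", "frame", "mean"],
        ).to_csv(out / "roi_frames.csv", index=False)
        pd.DataFrame(
            [
                {
                    "loop_id": s.loop_id, "roi_id": s.roi_id, "zone": s.zone,
                    "timepoint": s.timepoint, "mean": s.mean, "sd": s.sd,
                    "pixel_sd": s.pixel_sd, "n_frames": s.n_frames,
                }
                for s in series
            ]
        ).to_csv(out / "roi_summary.csv", index=False)
    except LsciError as e:
        raise PipelineStageError("roi", str(e)) from e
    _stage(manifest, "roi", rois=len(series), frames_used=config.n_middle_frames)

    # --- study emulation ----------------------------------------------
    try:
        tables = generate_study(
            StudyDesign(), ZoneDistributions(), seed=config.seed,
            link_mode=config.study_link_mode,
        )
        tables.lspu_records.to_csv(out / "lspu_records.csv", index=False)
        tables.lactate_records.to_csv(out / "lactate_records.csv", index=False)
    except LsciError as e:
        raise PipelineStageError("study", str(e)) from e
    _stage(
        manifest, "study",
        lspu_records=len(tables.lspu_records),
        lactate_records=len(tables.lactate_records),
    )

    # --- cut-offs -----------------------------------------------------
    try:
        lspu_cut = optimal_cutoff(labeled_values(tables, "lspu"), config.lspu_direction)
        lac_cut = optimal_cutoff(
            labeled_values(tables, "lactate"), config.lactate_direction
        )
        paired = paired_lspu_lactate(tables)
        fit = log_curve_fit(paired["lspu"], paired["lactate"])
        cut_report = {
            "lspu": {
                "threshold": lspu_cut.threshold,
                "sensitivity": lspu_cut.sensitivity,
                "specificity": lspu_cut.specificity,
                "youden_j": lspu_cut.youden_j,
            },
            "lactate": {
                "threshold": lac_cut.threshold,
                "sensitivity": lac_cut.sensitivity,
                "specificity": lac_cut.specificity,
                "youden_j": lac_cut.youden_j,
            },
            "log_fit": {"b0": fit.b0, "b1": fit.b1, "r_squared": fit.r_squared},
        }
        (out / "cutoffs.json").write_text(json.dumps(cut_report, indent=2, sort_keys=True))
        pd.DataFrame(
            lspu_cut.roc, columns=["threshold", "sensitivity", "specificity"]
        ).to_csv(out / "roc_lspu.csv", index=False)
    except LsciError as e:
        raise PipelineStageError("cutoff", str(e)) from e
    _stage(manifest, "cutoff", lspu_threshold=lspu_cut.threshold,
           lactate_threshold=lac_cut.threshold, r_squared=fit.r_squared)

    # --- observer agreement -------------------------------------------
    try:
        midlines = {
            side: loop_midline(phantom, side)
            for side in ("watershed_left", "watershed_right")
        }
        refs = []
        for tp in ("T0", "T60", "T120"):
            for roi in rois:
                if not roi.zone.startswith("watershed"):
                    continue
                refs.append(
                    {
                        "loop_id": "L01", "timepoint": tp, "side": roi.zone,
                        "row": roi.top_left[0] + roi.size[0] / 2,
                        "col": roi.top_left[1] + roi.size[1] / 2,
                    }
                )
        refs = pd.DataFrame(refs)
        mean_cm, sd_cm = config.n_observer_shift_cm
        placements = pd.concat(
            [
                simulate_placements(
                    midlines[side], refs[refs.side == side],
                    shift_mean_cm=mean_cm, shift_sd_cm=sd_cm,
                    missing_rate=config.observer_missing_rate,
                    seed=config.seed + 1 + i,
                )
                for i, side in enumerate(sorted(midlines))
            ],
            ignore_index=True,
        )
        dists = []
        for _, p in placements.iterrows():
            ref = refs[
                (refs.loop_id == p.loop_id) & (refs.timepoint == p.timepoint)
                & (refs.side == p.side)
            ].iloc[0]
            if np.isnan(p.row):
                dists.append(np.nan)
            else:
                dists.append(
                    signed_midline_distance(
                        midlines[p.side], (ref.row, ref.col), (p.row, p.col)
                    )
                )
        placements = placements.assign(distance_cm=dists)
        placements.to_csv(out / "placements.csv", index=False)

        within1 = fraction_within(dists, 1.0)
        within2 = fraction_within(dists, 2.0)
        cats = placement_categories(dists)
        placements = placements.assign(category=cats)
        ex = placements[placements.expertise == "expert"].sort_values(
            ["loop_id", "timepoint", "side", "observer_id"]
        )
        px = placements[placements.expertise == "physician"].sort_values(
            ["loop_id", "timepoint", "side", "observer_id"]
        )
        kappa = cohens_kappa(
            ex.category.to_numpy(), px.category.to_numpy(), seed=config.seed + 2
        )
        agree_report = {
            "fraction_within_1cm": within1.fraction,
            "fraction_within_2cm": within2.fraction,
            "n_missing": within1.n_missing,
            "kappa_expert_vs_physician": kappa.kappa,
            "kappa_ci": [kappa.ci_low, kappa.ci_high],
        }
        (out / "agreement.json").write_text(
            json.dumps(agree_report, indent=2, sort_keys=True)
        )
    except LsciError as e:
        raise PipelineStageError("agreement", str(e)) from e
    _stage(manifest, "agreement", placements=len(placements),
           fraction_within_1cm=within1.fraction)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
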