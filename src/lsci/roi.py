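"""Frame selection, ROI perfusion statistics, and group comparisons.

Implements the study's data-quality rules: the middle 96 frames of each
recording are analysed, and perfusion is summarised over surgeon-marked
60 x 60 px regions of interest (well-perfused, two watershed, ischemic).
Group comparisons follow the normality-gated convention: Shapiro-Wilk per
group, then Welch's t test when both groups look normal and a two-sided
Mann-Whitney U otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .contrast import PerfusionMap
from .errors import DataError, UsageError

__all__ = [
    "ROISpec",
    "PerfusionSeries",
    "GroupTestResult",
    "middle_slice",
    "select_middle_frames",
    "roi_series",
    "compare_groups",
]

TIMEPOINTS = ("Tm1", "T0", "T60", "T120")
DEFAULT_N_FRAMES = 96
DEFAULT_ROI_SIZE = (60, 60)


@dataclass
class ROISpec:
    """A rectangular region of interest (0-based, row-major, half-open)."""

    roi_id: str
    zone: str
    top_left: tuple[int, int]
    size: tuple[int, int] = DEFAULT_ROI_SIZE

    @property
    def rows(self) -> slice:
        return slice(self.top_left[0], self.top_left[0] + self.size[0])

    @property
    def cols(self) -> slice:
        return slice(self.top_left[1], self.top_left[1] + self.size[1])


@dataclass
class PerfusionSeries:
    """Per-frame ROI perfusion means plus the across-frame summary."""

    loop_id: str
    roi_id: str
    zone: str
    timepoint: str
    frame_means: np.ndarray  # AU, one entry per analysed frame
    mean: float  # across-frame mean (AU)
    sd: float  # sample SD (n-1) across frame means
    pixel_sd: float  # mean across frames of the within-ROI pixel SD
    n_frames: int


@dataclass
class GroupTestResult:
    """Which two-sample test ran and what it returned."""

    test_used: str  # "t" (Welch) or "mann_whitney"
    statistic: float
    p_value: float
    normality_p: tuple[float, float] = field(default=(np.nan, np.nan))


def middle_slice(n_total: int, n: int = DEFAULT_N_FRAMES) -> slice:
    """Half-open slice of the middle ``n`` of ``n_total`` items.

    ``start = floor((n_total - n) / 2)`` — deterministically one earlier
    when the excess is odd.
    """
    if n_total < n:
        raise DataError(f"recording has {n_total} frames, fewer than the required {n}")
    start = (n_total - n) // 2
    return slice(start, start + n)


def select_middle_frames(seq, n: int = DEFAULT_N_FRAMES, name: str = "recording"):
    """Return the middle ``n`` frames of a stack or map sequence, order kept."""
    frames = seq.frames if hasattr(seq, "frames") else seq
    n_total = len(frames)
    try:
        sl = middle_slice(n_total, n)
    except DataError:
        raise DataError(f"{name}: has {n_total} frames, fewer than the required {n}") from None
    return frames[sl] if isinstance(frames, np.ndarray) else list(frames)[sl]


def roi_series(
    maps: Sequence[PerfusionMap],
    rois: Sequence[ROISpec],
    loop_id: str = "loop",
    timepoint: str = "T0",
) -> list[PerfusionSeries]:
    """Per-ROI perfusion statistics over a sequence of per-frame maps.

    Per frame, the ROI mean is taken over the valid LSPU pixels in the
    rectangle; the headline summary is the mean and sample SD (ddof=1)
    across the per-frame means.  The mean within-ROI pixel SD is also kept,
    since a reported SD could have either basis.
    """
    maps = list(maps)
    if not maps:
        raise UsageError("roi_series needs at least one map")
    out = []
    for roi in rois:
        means = np.empty(len(maps))
        pix_sds = np.empty(len(maps))
        for i, pm in enumerate(maps):
            sub_valid = pm.valid_mask[roi.rows, roi.cols]
            if sub_valid.shape != tuple(roi.size) or not sub_valid.all():
                raise DataError(
                    f"ROI {roi.roi_id} does not lie fully inside the valid region "
                    f"of frame {i}"
                )
            vals = pm.lspu[roi.rows, roi.cols]
            means[i] = vals.mean()
            pix_sds[i] = vals.std(ddof=1)
        sd = float(means.std(ddof=1)) if len(maps) > 1 else 0.0
        out.append(
            PerfusionSeries(
                loop_id=loop_id,
                roi_id=roi.roi_id,
                zone=roi.zone,
                timepoint=timepoint,
                frame_means=means,
                mean=float(means.mean()),
                sd=sd,
                pixel_sd=float(pix_sds.mean()),
                n_frames=len(maps),
            )
        )
    return out


def compare_groups(a, b, alpha_normality: float = 0.05, force: str | None = None) -> GroupTestResult:
    """Two-sample comparison with a normality-gated test choice.

    Shapiro-Wilk is run per group at ``alpha_normality``; if both groups
    pass, a two-sided Welch t test is used, otherwise a two-sided
    Mann-Whitney U.  ``force`` ("t" or "mann_whitney") bypasses the gate.
    Two degenerate identical zero-variance groups return p = 1 with a
    warning (no separation, no test).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise UsageError("each group needs at least 3 values")

    if a.std() == 0 and b.std() == 0 and len(set(a)) == 1 and a[0] == b[0]:
        warnings.warn("both groups are identical constants; returning p = 1")
        return GroupTestResult("degenerate", float("nan"), 1.0, (np.nan, np.nan))

    def _shapiro_p(x):
        if np.ptp(x) == 0:
            return 0.0  # constant group: treat as non-normal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    use_t = pa > alpha_normality and pb > alpha_normality
    if force == "t":
        use_t = True
    elif force == "mann_whitney":
        use_t = False

    if use_t:
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupTestResult("t", float(res.statistic), float(res.pvalue), (pa, pb))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTestResult("mann_whitney", float(res.statistic), float(res.pvalue), (pa, pb))
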