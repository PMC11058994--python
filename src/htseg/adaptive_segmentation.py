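"""Adaptive Hounsfield-unit thresholding of hemorrhage within a user ROI.

The method segments acute blood on non-contrast CT with an intensity
window that adapts to the patient.  An initial pass uses the nominal
acute-blood window 50-80 HU inside the user's region of interest; the
standard deviation (SD) of the selected voxels then classifies the case
as under-, well- or over-segmented and selects an updated 30-HU-wide
window via a small rule table:

    SD = 0          under-segmented   35-65 HU
    0 < SD <= 2.3   under-segmented   40-70 HU
    2.3 < SD <= 6   under-segmented   45-75 HU
    6 < SD <= 11    well-segmented    50-80 HU
    SD > 11         over-segmented    55-85 HU

A narrow intensity spread means the initial window clipped the lesion's
density range (under-segmentation: lower the window); a wide spread
means background tissue leaked in (over-segmentation: raise it).  The
final mask is re-thresholded at the updated window and closed
morphologically (4 x 4 square, per slice) to fill holes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .preprocessing import BrainMask
from .volume_io import BinaryMask, CTVolume, mask_volume_ml

__all__ = [
    "ROIBox",
    "ThresholdWindow",
    "RegionStats",
    "RuleTable",
    "SegmentationResult",
    "DEFAULT_RULES",
    "threshold_segment",
    "region_stats",
    "classify_and_update",
    "close_mask",
    "adaptive_segment",
]

UNDER = "under-segmented"
WELL = "well-segmented"
OVER = "over-segmented"


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned box of voxel indices, half-open on every axis."""

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if not (self.z0 < self.z1 and self.y0 < self.y1 and self.x0 < self.x1):
            raise ValueError(f"empty ROI interval in {self}")
        if min(self.z0, self.y0, self.x0) < 0:
            raise ValueError(f"negative ROI index in {self}")

    def check_bounds(self, shape: tuple[int, int, int]) -> None:
        if self.z1 > shape[0] or self.y1 > shape[1] or self.x1 > shape[2]:
            raise IndexError(f"ROI {self} exceeds volume shape {shape}")

    def slices(self) -> tuple[slice, slice, slice]:
        return slice(self.z0, self.z1), slice(self.y0, self.y1), slice(self.x0, self.x1)

    def support(self, shape: tuple[int, int, int]) -> np.ndarray:
        self.check_bounds(shape)
        m = np.zeros(shape, dtype=bool)
        m[self.slices()] = True
        return m

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.z0, self.z1, self.y0, self.y1, self.x0, self.x1)


@dataclass(frozen=True)
class ThresholdWindow:
    """Inclusive [low, high] HU band of candidate hemorrhage voxels."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"window low must be < high, got {self}")

    @property
    def width(self) -> float:
        return self.high - self.low

    def as_tuple(self) -> tuple[float, float]:
        return (self.low, self.high)


@dataclass(frozen=True)
class RegionStats:
    """Intensity mean and population SD over a segmented region."""

    mean: float  # NaN when the region is empty
    sd: float
    voxel_count: int


@dataclass(frozen=True)
class RuleTable:
    """SD-band -> (classification, updated window) lookup.

    ``rows`` are ``(sd_upper_bound, label, window)`` with inclusive upper
    bounds, tried in order; the final row has an infinite bound.  The
    zero-SD case (including an empty initial mask, the extreme of
    under-segmentation) routes to the first row.
    """

    rows: tuple[tuple[float, str, ThresholdWindow], ...]
    initial: ThresholdWindow = ThresholdWindow(50.0, 80.0)

    def classify(self, sd: float) -> tuple[str, ThresholdWindow]:
        if sd < 0:
            raise ValueError(f"sd must be >= 0, got {sd}")
        if sd == 0.0:
            bound, label, window = self.rows[0]
            return label, window
        for bound, label, window in self.rows[1:]:
            if sd <= bound:
                return label, window
        raise AssertionError("rule table does not cover all sd >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleTable":
        """Load a rule table from YAML.

        Expected layout::

            initial: [50, 80]
            rules:
              - {sd_max: 0,    label: under-segmented, window: [35, 65]}
              - {sd_max: 2.3,  label: under-segmented, window: [40, 70]}
              - {sd_max: .inf, label: over-segmented,  window: [55, 85]}
        """
        cfg = yaml.safe_load(Path(path).read_text())
        rows = tuple(
            (float(r["sd_max"]), str(r["label"]), ThresholdWindow(*map(float, r["window"])))
            for r in cfg["rules"]
        )
        if rows[0][0] != 0.0:
            raise ValueError("first rule row must be the sd_max: 0 row")
        if not np.isinf(rows[-1][0]):
            raise ValueError("last rule row must have sd_max: .inf")
        initial = ThresholdWindow(*map(float, cfg.get("initial", (50, 80))))
        return cls(rows=rows, initial=initial)


DEFAULT_RULES = RuleTable(
    rows=(
        (0.0, UNDER, ThresholdWindow(35.0, 65.0)),
        (2.3, UNDER, ThresholdWindow(40.0, 70.0)),
        (6.0, UNDER, ThresholdWindow(45.0, 75.0)),
        (11.0, WELL, ThresholdWindow(50.0, 80.0)),
        (np.inf, OVER, ThresholdWindow(55.0, 85.0)),
    )
)


@dataclass(frozen=True)
class SegmentationResult:
    mask: BinaryMask
    initial_window: ThresholdWindow
    final_window: ThresholdWindow
    stats: RegionStats  # from the initial pass
    label: str
    volume_ml: float

    def to_dict(self) -> dict:
        return {
            "initial_window": self.initial_window.as_tuple(),
            "final_window": self.final_window.as_tuple(),
            "initial_mean_hu": None if np.isnan(self.stats.mean) else round(self.stats.mean, 4),
            "initial_sd_hu": round(self.stats.sd, 4),
            "initial_voxel_count": self.stats.voxel_count,
            "label": self.label,
            "volume_ml": round(self.volume_ml, 4),
        }


def threshold_segment(
    vol: CTVolume, roi: ROIBox, brain: BrainMask, window: ThresholdWindow
) -> BinaryMask:
    """Voxels inside ROI and brain with ``low <= HU <= high`` (inclusive)."""
    roi.check_bounds(vol.shape)
    sel = (vol.voxels >= window.low) & (vol.voxels <= window.high)
    sel &= roi.support(vol.shape)
    sel &= brain.voxels
    return BinaryMask.like(vol, sel)


def region_stats(vol: CTVolume, mask: BinaryMask) -> RegionStats:
    """Mean and population SD of the HU values under the mask.

    An empty mask yields ``mean = NaN, sd = 0, voxel_count = 0``, which
    routes through the rule table's zero-SD branch.
    """
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    values = vol.voxels[mask.voxels]
    if values.size == 0:
        return RegionStats(mean=float("nan"), sd=0.0, voxel_count=0)
    return RegionStats(
        mean=float(np.mean(values, dtype=np.float64)),
        sd=float(np.std(values, dtype=np.float64)),  # population SD
        voxel_count=int(values.size),
    )


def classify_and_update(
    sd: float, rules: RuleTable = DEFAULT_RULES
) -> tuple[str, ThresholdWindow]:
    """Map the initial-pass intensity SD to a label and updated window."""
    return rules.classify(sd)


def _close_slice(mask2d: np.ndarray, size: int) -> np.ndarray:
    # Mathematical closing against a False background: complement of the
    # opening of the complement.  Opening is anchor-free, so an even-sized
    # element introduces no half-pixel shift.
    pad = size
    padded = np.pad(mask2d, pad, mode="constant", constant_values=False)
    opened_bg = ndimage.binary_opening(~padded, structure=np.ones((size, size), dtype=bool))
    return (~opened_bg)[pad:-pad, pad:-pad]


def close_mask(mask: BinaryMask, kernel_size: int = 4, roi: ROIBox | None = None) -> BinaryMask:
    """Per-slice binary closing with a square element; fills small holes.

    With ``roi`` given the closing is computed on the ROI crop, so the
    result never extends past the ROI.  Output is a superset of the
    input (closing is extensive).
    """
    if kernel_size < 1:
        raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
    out = mask.voxels.copy()
    if roi is None:
        for z in range(out.shape[0]):
            out[z] = _close_slice(out[z], kernel_size)
    else:
        roi.check_bounds(mask.shape)
        zs, ys, xs = roi.slices()
        crop = out[zs, ys, xs]
        for i in range(crop.shape[0]):
            crop[i] = _close_slice(crop[i], kernel_size)
        out[zs, ys, xs] = crop
    return BinaryMask(voxels=out, spacing=mask.spacing, origin=mask.origin)


def adaptive_segment(
    vol: CTVolume,
    roi: ROIBox,
    brain: BrainMask,
    rules: RuleTable = DEFAULT_RULES,
    kernel_size: int = 4,
    adaptive: bool = True,
) -> SegmentationResult:
    """Run the full thresholding stage on a preprocessed volume.

    Single adaptation pass: threshold at the nominal window, compute the
    region SD, look up the updated window, re-threshold, close, and
    measure the volume.  ``adaptive=False`` keeps the nominal window
    throughout (the global-thresholding baseline).
    """
    initial_window = rules.initial
    initial_mask = threshold_segment(vol, roi, brain, initial_window)
    stats = region_stats(vol, initial_mask)

    if adaptive:
        label, final_window = classify_and_update(stats.sd, rules)
        final_mask = threshold_segment(vol, roi, brain, final_window)
    else:
        label, final_window = WELL, initial_window
        final_mask = initial_mask

    closed = close_mask(final_mask, kernel_size=kernel_size, roi=roi)
    confined = BinaryMask.like(vol, closed.voxels & brain.voxels)
    return SegmentationResult(
        mask=confined,
        initial_window=initial_window,
        final_window=final_window,
        stats=stats,
        label=label,
        volume_ml=mask_volume_ml(confined),
    )
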