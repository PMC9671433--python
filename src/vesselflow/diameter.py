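"""Vessel diameter from a rotated binary ROI.

The vessel segment inside a manually selected ROI is straightened by
estimating its orientation with a straight-line Hough transform on the
mask edges and rotating it to horizontal. Diameter is then the white-pixel
area of the rotated mask divided by the length of the analyzed segment —
i.e. the column-mean lumen thickness — converted to micrometres.

Angles follow the package convention: degrees counter-clockwise from the
image horizontal axis (as displayed, origin top-left), reduced to [0, 180).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import erosion
from skimage.transform import hough_line, rotate

from .exceptions import EstimationError, InputError
from .io import Calibration

#: Minimum mask pixels required for a meaningful orientation estimate.
MIN_ORIENTATION_PIXELS = 20

#: Minimum aligned edge pixels for a Hough peak to count as a line.
MIN_HOUGH_PEAK = 10


@dataclass
class VesselROI:
    """A rectangular sub-mask with its estimated orientation.

    ``rect`` is (row, col, height, width) in full-frame coordinates.
    """

    rect: tuple[int, int, int, int]
    mask_patch: np.ndarray
    angle: float | None = None
    rotated_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask_patch = np.asarray(self.mask_patch, dtype=bool)


@dataclass(frozen=True)
class DiameterMeasurement:
    """Diameter as white-pixel area over analyzed segment length."""

    area_px: int
    length_px: int
    diameter_px: float
    diameter_um: float
    angle_deg: float | None = None


@dataclass(frozen=True)
class PercentChange:
    """Diameter reduction relative to basal (basal = 100%)."""

    basal_um: float
    stimulated_um: float
    change_pct: float


def extract_roi(mask: np.ndarray, rect: tuple[int, int, int, int]) -> VesselROI:
    """Cut ``rect`` = (row, col, height, width) out of a full-frame mask."""
    mask = np.asarray(mask, dtype=bool)
    r, c, h, w = rect
    if r < 0 or c < 0 or h < 1 or w < 1 or r + h > mask.shape[0] or c + w > mask.shape[1]:
        raise InputError(f"ROI {rect} outside mask of shape {mask.shape}")
    return VesselROI(rect=rect, mask_patch=mask[r : r + h, c : c + w].copy())


def estimate_orientation(mask_patch: np.ndarray) -> float:
    """Dominant line orientation of a binary vessel patch, in degrees.

    A straight-line Hough transform (1 degree angular, 1 px radial
    resolution) is applied to the mask's edge pixels; the global
    accumulator maximum gives the orientation, ties broken toward the
    smaller angle. Returns degrees CCW from horizontal in [0, 180).
    """
    mask_patch = np.asarray(mask_patch, dtype=bool)
    if int(mask_patch.sum()) < MIN_ORIENTATION_PIXELS:
        raise EstimationError(
            f"mask has fewer than {MIN_ORIENTATION_PIXELS} true pixels"
        )
    edges = mask_patch & ~erosion(mask_patch)
    # theta here is the angle of the line's normal in (col, row) coordinates
    thetas = np.deg2rad(np.arange(-90.0, 90.0, 1.0))
    accumulator, theta, _ = hough_line(edges.astype(np.uint8), theta=thetas)
    peak = int(accumulator.max())
    if peak < MIN_HOUGH_PEAK:
        raise EstimationError(
            f"no Hough peak above noise floor (max {peak} aligned pixels)"
        )
    # global max; np.argmax is row-major so ties resolve to smaller distance
    # first; among angle ties we take the smallest resulting orientation.
    peak_mask = accumulator == peak
    angles = (90.0 - np.rad2deg(theta[np.any(peak_mask, axis=0)])) % 180.0
    return float(np.min(angles))


def rotate_to_horizontal(roi: VesselROI) -> VesselROI:
    """Rotate the ROI mask so the vessel lies horizontal.

    Estimates the angle if not already set, rotates by -angle about the
    patch center with nearest-neighbor interpolation (the result stays
    binary), and expands the canvas so no lumen pixel is clipped.
    """
    angle = roi.angle if roi.angle is not None else estimate_orientation(roi.mask_patch)
    if angle == 0.0:
        rotated = roi.mask_patch.copy()
    else:
        rotated = (
            rotate(
                roi.mask_patch.astype(np.float64),
                -angle,
                resize=True,
                order=0,
                preserve_range=True,
            )
            > 0.5
        )
    return VesselROI(
        rect=roi.rect, mask_patch=roi.mask_patch, angle=angle, rotated_mask=rotated
    )


def measure_diameter(
    rotated_mask: np.ndarray,
    column_range: tuple[int, int],
    calibration: Calibration,
    angle_deg: float | None = None,
) -> DiameterMeasurement:
    """Diameter of a horizontal vessel as area / segment length.

    ``column_range`` is a half-open (start, end) span of at least 10
    columns that the vessel fully crosses. Columns with no lumen pixel
    raise a warning (constricted or broken mask) but a value is still
    returned.
    """
    rotated_mask = np.asarray(rotated_mask, dtype=bool)
    start, end = column_range
    if not (0 <= start < end <= rotated_mask.shape[1]):
        raise InputError(
            f"column range {column_range} outside mask width {rotated_mask.shape[1]}"
        )
    if end - start < 10:
        raise InputError("analyzed segment must span at least 10 columns")
    segment = rotated_mask[:, start:end]
    per_column = segment.sum(axis=0)
    if np.any(per_column == 0):
        warnings.warn(
            f"{int((per_column == 0).sum())} columns have no lumen pixels "
            "(constricted or broken mask)",
            stacklevel=2,
        )
    area = int(segment.sum())
    length = int(end - start)
    diameter_px = area / length
    return DiameterMeasurement(
        area_px=area,
        length_px=length,
        diameter_px=diameter_px,
        diameter_um=diameter_px * calibration.pixel_size,
        angle_deg=angle_deg,
    )


def diameter_trace(
    rotated_mask: np.ndarray, column_range: tuple[int, int], calibration: Calibration
) -> np.ndarray:
    """Per-column lumen thickness in micrometres (wall-irregularity view)."""
    rotated_mask = np.asarray(rotated_mask, dtype=bool)
    start, end = column_range
    return rotated_mask[:, start:end].sum(axis=0) * calibration.pixel_size


def percent_change(
    basal: DiameterMeasurement, stimulated: DiameterMeasurement
) -> PercentChange:
    """Percent diameter reduction relative to basal (dilation is negative)."""
    if basal.diameter_um <= 0:
        raise ZeroDivisionError("basal diameter must be positive")
    change = (basal.diameter_um - stimulated.diameter_um) / basal.diameter_um * 100.0
    return PercentChange(
        basal_um=basal.diameter_um,
        stimulated_um=stimulated.diameter_um,
        change_pct=change,
    )
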