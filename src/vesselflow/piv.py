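"""Micro-PIV: interrogation-window mesh, NCC tracking, outlier fences.

A mesh of interrogation windows (default 15 rows x 5 columns of 20x20 px,
46.24 um² at 0.34 um/px — about the size of a red blood cell) is placed in
the straightened lumen, row centers spanning wall to wall symmetrically
about the centerline. Each window is tracked between frames by normalized
2-D cross-correlation

    gamma(u,v) = sum((f - f̄)(t - t̄)) / sqrt(sum((f - f̄)²) sum((t - t̄)²))

evaluated at every integer shift (u,v) that keeps the template inside the
search area; displacement times pixel size times frame rate gives speed.
Spurious vectors — an intrinsic hazard of correlation PIV on noisy video —
are flagged with Tukey's fences (1.5 IQR beyond the quartiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InputError, MatchError, MeshError
from .io import VideoSequence

DEFAULT_MESH_ROWS = 15
DEFAULT_MESH_COLS = 5
DEFAULT_WINDOW_SIZE = 20  # px
DEFAULT_SEARCH_RADIUS = 15  # px; ~10,200 um/s ceiling at gap 1, 0.34 um/px
TUKEY_MULTIPLIER = 1.5

def window_area_um2(window_size: int, calibration) -> float:
    """Physical area of a square interrogation window, in um²."""
    side = window_size * calibration.pixel_size
    return side * side


#: Reason codes for invalid velocity vectors.
REASON_OK = 0
REASON_ZERO_VARIANCE = 1
REASON_NO_PEAK = 2
REASON_OUTLIER = 3


@dataclass
class PIVMesh:
    """Grid of interrogation-window centers inside the straightened lumen.

    ``row_centers``/``col_centers`` are float pixel coordinates in the
    rotated-mask frame; the outermost rows touch (never cross) the walls.
    """

    row_centers: np.ndarray
    col_centers: np.ndarray
    window_size: int
    overlap_fraction: float
    centerline_row: float
    lumen_height: float
    wall_top: float
    wall_bottom: float

    @property
    def n_rows(self) -> int:
        return len(self.row_centers)

    @property
    def n_cols(self) -> int:
        return len(self.col_centers)

    def window_origin(self, i: int, j: int) -> tuple[int, int]:
        """Top-left integer origin of window (row i, col j)."""
        half = (self.window_size - 1) / 2.0
        r = int(round(self.row_centers[i] - half))
        c = int(round(self.col_centers[j] - half))
        return r, c


@dataclass
class VelocityField:
    """Per-frame-pair grid of displacements, correlations and speeds."""

    frame_pairs: list[tuple[int, int]]
    displacement: np.ndarray  # (n_pairs, n_rows, n_cols, 2) in px, (drow, dcol)
    peak_correlation: np.ndarray  # (n_pairs, n_rows, n_cols)
    speed: np.ndarray  # (n_pairs, n_rows, n_cols) in um/s
    valid: np.ndarray  # bool, same grid
    reason: np.ndarray  # int codes, same grid
    mesh: PIVMesh


def build_mesh(
    rotated_mask: np.ndarray,
    n_rows: int = DEFAULT_MESH_ROWS,
    n_cols: int = DEFAULT_MESH_COLS,
    window_size: int = DEFAULT_WINDOW_SIZE,
    column_range: tuple[int, int] | None = None,
) -> PIVMesh:
    """Place the interrogation-window mesh in a horizontal lumen mask.

    Wall positions are the mean first/last lumen row over the analyzed
    columns. Row centers are evenly spaced and symmetric about the
    centerline with the outermost windows touching the walls; when the
    lumen height equals the window size all rows coincide at the
    centerline. The overlap fraction follows from the lumen height:
    ``1 - (H - ws) / ((n_rows - 1) * ws)``, clamped to [0, 0.95].
    """
    rotated_mask = np.asarray(rotated_mask, dtype=bool)
    if column_range is None:
        cols_any = np.flatnonzero(rotated_mask.any(axis=0))
        if cols_any.size == 0:
            raise MeshError("mask is empty: no lumen to mesh")
        column_range = (int(cols_any[0]), int(cols_any[-1]) + 1)
    c0, c1 = column_range
    segment = rotated_mask[:, c0:c1]
    col_has = segment.any(axis=0)
    if not col_has.all():
        raise MeshError("lumen does not cross every column of the mesh range")
    rows = np.arange(segment.shape[0])
    top = float(np.mean([rows[col][0] for col in segment.T.astype(bool)]))
    bottom = float(np.mean([rows[col][-1] for col in segment.T.astype(bool)]))
    height = bottom - top + 1.0
    if height < window_size:
        raise MeshError(
            f"lumen height {height:.1f} px is narrower than the "
            f"{window_size} px window (constricted vessel)"
        )
    half = (window_size - 1) / 2.0
    row_centers = np.linspace(top + half, bottom - half, n_rows)
    span = c1 - c0
    if span < window_size:
        raise MeshError(f"column range {column_range} narrower than a window")
    col_centers = np.linspace(c0 + half, c1 - 1 - half, n_cols)
    if n_rows > 1:
        overlap = 1.0 - (height - window_size) / ((n_rows - 1) * window_size)
    else:
        overlap = 0.0
    overlap = float(np.clip(overlap, 0.0, 0.95))
    return PIVMesh(
        row_centers=row_centers,
        col_centers=col_centers,
        window_size=window_size,
        overlap_fraction=overlap,
        centerline_row=(top + bottom) / 2.0,
        lumen_height=height,
        wall_top=top,
        wall_bottom=bottom,
    )


def ncc_match(
    template: np.ndarray,
    search_area: np.ndarray,
    origin: tuple[int, int] | None = None,
    subpixel: bool = False,
) -> tuple[tuple[float, float], float]:
    """Best integer shift of ``template`` inside ``search_area`` by NCC.

    gamma is evaluated at every placement of the template fully inside the
    search area; the returned displacement is relative to ``origin`` (the
    top-left placement meaning zero shift; defaults to the centered
    placement). Ties on gamma go to the smallest displacement magnitude,
    then row-major order. With ``subpixel=True`` the integer peak is
    refined by a 3-point Gaussian fit along each axis (a standard PIV
    refinement; the integer result is the definition).
    """
    t = np.asarray(template, dtype=np.float64)
    s = np.asarray(search_area, dtype=np.float64)
    if s.shape[0] < t.shape[0] or s.shape[1] < t.shape[1]:
        raise MatchError("search area smaller than template")
    if s.shape == t.shape:
        raise MatchError("search area must be strictly larger than template")
    tc = t - t.mean()
    t_norm = float(np.sqrt((tc * tc).sum()))
    if t_norm == 0.0:
        raise MatchError("zero-variance template")
    windows = sliding_window_view(s, t.shape)  # (nr, nc, th, tw)
    wc = windows - windows.mean(axis=(2, 3), keepdims=True)
    w_norm = np.sqrt((wc * wc).sum(axis=(2, 3)))
    num = np.einsum("ijkl,kl->ij", wc, tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = num / (w_norm * t_norm)
    gamma[w_norm == 0.0] = np.nan
    if np.all(np.isnan(gamma)):
        raise MatchError("all shifts undefined (constant search area)")
    if origin is None:
        origin = ((gamma.shape[0] - 1) // 2, (gamma.shape[1] - 1) // 2)
    peak = np.nanmax(gamma)
    rr, cc = np.nonzero(gamma == peak)
    dr = rr - origin[0]
    dc = cc - origin[1]
    order = np.lexsort((cc, rr, dr * dr + dc * dc))  # |d|² first, then row-major
    best = order[0]
    disp = (float(dr[best]), float(dc[best]))
    if subpixel:
        disp = _gaussian_subpixel(gamma, int(rr[best]), int(cc[best]), origin)
    return disp, float(peak)


def _gaussian_subpixel(
    gamma: np.ndarray, r: int, c: int, origin: tuple[int, int]
) -> tuple[float, float]:
    """3-point Gaussian peak interpolation; falls back to the integer peak."""

    def refine(m1: float, c0: float, p1: float) -> float:
        if min(m1, c0, p1) <= 0 or not (c0 >= m1 and c0 >= p1):
            return 0.0
        denom = 2.0 * (np.log(m1) + np.log(p1) - 2.0 * np.log(c0))
        if denom == 0.0:
            return 0.0
        return (np.log(m1) - np.log(p1)) / denom

    dr = dc = 0.0
    if 0 < r < gamma.shape[0] - 1 and np.all(np.isfinite(gamma[r - 1 : r + 2, c])):
        dr = refine(gamma[r - 1, c], gamma[r, c], gamma[r + 1, c])
    if 0 < c < gamma.shape[1] - 1 and np.all(np.isfinite(gamma[r, c - 1 : c + 2])):
        dc = refine(gamma[r, c - 1], gamma[r, c], gamma[r, c + 1])
    return (r - origin[0] + dr, c - origin[1] + dc)


#: Peak-correlation validity floor: a window containing no trackable
#: texture (e.g. particle-free lumen) correlates with noise at low gamma;
#: such matches are random and are marked invalid.
DEFAULT_MIN_GAMMA = 0.3


def track_field(
    video: VideoSequence,
    mesh: PIVMesh,
    frame_pairs: list[tuple[int, int]],
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    subpixel: bool = False,
    min_gamma: float = DEFAULT_MIN_GAMMA,
) -> VelocityField:
    """Track every mesh window across the given frame pairs.

    Each window's template from the earlier frame is matched within
    ±``search_radius`` px of its initial position in the later frame.
    Speed = |displacement| x pixel_size x frame_rate / frame_gap. Match
    failures and peaks below ``min_gamma`` mark the vector invalid rather
    than raising.
    """
    n = video.frame_count
    for k0, k1 in frame_pairs:
        if not (0 <= k0 < n and 0 <= k1 < n and k1 > k0):
            raise InputError(f"frame pair ({k0}, {k1}) outside video of {n} frames")
    ws = mesh.window_size
    cal = video.calibration
    h, w = video.frame_shape
    shape = (len(frame_pairs), mesh.n_rows, mesh.n_cols)
    displacement = np.zeros(shape + (2,))
    peak_corr = np.full(shape, np.nan)
    speed = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    reason = np.full(shape, REASON_NO_PEAK, dtype=np.int8)
    frames = video.frames
    for p, (k0, k1) in enumerate(frame_pairs):
        gap = k1 - k0
        f0 = frames[k0]
        f1 = frames[k1]
        for i in range(mesh.n_rows):
            for j in range(mesh.n_cols):
                r0, c0 = mesh.window_origin(i, j)
                if r0 < 0 or c0 < 0 or r0 + ws > h or c0 + ws > w:
                    continue
                template = f0[r0 : r0 + ws, c0 : c0 + ws]
                rs = max(0, r0 - search_radius)
                cs = max(0, c0 - search_radius)
                re = min(h, r0 + ws + search_radius)
                ce = min(w, c0 + ws + search_radius)
                try:
                    disp, g = ncc_match(
                        template,
                        f1[rs:re, cs:ce],
                        origin=(r0 - rs, c0 - cs),
                        subpixel=subpixel,
                    )
                except MatchError:
                    reason[p, i, j] = REASON_ZERO_VARIANCE
                    continue
                displacement[p, i, j] = disp
                peak_corr[p, i, j] = g
                if g < min_gamma:
                    reason[p, i, j] = REASON_NO_PEAK
                    continue
                mag = float(np.hypot(*disp))
                speed[p, i, j] = mag * cal.pixel_size * cal.frame_rate / gap
                valid[p, i, j] = True
                reason[p, i, j] = REASON_OK
    return VelocityField(
        frame_pairs=list(frame_pairs),
        displacement=displacement,
        peak_correlation=peak_corr,
        speed=speed,
        valid=valid,
        reason=reason,
        mesh=mesh,
    )


def remove_outliers(
    speeds: np.ndarray, multiplier: float = TUKEY_MULTIPLIER
) -> tuple[np.ndarray, np.ndarray]:
    """Tukey's fences on a collection of speeds.

    Returns ``(kept_values, keep_mask)``. Values outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are flagged; quartiles use the inclusive
    linear-interpolation convention. An IQR of zero removes nothing; fewer
    than 4 values skips filtering with a warning.
    """
    speeds = np.asarray(speeds, dtype=np.float64)
    if speeds.size < 4:
        warnings.warn("fewer than 4 speeds: Tukey filtering skipped", stacklevel=2)
        return speeds, np.ones(speeds.shape, dtype=bool)
    q1, q3 = np.percentile(speeds, [25, 75], method="linear")
    iqr = q3 - q1
    if iqr == 0:
        return speeds, np.ones(speeds.shape, dtype=bool)
    keep = (speeds >= q1 - multiplier * iqr) & (speeds <= q3 + multiplier * iqr)
    return speeds[keep], keep


def filter_field(
    field: VelocityField, multiplier: float = TUKEY_MULTIPLIER
) -> VelocityField:
    """Apply Tukey's fences over all valid speeds of a field, in place.

    Fences are computed on the pooled valid speeds (all frame pairs and
    windows together) and flagged vectors get reason ``REASON_OUTLIER``.
    """
    vals = field.speed[field.valid]
    if vals.size < 4:
        warnings.warn("fewer than 4 valid vectors: Tukey filtering skipped",
                      stacklevel=2)
        return field
    _, keep = remove_outliers(vals, multiplier)
    idx = np.nonzero(field.valid)
    drop = ~keep
    field.valid[idx[0][drop], idx[1][drop], idx[2][drop]] = False
    field.reason[idx[0][drop], idx[1][drop], idx[2][drop]] = REASON_OUTLIER
    return field
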