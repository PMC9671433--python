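"""Rest-interval selection by inter-frame correlation.

Intravital recordings carry episodic whole-frame motion from tissue
contraction and respiration. Rather than registering frames, the method
selects a contiguous span of frames ("rest interval") during which the
tissue is still, scored by the Pearson correlation coefficient

    r_k = sum((f - f̄)(g - ḡ)) / sqrt(sum((f - f̄)²) sum((g - ḡ)²))

computed between consecutive frames over a small interrogation window
placed by the user outside the most prominent vessels (flowing blood
decorrelates frames even at rest, so the window must sample tissue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    BoundsError,
    InputError,
    NoRestIntervalError,
    UndefinedCorrelationError,
)
from .io import VideoSequence

#: Rest-interval length used by default (frames).
DEFAULT_REST_LENGTH = 50


@dataclass(frozen=True)
class InterrogationWindow:
    """An axis-aligned rectangular patch, ``origin`` = (row, col)."""

    origin: tuple[int, int]
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise InputError("interrogation window must be at least 2x2 pixels")
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise BoundsError(f"window origin {self.origin} outside frame")

    def validate(self, frame_shape: tuple[int, int]) -> None:
        r, c = self.origin
        if r + self.height > frame_shape[0] or c + self.width > frame_shape[1]:
            raise BoundsError(
                f"window {self} exceeds frame of shape {frame_shape}"
            )

    def slices(self) -> tuple[slice, slice]:
        r, c = self.origin
        return slice(r, r + self.height), slice(c, c + self.width)


@dataclass
class CorrelationTrace:
    """Consecutive-pair correlations r_k; undefined pairs stored as NaN."""

    values: np.ndarray
    window: InterrogationWindow

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class RestInterval:
    """A span of ``length`` frames starting at ``start_frame``."""

    start_frame: int
    length: int
    score: float = math.nan

    def __post_init__(self) -> None:
        if self.start_frame < 0:
            raise InputError("start_frame must be >= 0")
        if self.length < 2:
            raise InputError("rest interval needs at least 2 frames")

    @property
    def stop_frame(self) -> int:
        """Exclusive end index."""
        return self.start_frame + self.length


def frame_correlation(f: np.ndarray, g: np.ndarray) -> float:
    """Pearson correlation between two equally-shaped grayscale windows.

    Raises :class:`UndefinedCorrelationError` when either window is uniform
    (zero variance), in which case the coefficient is undefined.
    """
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape:
        raise InputError(f"window shapes differ: {f.shape} vs {g.shape}")
    df = f - f.mean()
    dg = g - g.mean()
    denom = math.sqrt(float((df * df).sum()) * float((dg * dg).sum()))
    if denom == 0.0:
        raise UndefinedCorrelationError("zero intensity variance in a window")
    r = float((df * dg).sum()) / denom
    # guard against tiny float excursions outside [-1, 1]
    return min(1.0, max(-1.0, r))


def correlation_trace(
    video: VideoSequence, iw: InterrogationWindow
) -> CorrelationTrace:
    """Correlation r_k of every consecutive frame pair (k, k+1) in ``iw``.

    Pairs where either window is uniform are flagged NaN, not dropped, so
    the trace index always equals the first frame of the pair.
    """
    iw.validate(video.frame_shape)
    sl = iw.slices()
    patches = video.frames[:, sl[0], sl[1]].astype(np.float64)
    n = video.frame_count
    values = np.empty(n - 1, dtype=np.float64)
    for k in range(n - 1):
        try:
            values[k] = frame_correlation(patches[k], patches[k + 1])
        except UndefinedCorrelationError:
            values[k] = np.nan
    return CorrelationTrace(values=values, window=iw)


def find_rest_interval(
    trace: CorrelationTrace, length: int = DEFAULT_REST_LENGTH
) -> RestInterval:
    """Frame window of ``length`` frames with maximal mean pair correlation.

    A window of L frames covers L-1 consecutive pairs; its score is the
    mean of those pair correlations. Ties go to the earliest start; windows
    containing an undefined pair are ineligible.
    """
    if length < 2:
        raise InputError("rest-interval length must be >= 2 frames")
    n_pairs = len(trace.values)
    n_frames = n_pairs + 1
    if n_frames < length:
        raise InputError(
            f"video has {n_frames} frames, shorter than rest length {length}"
        )
    w = length - 1  # pairs per window
    valid = trace.defined
    vals = np.where(valid, trace.values, 0.0)
    # sliding sums over pairs
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    starts = np.arange(n_pairs - w + 1)
    sums = csum[starts + w] - csum[starts]
    counts = ccnt[starts + w] - ccnt[starts]
    eligible = counts == w
    if not np.any(eligible):
        raise NoRestIntervalError(
            "every candidate window contains an undefined correlation pair"
        )
    scores = np.where(eligible, sums / w, -np.inf)
    # earliest start wins ties; cumulative sums carry ~1e-15 float drift,
    # so compare with a tolerance far below any real correlation difference
    top = scores.max()
    best = int(np.argmax(scores >= top - 1e-10))
    return RestInterval(start_frame=best, length=length, score=float(scores[best]))


def suggest_window(
    video: VideoSequence, width: int = 32, height: int = 32, stride: int = 16
) -> InterrogationWindow:
    """Suggest a background interrogation window (lowest temporal variance).

    A convenience helper only: window placement is a user decision and this
    suggestion never overrides an explicit choice. Scans a coarse grid and
    returns the block whose summed per-pixel temporal variance is smallest,
    i.e. the stillest, most vessel-free patch.
    """
    h, w = video.frame_shape
    if width > w or height > h:
        raise BoundsError("suggested window larger than the frame")
    var = np.var(video.frames.astype(np.float64), axis=0)
    best: tuple[float, int, int] | None = None
    for r in range(0, h - height + 1, stride):
        for c in range(0, w - width + 1, stride):
            s = float(var[r : r + height, c : c + width].sum())
            if best is None or s < best[0]:
                best = (s, r, c)
    assert best is not None
    return InterrogationWindow(origin=(best[1], best[2]), width=width, height=height)
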