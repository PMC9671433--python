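"""Video input and result output.

Conventions used throughout the package (stated once, here):

* pixel coordinates are 0-based ``(row, col)`` with the origin at the
  top-left of the frame;
* angles are measured counter-clockwise from the image horizontal axis,
  in degrees, and reduced to ``[0, 180)``;
* intensities are kept in the native integer depth of the container
  (8- or 16-bit) until a variance or correlation is computed, which is
  always done in ``float64``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, InputError

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
_BT601 = np.array([0.299, 0.587, 0.114])

_FRAME_EXTENSIONS = {".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal calibration of a recording.

    Parameters
    ----------
    pixel_size : float
        Physical size of one pixel, in micrometres per pixel.
    frame_rate : float
        Acquisition rate in frames per second.
    """

    pixel_size: float
    frame_rate: float

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise InputError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.frame_rate > 0):
            raise InputError(f"frame_rate must be > 0, got {self.frame_rate}")


@dataclass
class VideoSequence:
    """An ordered stack of single-channel grayscale frames.

    ``frames`` is an ``(n_frames, height, width)`` array. Intensities stay
    in their native dtype; downstream statistics promote to float.
    """

    frames: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InputError(
                f"frames must be (n, height, width), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InputError("a video needs at least 2 frames")
        if np.issubdtype(self.frames.dtype, np.floating) and not np.all(
            np.isfinite(self.frames)
        ):
            raise InputError("frame intensities must be finite")

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame stack to single-channel grayscale.

    Already-grayscale input is returned unchanged (identity). RGB uses
    BT.601 luma weights and is rounded back to the input integer dtype;
    an alpha channel is ignored. Any other channel count is ambiguous.
    """
    frames = np.asarray(frames)
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        rgb = frames[..., :3]
        luma = rgb.astype(np.float64) @ _BT601
        if np.issubdtype(frames.dtype, np.integer):
            info = np.iinfo(frames.dtype)
            return np.clip(np.rint(luma), info.min, info.max).astype(frames.dtype)
        return luma
    raise FormatError(
        f"cannot interpret shape {frames.shape} as grayscale or RGB(A) video"
    )


def _read_container(path: Path) -> np.ndarray:
    if path.is_dir():
        names = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not names:
            raise FormatError(f"no PNG/TIFF frames found in directory {path}")
        import imageio.v3 as iio

        frames = [np.asarray(iio.imread(p)) for p in names]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise FormatError(f"frames in {path} have differing shapes: {shapes}")
        return np.stack(frames)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        try:
            return np.asarray(tifffile.imread(path))
        except Exception as exc:  # tifffile raises assorted types on truncation
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if suffix == ".avi":
        try:
            import imageio.v3 as iio

            return np.asarray(iio.imread(path, plugin=None))
        except Exception as exc:
            raise FormatError(
                f"cannot decode AVI {path}: no working decoder available "
                f"({exc}); convert to multi-page TIFF or a frame directory"
            ) from exc
    raise FormatError(f"unsupported container {path.suffix!r} for {path}")


def load_video(path: str | os.PathLike, calibration: Calibration) -> VideoSequence:
    """Load a video from a multi-page TIFF, AVI, or directory of frames.

    Frames are converted to single-channel grayscale (BT.601 for RGB) with
    order preserved; the calibration record is attached to the result.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input path does not exist: {path}")
    frames = _read_container(path)
    if frames.ndim == 2:
        frames = frames[None]
    frames = to_grayscale(frames)
    if frames.shape[0] < 2:
        raise InputError(
            f"video {path} has {frames.shape[0]} frame(s); at least 2 required"
        )
    return VideoSequence(frames=frames, calibration=calibration)


# ---------------------------------------------------------------------------
# Result tables


RESULT_COLUMNS = [
    "stage",
    "frame_start",
    "frame_end",
    "diameter_um",
    "mean_velocity_um_s",
    "v_max_um_s",
    "bluntness_k",
    "percent_change",
]


def write_results(
    records: Iterable[Mapping[str, Any]] | pd.DataFrame,
    path: str | os.PathLike,
    *,
    config: Mapping[str, Any] | None = None,
    provenance: Mapping[str, Any] | None = None,
) -> None:
    """Write measurement records to CSV with a JSON sidecar.

    One row per measurement; the sidecar ``<path>.json`` captures the
    configuration and provenance of the run. Floats are written with
    ``repr`` precision so a read-back reproduces them exactly.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        table = records
    else:
        records = list(records)
        table = pd.DataFrame.from_records(records) if records else pd.DataFrame(
            columns=RESULT_COLUMNS
        )
    try:
        table.to_csv(path, index=False, float_format=None)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    sidecar = {
        "config": dict(config or {}),
        "provenance": dict(provenance or {}),
        "columns": list(table.columns),
        "n_rows": int(len(table)),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_results`."""
    return pd.read_csv(path)
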