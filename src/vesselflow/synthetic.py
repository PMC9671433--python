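"""Synthetic intravital-microscopy videos with exact ground truth.

Validation by simulation: the pipeline is exercised on computer-generated
videos that emulate the relevant features of a transilluminated cremaster
recording — a dark, roughly straight vessel band on a lighter textured
background, RBC-sized dark particles advected by an axisymmetric profile
V(r) = Vmax (1 - (|r|/R)^k), episodic whole-frame jitter standing in for
muscle contraction, and optional diameter-change schedules — while every
generative quantity (diameter per frame, velocity profile, particle
tracks, quiet spans) is recorded as ground truth.

Deliberately NOT modeled: light scattering, the biconcave RBC shape,
two-phase plasma/cell rheology, radial particle migration, and 3-D vessel
geometry. Particles are anti-aliased discs and advection is axial-only,
matching the axisymmetric model under test.

All randomness comes from one seeded generator per scene; rendering is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import ndimage

from .exceptions import InputError
from .io import Calibration, VideoSequence

#: Default calibration mirrors the experimental recording setup:
#: 0.34 um/pixel at 2000 frames/s.
DEFAULT_CALIBRATION = Calibration(pixel_size=0.34, frame_rate=2000.0)

# 8-bit gray levels of the rendered scene
BACKGROUND_LEVEL = 170.0
LUMEN_LEVEL = 130.0
PARTICLE_LEVEL = 60.0
WALL_DARKENING = 35.0  # extra darkening of a ~1.5 px wall line


@dataclass(frozen=True)
class VesselSpec:
    """Geometry and appearance of the vessel band."""

    diameter_um: float = 25.0
    orientation_deg: float = 0.0  # CCW from horizontal, [0, 180)
    wall_contrast: float = WALL_DARKENING
    centerline_offset_px: float = 0.0  # normal offset from frame center


@dataclass(frozen=True)
class FlowSpec:
    """Axisymmetric flow profile and tracer particles.

    Defaults sit mid-range of the experimental regime (20-30 um arterioles,
    ~700-1800 um/s): Vmax 1400 um/s, parabolic k = 2, RBC-sized discs of
    radius 3.4 um (10 px). The density approximates the projected cell
    coverage of a transilluminated arteriole: light crosses a ~25 um deep
    column of blood at ~25% tube hematocrit, so nearly every lumen pixel
    lies over some cell and the lumen is a continuous moving texture.
    """

    v_max_um_s: float = 1400.0
    bluntness_k: float = 2.0
    particle_radius_um: float = 3.4
    particle_density_per_um2: float = 0.08
    particle_contrast: float = LUMEN_LEVEL - PARTICLE_LEVEL


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise and static background texture."""

    gaussian_sigma: float = 2.0
    texture_amplitude: float = 8.0
    texture_scale_px: float = 4.0


@dataclass(frozen=True)
class JitterEpisode:
    """Whole-frame translation episode over [start_frame, end_frame)."""

    start_frame: int
    end_frame: int
    amplitude_px: int = 4
    pattern: str = "random"  # "random" integer offsets per frame


@dataclass
class SceneSpec:
    """Complete description of one synthetic scene."""

    frame_size: tuple[int, int] = (256, 256)
    n_frames: int = 300
    calibration: Calibration = field(default_factory=lambda: DEFAULT_CALIBRATION)
    vessel: VesselSpec = field(default_factory=VesselSpec)
    flow: FlowSpec = field(default_factory=FlowSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    jitter: list[JitterEpisode] = field(default_factory=list)
    contraction: list[tuple[int, float]] | None = None  # (frame, diameter um)
    seed: int = 0

    def validate(self) -> None:
        h, w = self.frame_size
        extent_um = min(h, w) * self.calibration.pixel_size
        if not (0 < self.vessel.diameter_um < extent_um):
            raise InputError(
                f"diameter {self.vessel.diameter_um} um must be positive and "
                f"smaller than the frame extent {extent_um:.1f} um"
            )
        if self.flow.v_max_um_s < 0:
            raise InputError("v_max must be >= 0")
        if self.flow.particle_density_per_um2 < 0:
            raise InputError("particle density must be >= 0")
        if self.n_frames < 2:
            raise InputError("need at least 2 frames")
        for ep in self.jitter:
            if not (0 <= ep.start_frame < ep.end_frame <= self.n_frames):
                raise InputError(f"jitter episode {ep} outside video")
        if self.contraction is not None:
            frames = [f for f, _ in self.contraction]
            if frames != sorted(frames):
                raise InputError("contraction schedule must be monotone in frame")
            for _, d in self.contraction:
                if not (0 < d < extent_um):
                    raise InputError(f"contraction diameter {d} um out of range")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["calibration"] = {
            "pixel_size": self.calibration.pixel_size,
            "frame_rate": self.calibration.frame_rate,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SceneSpec":
        d = dict(d)
        if "calibration" in d:
            d["calibration"] = Calibration(**d["calibration"])
        for key, sub in (("vessel", VesselSpec), ("flow", FlowSpec), ("noise", NoiseSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "jitter" in d:
            d["jitter"] = [
                JitterEpisode(**ep) if isinstance(ep, dict) else ep
                for ep in d["jitter"]
            ]
        if "frame_size" in d:
            d["frame_size"] = tuple(d["frame_size"])
        if "contraction" in d and d["contraction"] is not None:
            d["contraction"] = [tuple(k) for k in d["contraction"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact generative quantities mirrored from a SceneSpec render."""

    diameter_um_per_frame: np.ndarray  # (n_frames,)
    v_max_um_s: float
    bluntness_k: float
    particle_tracks: np.ndarray  # (n_frames, n_particles, 2) px (row, col)
    particle_radial_um: np.ndarray  # (n_frames, n_particles) signed r
    rest_spans: list[tuple[int, int]]  # jitter-free [start, end) frame ranges
    jitter_offsets: np.ndarray  # (n_frames, 2) integer (drow, dcol)

    def velocity_profile(self, r_um: np.ndarray, frame: int = 0,
                         diameter_um: float | None = None) -> np.ndarray:
        """Exact generative speed V(r) in um/s at signed radii ``r_um``."""
        if diameter_um is None:
            diameter_um = float(self.diameter_um_per_frame[frame])
        radius = diameter_um / 2.0
        r = np.minimum(np.abs(np.asarray(r_um, dtype=np.float64)), radius)
        return self.v_max_um_s * (1.0 - (r / radius) ** self.bluntness_k)


def _axes(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Signed radial and axial pixel coordinates of every pixel.

    Orientation theta (CCW from horizontal as displayed, row axis down)
    has along-vessel direction (dcol, drow) = (cos t, -sin t) and normal
    (sin t, cos t); radial = normal . (pixel - center) and axial is the
    along-vessel coordinate.
    """
    h, w = spec.frame_size
    sin_t, cos_t = _trig(spec.vessel.orientation_deg)
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy = rows - cy - spec.vessel.centerline_offset_px * cos_t
    dx = cols - cx - spec.vessel.centerline_offset_px * sin_t
    radial = sin_t * dx + cos_t * dy
    axial = cos_t * dx - sin_t * dy
    return radial, axial


def _trig(angle_deg: float) -> tuple[float, float]:
    """(sin, cos) with float dust snapped at exact right angles."""
    t = np.deg2rad(angle_deg)
    sin_t, cos_t = float(np.sin(t)), float(np.cos(t))
    if abs(sin_t) < 1e-12:
        sin_t = 0.0
    if abs(cos_t) < 1e-12:
        cos_t = 0.0
    return sin_t, cos_t


def _diameter_schedule(spec: SceneSpec) -> np.ndarray:
    frames = np.arange(spec.n_frames, dtype=np.float64)
    if not spec.contraction:
        return np.full(spec.n_frames, spec.vessel.diameter_um)
    knots_f = np.array([f for f, _ in spec.contraction], dtype=np.float64)
    knots_d = np.array([d for _, d in spec.contraction], dtype=np.float64)
    return np.interp(frames, knots_f, knots_d,
                     left=knots_d[0], right=knots_d[-1])


def _jitter_offsets(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    offsets = np.zeros((spec.n_frames, 2), dtype=np.int64)
    for ep in spec.jitter:
        for f in range(ep.start_frame, ep.end_frame):
            if ep.pattern == "random":
                # nonzero integer offsets so every episode frame truly moves
                while True:
                    o = rng.integers(-ep.amplitude_px, ep.amplitude_px + 1, size=2)
                    if o[0] != 0 or o[1] != 0:
                        break
                offsets[f] = o
            else:
                raise InputError(f"unknown jitter pattern {ep.pattern!r}")
    return offsets


def _rest_spans(spec: SceneSpec) -> list[tuple[int, int]]:
    moving = np.zeros(spec.n_frames, dtype=bool)
    for ep in spec.jitter:
        moving[ep.start_frame : ep.end_frame] = True
    spans: list[tuple[int, int]] = []
    start = None
    for f in range(spec.n_frames):
        if not moving[f] and start is None:
            start = f
        elif moving[f] and start is not None:
            spans.append((start, f))
            start = None
    if start is not None:
        spans.append((start, spec.n_frames))
    return spans


def _stamp_particles(
    frame: np.ndarray,
    positions: np.ndarray,
    radius_px: float,
    contrast: float,
    lumen: np.ndarray,
) -> None:
    """Draw anti-aliased dome-shaded dark cells, clipped to the lumen.

    Shading falls off parabolically from the center so the particle
    interior carries an intensity gradient: a correlation window landing
    anywhere on a cell then has texture to track (a uniform disc would be
    featureless inside and untrackable). Overlapping cells combine by
    maximum opacity rather than adding — cells are opaque absorbers, so a
    stack of them is no darker than one, which keeps the texture crisp at
    realistic packing densities.
    """
    h, w = frame.shape
    pad = int(np.ceil(radius_px)) + 1
    opacity = np.zeros_like(frame)
    for pr, pc in positions:
        r0 = max(0, int(np.floor(pr)) - pad)
        r1 = min(h, int(np.ceil(pr)) + pad + 1)
        c0 = max(0, int(np.floor(pc)) - pad)
        c1 = min(w, int(np.ceil(pc)) + pad + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dist = np.hypot(rr - pr, cc - pc)
        coverage = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
        dome = np.clip(1.0 - (dist / (radius_px + 0.5)) ** 2, 0.0, 1.0)
        np.maximum(opacity[r0:r1, c0:c1], coverage * dome,
                   out=opacity[r0:r1, c0:c1])
    frame -= contrast * opacity * lumen


def render_scene(spec: SceneSpec) -> tuple[VideoSequence, GroundTruth]:
    """Render a synthetic scene and its exact ground truth.

    Particles are seeded uniformly in the lumen and advected along the
    vessel axis by V(r)/frame_rate per frame with periodic axial
    wrap-around, so particle count is conserved. Jitter episodes translate
    the whole frame by integer offsets (periodic boundary). Contraction
    interpolates the diameter linearly between schedule knots and rescales
    particle radial positions with the lumen so they stay inside.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    px = spec.calibration.pixel_size
    fps = spec.calibration.frame_rate
    radial_px, axial_px = _axes(spec)

    # static background texture (value noise smoothed to a spatial scale)
    tex = rng.normal(0.0, 1.0, size=(h, w))
    tex = ndimage.gaussian_filter(tex, spec.noise.texture_scale_px)
    std = tex.std()
    if std > 0:
        tex *= spec.noise.texture_amplitude / std
    background = BACKGROUND_LEVEL + tex

    diam_um = _diameter_schedule(spec)
    radius0_px = diam_um[0] / 2.0 / px
    pr_px = spec.flow.particle_radius_um / px

    # particle seeding in the frame-0 lumen
    axial_extent = float(np.hypot(h, w)) + 4 * pr_px  # covers any orientation
    # lumen area seeded = diameter x axial extent (um²)
    n_particles = int(round(spec.flow.particle_density_per_um2
                            * diam_um[0] * (axial_extent * px)))
    n_particles = max(n_particles, 0)
    ax0 = rng.uniform(-axial_extent / 2.0, axial_extent / 2.0, size=n_particles)
    # uniform across the whole lumen; rendering clips discs at the wall
    rad0 = rng.uniform(-radius0_px, radius0_px, size=n_particles)

    offsets = _jitter_offsets(spec, rng)
    # per-frame noise drawn up front in frame order for reproducibility
    noise_sigma = spec.noise.gaussian_sigma

    sin_t, cos_t = _trig(spec.vessel.orientation_deg)
    along = np.array([-sin_t, cos_t])  # (drow, dcol) per +axial
    normal = np.array([cos_t, sin_t])  # (drow, dcol) per +radial
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    center = np.array([cy + spec.vessel.centerline_offset_px * cos_t,
                       cx + spec.vessel.centerline_offset_px * sin_t])

    frames = np.empty((spec.n_frames, h, w), dtype=np.uint8)
    tracks = np.empty((spec.n_frames, n_particles, 2))
    radial_track = np.empty((spec.n_frames, n_particles))
    axial = ax0.copy()
    rad = rad0.copy()

    for f in range(spec.n_frames):
        radius_px_f = diam_um[f] / 2.0 / px
        scale = radius_px_f / radius0_px
        rad_f = rad0 * scale
        lumen = np.abs(radial_px) <= radius_px_f
        img = np.where(lumen, LUMEN_LEVEL, background)
        # darken a thin wall line just outside the lumen
        wall = (~lumen) & (np.abs(radial_px) <= radius_px_f + 1.5)
        img = np.where(wall, img - spec.vessel.wall_contrast, img)

        if n_particles:
            pos = (center[None, :]
                   + axial[:, None] * along[None, :]
                   + rad_f[:, None] * normal[None, :])
            _stamp_particles(img, pos, pr_px, spec.flow.particle_contrast,
                             lumen.astype(np.float64))
            tracks[f] = pos
            radial_track[f] = rad_f * px
        if offsets[f, 0] or offsets[f, 1]:
            img = np.roll(img, shift=tuple(offsets[f]), axis=(0, 1))
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

        # advect for the next frame: axial step = V(r) / fps, in px
        if n_particles:
            r_um = np.abs(rad_f) * px
            radius_um_f = radius_px_f * px
            v = spec.flow.v_max_um_s * (
                1.0 - (np.minimum(r_um, radius_um_f) / radius_um_f)
                ** spec.flow.bluntness_k
            )
            axial = axial + v / fps / px
            # periodic wrap keeps particle count conserved
            axial = ((axial + axial_extent / 2.0) % axial_extent
                     - axial_extent / 2.0)

    video = VideoSequence(frames=frames, calibration=spec.calibration)
    truth = GroundTruth(
        diameter_um_per_frame=diam_um,
        v_max_um_s=spec.flow.v_max_um_s,
        bluntness_k=spec.flow.bluntness_k,
        particle_tracks=tracks,
        particle_radial_um=radial_track,
        rest_spans=_rest_spans(spec),
        jitter_offsets=offsets,
    )
    return video, truth


def fixture_specs() -> dict[str, SceneSpec]:
    """Named deterministic scene specifications used across the test suite.

    Each fixture is at most 300 frames of 256x256 px so the full suite
    renders in minutes. "constriction" drops the diameter by 80% mid-video
    — the strongest constriction the method is expected to segment.
    """
    return {
        "static": SceneSpec(
            n_frames=120,
            flow=FlowSpec(v_max_um_s=0.0),
            noise=NoiseSpec(gaussian_sigma=1.0),
            seed=101,
        ),
        "parabolic_default": SceneSpec(
            n_frames=300,
            vessel=VesselSpec(diameter_um=25.0),
            flow=FlowSpec(v_max_um_s=1400.0, bluntness_k=2.0),
            jitter=[JitterEpisode(start_frame=100, end_frame=140)],
            seed=202,
        ),
        "blunt_k4": SceneSpec(
            n_frames=300,
            vessel=VesselSpec(diameter_um=25.0),
            flow=FlowSpec(v_max_um_s=1400.0, bluntness_k=4.0),
            jitter=[JitterEpisode(start_frame=100, end_frame=140)],
            seed=303,
        ),
        "constriction": SceneSpec(
            n_frames=200,
            vessel=VesselSpec(diameter_um=25.0),
            flow=FlowSpec(v_max_um_s=900.0),
            contraction=[(0, 25.0), (80, 25.0), (120, 5.0), (200, 5.0)],
            seed=404,
        ),
        "jittered": SceneSpec(
            n_frames=240,
            jitter=[
                JitterEpisode(start_frame=30, end_frame=60, amplitude_px=5),
                JitterEpisode(start_frame=150, end_frame=180, amplitude_px=5),
            ],
            seed=505,
        ),
        "noisy": SceneSpec(
            n_frames=200,
            noise=NoiseSpec(gaussian_sigma=6.0, texture_amplitude=12.0),
            seed=606,
        ),
    }


def fixture_suite() -> dict[str, tuple[SceneSpec, GroundTruth]]:
    """Render every named fixture; returns name -> (SceneSpec, GroundTruth).

    Rendering the same spec again (``render_scene``) reproduces the video
    bit-identically, so callers needing frames can re-render cheaply.
    """
    out: dict[str, tuple[SceneSpec, GroundTruth]] = {}
    for name, spec in fixture_specs().items():
        _, truth = render_scene(spec)
        out[name] = (spec, truth)
    return out
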