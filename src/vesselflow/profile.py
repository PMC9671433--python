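"""Radial velocity profile averaging and bluntness-model fitting.

The velocity field is reduced to a single radial profile: per mesh column
a time average over frame pairs, then an unweighted spatial average across
columns. The profile is fitted with the axisymmetric bluntness model

    V(r) = Vmax * (1 - (|r| / R)^k)

where R is the vessel radius (fixed from the measured diameter, not
co-fitted) and k is the bluntness index: k = 2 is parabolic (Poiseuille)
flow, larger k approaches plug flow. The cross-sectional mean velocity of
this profile over the circular lumen is Vmax * k / (k + 2), and volumetric
flow is mean velocity times pi R².

Given k, the optimal Vmax is linear least squares, so the fit profiles
Vmax out analytically and searches only over k — mathematically equivalent
to the joint optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import FitError, InputError
from .io import Calibration
from .piv import PIVMesh, VelocityField

K_RANGE = (0.5, 10.0)
K_STARTS = (1.0, 2.0, 4.0)
#: Relative parameter tolerance declared converged.
K_TOL = 1e-6


@dataclass
class VelocityProfile:
    """Time/space-averaged speed per mesh row at signed radial positions."""

    radial_positions: np.ndarray  # um, signed, 0 at centerline
    speeds: np.ndarray  # um/s; NaN where a row had no valid vector
    n_valid: np.ndarray  # vectors averaged per row

    def __post_init__(self) -> None:
        self.radial_positions = np.asarray(self.radial_positions, dtype=np.float64)
        self.speeds = np.asarray(self.speeds, dtype=np.float64)
        self.n_valid = np.asarray(self.n_valid, dtype=np.int64)

    @property
    def missing(self) -> np.ndarray:
        return self.n_valid == 0


@dataclass(frozen=True)
class ProfileFit:
    """Least-squares fit of the bluntness model to a velocity profile."""

    v_max: float  # um/s
    radius_R: float  # um, fixed input
    bluntness_k: float
    rss: float  # residual sum of squares, (um/s)²
    mean_velocity: float  # um/s, = v_max * k / (k + 2)
    flow: float  # um³/s, = mean_velocity * pi R²
    residuals: np.ndarray | None = None


def average_profiles(
    field: VelocityField, mesh: PIVMesh, calibration: Calibration
) -> VelocityProfile:
    """Collapse a velocity field to one radial profile.

    Per column, valid speeds are time-averaged per mesh row; the column
    profiles are then averaged unweighted (columns with no valid vector in
    a row are excluded from that row's mean). Radial position of a row is
    the signed distance of its window center from the lumen centerline,
    in micrometres.
    """
    if not field.valid.any():
        raise InputError("velocity field has no valid vectors")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
        speed = np.where(field.valid, field.speed, np.nan)
        # time average per (row, col)
        col_profiles = np.nanmean(speed, axis=0)  # (n_rows, n_cols)
        # spatial average across columns
        speeds = np.nanmean(col_profiles, axis=1)  # (n_rows,)
    n_valid = field.valid.sum(axis=(0, 2))
    radial = (mesh.row_centers - mesh.centerline_row) * calibration.pixel_size
    return VelocityProfile(radial_positions=radial, speeds=speeds, n_valid=n_valid)


def _design(radial_abs: np.ndarray, radius: float, k: float) -> np.ndarray:
    return 1.0 - (radial_abs / radius) ** k


def fit_profile(
    profile: VelocityProfile,
    radius_R: float,
    k_range: tuple[float, float] = K_RANGE,
) -> ProfileFit:
    """Least-squares fit of V = Vmax (1 - (|r|/R)^k) with R fixed.

    Vmax is profiled out analytically for each candidate k; k is optimized
    inside ``k_range`` with multistart (local minimization from k = 1, 2
    and 4, then a bounded polish). Rows with no valid vectors are excluded;
    rows at or beyond the wall are clamped to 0.999 R with a warning.
    """
    if radius_R <= 0:
        raise InputError("radius_R must be positive")
    ok = ~profile.missing & np.isfinite(profile.speeds)
    r = np.abs(profile.radial_positions[ok])
    v = profile.speeds[ok]
    if r.size < 4:
        raise FitError(f"only {r.size} usable profile rows; need at least 4")
    if np.any(r >= radius_R):
        warnings.warn(
            "radial positions at or beyond the wall clamped to 0.999 R",
            stacklevel=2,
        )
        r = np.minimum(r, 0.999 * radius_R)
    if np.ptp(v) == 0 and v[0] == 0:
        raise FitError("flat all-zero profile: no flow to fit")

    def vmax_for(k: float) -> float:
        b = _design(r, radius_R, k)
        denom = float(b @ b)
        if denom == 0.0:
            return 0.0
        return float(v @ b) / denom

    def rss(k: float) -> float:
        b = _design(r, radius_R, k)
        return float(np.sum((v - vmax_for(k) * b) ** 2))

    lo, hi = k_range
    best_k, best_rss = None, np.inf
    for start in K_STARTS:
        x0 = float(np.clip(start, lo, hi))
        res = optimize.minimize(
            lambda x: rss(float(x[0])),
            x0=[x0],
            bounds=[(lo, hi)],
            method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": 1e-12},
        )
        k_cand = float(res.x[0])
        if res.fun < best_rss:
            best_k, best_rss = k_cand, float(res.fun)
    assert best_k is not None
    # bounded scalar polish around the multistart winner
    bl = max(lo, best_k - 0.5)
    bh = min(hi, best_k + 0.5)
    res = optimize.minimize_scalar(
        rss, bounds=(bl, bh), method="bounded", options={"xatol": K_TOL * max(1.0, best_k)}
    )
    if float(res.fun) <= best_rss:
        best_k, best_rss = float(res.x), float(res.fun)
    if not np.isfinite(best_rss):
        raise FitError("profile fit did not converge")
    v_max = vmax_for(best_k)
    if v_max <= 0:
        raise FitError(f"fitted Vmax {v_max:.3g} um/s is not positive")
    residuals = v - v_max * _design(r, radius_R, best_k)
    rms = float(np.sqrt(best_rss / r.size))
    if v_max <= rms:
        raise FitError(
            f"flat profile: fitted Vmax {v_max:.3g} um/s does not exceed the "
            f"residual noise level {rms:.3g} um/s"
        )
    mean_v, flow = _mean_velocity_and_flow(v_max, best_k, radius_R)
    return ProfileFit(
        v_max=v_max,
        radius_R=radius_R,
        bluntness_k=best_k,
        rss=best_rss,
        mean_velocity=mean_v,
        flow=flow,
        residuals=residuals,
    )


def _mean_velocity_and_flow(
    v_max: float, k: float, radius: float
) -> tuple[float, float]:
    mean_v = v_max * k / (k + 2.0)
    return mean_v, mean_v * np.pi * radius**2


def mean_velocity_and_flow(fit: ProfileFit) -> tuple[float, float]:
    """Cross-sectional mean velocity (um/s) and volumetric flow (um³/s).

    Integrating V(r) over the circular cross-section gives
    mean = Vmax k / (k + 2); flow = mean * pi R². For k = 2 this is the
    classic parabolic result mean = Vmax / 2; k -> inf approaches plug
    flow (mean -> Vmax).
    """
    return _mean_velocity_and_flow(fit.v_max, fit.bluntness_k, fit.radius_R)
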