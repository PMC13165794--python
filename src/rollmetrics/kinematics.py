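"""Frame kinematics from left/right wheel angular velocity.

A cambered differential-drive model: with wheel radius r, camber angle
theta (tops tilted inwards) and hub track width w, the effective rolling
radius is r_eff = r*cos(theta) and the ground-contact track widens to
w_g = w + 2*r*sin(theta).  Frame speed and yaw rate follow from the wheel
angular rates (omega in rad/s):

    v        = r_eff * (omega_L + omega_R) / 2
    yaw_rate = r_eff * (omega_R - omega_L) / w_g      (+ = counter-clockwise)
    radius   = v / |yaw_rate|                          (straights: undefined)

Cumulative distance is the trapezoidal integral of v; acceleration is a
central difference of a lightly smoothed v (0.5 s moving average) because
the 100 Hz gyro derivative is otherwise noise-dominated.

Distance calibration: integrating v over a known reference distance gives
a multiplicative correction factor (reference/computed) applied uniformly
to v, a and distance; a typical wheel-radius error of ~0.1 % is absorbed
this way.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d

__all__ = [
    "WheelchairGeometry",
    "FrameKinematics",
    "DistanceCalibration",
    "frame_kinematics",
    "calibrate_distance",
    "apply_correction",
]

GYRO_RANGE_DPS = 2000.0
YAW_RATE_FLOOR = 1e-3  # rad/s below which turn radius is undefined


@dataclass(frozen=True)
class WheelchairGeometry:
    """Wheel radius (m), camber angle (deg), hub track width (m)."""

    wheel_radius: float = 0.305
    camber_deg: float = 3.2
    track_width_hub: float = 0.56

    def __post_init__(self) -> None:
        if self.wheel_radius <= 0:
            raise ValueError("wheel_radius must be > 0")
        if not 0 <= self.camber_deg < 45:
            raise ValueError("camber_deg must be in [0, 45)")
        if self.track_width_hub <= 0:
            raise ValueError("track_width_hub must be > 0")

    @property
    def effective_radius(self) -> float:
        return self.wheel_radius * np.cos(np.radians(self.camber_deg))

    @property
    def ground_track(self) -> float:
        return self.track_width_hub + 2 * self.wheel_radius * np.sin(np.radians(self.camber_deg))


@dataclass(frozen=True)
class FrameKinematics:
    t: np.ndarray          # s
    v: np.ndarray          # m/s
    a: np.ndarray          # m/s^2
    yaw_rate: np.ndarray   # rad/s
    turn_radius: np.ndarray  # m, NaN on straights
    dist: np.ndarray       # m, cumulative


@dataclass(frozen=True)
class DistanceCalibration:
    correction_factor: float
    reference_distance: float
    computed_distance: float

    @property
    def overestimate_percent(self) -> float:
        """Signed overestimate of the computed distance, in percent."""
        return 100.0 * (self.computed_distance - self.reference_distance) / self.reference_distance


def frame_kinematics(
    t: np.ndarray,
    omega_left_dps: np.ndarray,
    omega_right_dps: np.ndarray,
    geometry: WheelchairGeometry,
    smooth_window_s: float = 0.5,
) -> FrameKinematics:
    """Compute frame speed, acceleration, yaw rate, turn radius and distance.

    ``omega_*_dps`` are wheel angular velocities in deg/s on a shared
    (post-synchronisation) time base.  Values outside the gyroscope range
    (+/-2000 deg/s) are clipped with a warning.
    """
    t = np.asarray(t, dtype=float)
    wl = np.asarray(omega_left_dps, dtype=float)
    wr = np.asarray(omega_right_dps, dtype=float)
    if not (t.shape == wl.shape == wr.shape) or t.ndim != 1:
        raise ValueError("mismatched timestamps: t, omega_left, omega_right must share shape")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.abs(wl) > GYRO_RANGE_DPS) or np.any(np.abs(wr) > GYRO_RANGE_DPS):
        import warnings

        warnings.warn("angular velocity outside gyroscope range; clipping to +/-2000 deg/s")
        wl = np.clip(wl, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
        wr = np.clip(wr, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)

    r_eff = geometry.effective_radius
    w_g = geometry.ground_track
    wl_rad = np.radians(wl)
    wr_rad = np.radians(wr)
    v = r_eff * (wl_rad + wr_rad) / 2.0
    yaw = r_eff * (wr_rad - wl_rad) / w_g

    with np.errstate(divide="ignore", invalid="ignore"):
        radius = np.abs(v) / np.abs(yaw)
    radius = np.where(np.abs(yaw) < YAW_RATE_FLOOR, np.nan, radius)

    dt = float(np.median(np.diff(t)))
    if smooth_window_s > 0:
        win = max(1, int(round(smooth_window_s / dt)))
        v_smooth = uniform_filter1d(v, size=win, mode="nearest")
    else:
        v_smooth = v
    a = np.gradient(v_smooth, t)

    dist = np.concatenate(([0.0], cumulative_trapezoid(v, t)))
    return FrameKinematics(t=t, v=v, a=a, yaw_rate=yaw, turn_radius=radius, dist=dist)


def calibrate_distance(computed: float, reference: float) -> DistanceCalibration:
    """Correction factor from a reference-distance calibration roll."""
    if computed <= 0 or reference <= 0:
        raise ValueError("computed and reference distances must be > 0")
    return DistanceCalibration(
        correction_factor=reference / computed,
        reference_distance=reference,
        computed_distance=computed,
    )


def apply_correction(kin: FrameKinematics, cal: DistanceCalibration) -> FrameKinematics:
    """Scale v, a and distance by the calibration factor; yaw is unchanged."""
    if cal.correction_factor <= 0:
        raise ValueError("correction factor must be > 0")
    f = cal.correction_factor
    # turn radius = v/|yaw| scales with v since yaw is left untouched
    return replace(kin, v=kin.v * f, a=kin.a * f, dist=kin.dist * f, turn_radius=kin.turn_radius * f)
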