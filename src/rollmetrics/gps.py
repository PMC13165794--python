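"""GPS track handling: micro-degrees to local metres, path distance, speed,
and alignment of the GPS clock to the IMU clock.

Positions arrive as 1 Hz latitude/longitude in micro-degrees.  They are
converted to a local east/north frame with a fixed small-area scale:
1.11 m per 10 micro-degrees of latitude, and the same scale times the
cosine of the (mean) latitude for longitude.  Over an ~800 m suburban
course the error of a single fixed latitude is negligible (<0.01 %).

The GPS receiver clock is aligned to the IMU clock by matching the
standstill-to-motion ramps at the start and end of a run: the integer-
second offset minimising the squared speed difference over the two ramp
windows is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeoTrack",
    "LocalPath",
    "METRES_PER_10_UDEG_LAT",
    "microdeg_to_metres",
    "metres_to_microdeg",
    "path_distance",
    "gps_speed",
    "align_gps_to_imu",
    "deviation_from_reference",
]

# Fixed conversion scale for latitude: 1.11 m per 10 micro-degrees.
METRES_PER_10_UDEG_LAT = 1.11


@dataclass(frozen=True)
class GeoTrack:
    """1 Hz GPS fixes: time (s), latitude and longitude in micro-degrees."""

    t: np.ndarray
    lat_udeg: np.ndarray
    lon_udeg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("GPS timestamps must be strictly increasing")


@dataclass(frozen=True)
class LocalPath:
    """Local east (x) / north (y) path in metres with cumulative distance."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cumulative_dist: np.ndarray


def lat_scale() -> float:
    """Metres per micro-degree of latitude."""
    return METRES_PER_10_UDEG_LAT / 10.0


def lon_scale(lat_deg: float) -> float:
    """Metres per micro-degree of longitude at the given latitude."""
    return lat_scale() * np.cos(np.radians(lat_deg))


def microdeg_to_metres(track: GeoTrack, ref_point: tuple[float, float] | None = None) -> LocalPath:
    """Convert a micro-degree track to a local metric frame.

    ``ref_point`` is (lat_udeg, lon_udeg) of the local origin; by default
    the first fix, so paths start at (0, 0).  The longitude scale uses the
    track's mean latitude.
    """
    lat = np.asarray(track.lat_udeg, dtype=float)
    lon = np.asarray(track.lon_udeg, dtype=float)
    if lat.size == 0:
        raise ValueError("empty track")
    if ref_point is None:
        ref_lat, ref_lon = float(lat[0]), float(lon[0])
    else:
        ref_lat, ref_lon = float(ref_point[0]), float(ref_point[1])
    mean_lat_deg = float(np.mean(lat)) * 1e-6
    y = (lat - ref_lat) * lat_scale()
    x = (lon - ref_lon) * lon_scale(mean_lat_deg)
    seg = np.hypot(np.diff(x), np.diff(y))
    dist = np.concatenate(([0.0], np.cumsum(seg)))
    return LocalPath(t=np.asarray(track.t, dtype=float), x=x, y=y, cumulative_dist=dist)


def metres_to_microdeg(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, ref_point: tuple[float, float]
) -> GeoTrack:
    """Inverse of :func:`microdeg_to_metres` (same fixed scales)."""
    ref_lat, ref_lon = float(ref_point[0]), float(ref_point[1])
    lat = ref_lat + np.asarray(y, dtype=float) / lat_scale()
    # match the forward conversion's scale: mean latitude of the resulting track
    # solved iteratively; one pass suffices because latitude varies by <1e-4 deg
    mean_lat_deg = float(np.mean(lat)) * 1e-6
    lon = ref_lon + np.asarray(x, dtype=float) / lon_scale(mean_lat_deg)
    return GeoTrack(t=np.asarray(t, dtype=float), lat_udeg=lat, lon_udeg=lon)


def path_distance(path: LocalPath) -> float:
    """Total travelled distance: sum of Euclidean segment lengths."""
    if path.x.size < 2:
        raise ValueError("need at least 2 points for a path distance")
    return float(path.cumulative_dist[-1])


def gps_speed(path: LocalPath) -> np.ndarray:
    """Per-sample resultant speed sqrt(dx/dt^2 + dy/dt^2)."""
    vx = np.gradient(path.x, path.t)
    vy = np.gradient(path.y, path.t)
    return np.hypot(vx, vy)


def _ramp_windows(v: np.ndarray, moving_threshold: float, half_width: int):
    """Sample indices around the start and end standstill-to-motion ramps.

    The ramp positions are located on the (already smoothed) speed using a
    threshold halfway between standstill and cruising level, so position
    noise does not masquerade as motion.
    """
    cruise = float(np.percentile(v, 80))
    threshold = max(moving_threshold, 0.4 * cruise)
    moving = np.flatnonzero(v > threshold)
    if moving.size == 0:
        raise ValueError("no standstill ramps: series never exceeds threshold")
    if moving[0] == 0 and moving[-1] == v.size - 1 and moving.size == v.size:
        raise ValueError("no standstill ramps: series never at standstill")
    first, last = moving[0], moving[-1]
    w1 = np.arange(max(first - half_width, 0), min(first + half_width + 1, v.size))
    w2 = np.arange(max(last - half_width, 0), min(last + half_width + 1, v.size))
    return np.union1d(w1, w2)


def align_gps_to_imu(
    path: LocalPath,
    imu_t: np.ndarray,
    imu_v: np.ndarray,
    max_offset_s: int = 30,
    moving_threshold: float = 0.1,
    ramp_half_width_s: int = 20,
    smooth_s: int = 11,
) -> int:
    """Integer-second offset of the GPS clock relative to the IMU clock.

    A noise-robust GPS speed is derived by smoothing the positions with a
    ``smooth_s``-second moving average before differencing (the rectified
    raw 1 Hz speed never drops to zero under metre-level position noise,
    so the standstill periods would be invisible in it).  The IMU speed is
    block-averaged to 1 Hz and smoothed identically.  The returned offset
    ``o`` minimises the mean squared speed difference over windows around
    the start and end ramps (standstill to motion and back).  Add ``o`` to
    GPS timestamps to place them on the IMU clock.
    """
    from scipy.ndimage import uniform_filter1d

    gps_t = np.asarray(path.t, dtype=float)
    imu_t = np.asarray(imu_t, dtype=float)
    imu_v = np.asarray(imu_v, dtype=float)
    win_n = max(1, int(smooth_s))
    xs = uniform_filter1d(path.x, size=win_n, mode="nearest")
    ys = uniform_filter1d(path.y, size=win_n, mode="nearest")
    gps_v = np.hypot(np.gradient(xs, gps_t), np.gradient(ys, gps_t))
    # 1 Hz block average of the IMU speed, smoothed with the same window
    t0 = np.floor(imu_t[0])
    sec = np.floor(imu_t - t0).astype(int)
    n_sec = sec[-1] + 1
    sums = np.bincount(sec, weights=imu_v, minlength=n_sec)
    counts = np.bincount(sec, minlength=n_sec)
    imu_1hz = uniform_filter1d(sums / np.maximum(counts, 1), size=win_n, mode="nearest")
    imu_sec_t = t0 + np.arange(n_sec) + 0.5

    win = _ramp_windows(gps_v, moving_threshold, ramp_half_width_s)
    _ramp_windows(imu_1hz, moving_threshold, ramp_half_width_s)  # validate IMU ramps exist

    best, best_cost = 0, np.inf
    for o in range(-max_offset_s, max_offset_s + 1):
        imu_at = np.interp(gps_t[win] + o, imu_sec_t, imu_1hz, left=np.nan, right=np.nan)
        ok = ~np.isnan(imu_at)
        if ok.sum() < max(3, win.size // 2):
            continue
        cost = float(np.mean((gps_v[win][ok] - imu_at[ok]) ** 2))
        if cost < best_cost:
            best, best_cost = o, cost
    if not np.isfinite(best_cost):
        raise ValueError("no overlapping ramp windows for any candidate offset")
    return best


def _crossings_x_at_y(path: LocalPath, at_y: float) -> np.ndarray:
    """x-positions where the path crosses the horizontal line y = at_y,
    linearly interpolated in y along each crossing segment."""
    y = path.y
    x = path.x
    d = y - at_y
    xs = list(x[d == 0])
    sign_change = np.flatnonzero(d[:-1] * d[1:] < 0)
    for i in sign_change:
        f = d[i] / (d[i] - d[i + 1])
        xs.append(x[i] + f * (x[i + 1] - x[i]))
    if not xs:
        raise ValueError(f"path does not cross y = {at_y:g}")
    return np.sort(np.asarray(xs))


def deviation_from_reference(path: LocalPath, reference: LocalPath, at_y: float) -> float:
    """Lateral deviation |x_path - x_reference| where both paths cross
    ``at_y``, each interpolated linearly in y.  When a closed path crosses
    the line more than once, the nearest pair of crossings is compared."""
    xa = _crossings_x_at_y(path, at_y)
    xb = _crossings_x_at_y(reference, at_y)
    diffs = np.abs(xa[:, None] - xb[None, :])
    return float(diffs.min())
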