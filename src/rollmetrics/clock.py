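"""Two-point clock synchronisation between free-running sensor clocks.

The wheel IMU (master) and the seat mat (slave) each run on their own
real-time clock; the clocks differ by an offset and a skew (rate).  At the
start and end of a recording the wheels are struck five times while
standing, producing simultaneous spikes in the wheel accelerometer and the
mat channels ("trigger pentads").  The clearest spike of each pentad gives
one (master, slave) anchor pair; the two pairs determine the affine map

    t_master = m * t_slave + dt_B + b

with skew m, begin-offset dt_B = t_Bm - t_Bs, and intercept b chosen so
that both anchors map exactly.  The remaining eight spikes serve as a
synchronisation-quality check (residual SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClockMap",
    "TriggerSet",
    "detect_triggers",
    "fit_clock_map",
    "apply_clock_map",
    "sync_residuals",
]


@dataclass(frozen=True)
class ClockMap:
    """Affine slave-to-master clock map t_m = skew_m * t_s + delta_tB + intercept_b."""

    skew_m: float
    intercept_b: float
    delta_tB: float
    anchors: tuple[float, float, float, float]  # (t_Bm, t_Bs, t_Em, t_Es)

    def __call__(self, t_slave):
        return self.skew_m * np.asarray(t_slave, dtype=float) + self.delta_tB + self.intercept_b

    def inverse(self, t_master):
        return (np.asarray(t_master, dtype=float) - self.delta_tB - self.intercept_b) / self.skew_m


@dataclass(frozen=True)
class TriggerSet:
    """Detected spike times for one pentad on one channel."""

    times: np.ndarray
    channel: str
    pentad: str  # "start" | "end"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("trigger times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def anchor(self) -> float:
        """Representative anchor time: set by detect_triggers to the
        maximum-amplitude spike of the pentad."""
        return self._anchor  # type: ignore[attr-defined]


def _find_spikes(t, x, threshold, min_separation):
    """Indices of local spike maxima above threshold, de-bounced."""
    above = np.flatnonzero(x > threshold)
    if above.size == 0:
        return np.array([], dtype=int)
    # group contiguous/nearby threshold crossings into single detections
    groups = []
    start = above[0]
    prev = above[0]
    for i in above[1:]:
        if t[i] - t[prev] > min_separation:
            groups.append((start, prev))
            start = i
        prev = i
    groups.append((start, prev))
    peaks = []
    for a, b in groups:
        seg = slice(a, b + 1)
        peaks.append(a + int(np.argmax(x[seg])))
    return np.asarray(peaks, dtype=int)


def detect_triggers(
    t: np.ndarray,
    x: np.ndarray,
    threshold_sd: float = 6.0,
    min_separation: float = 0.2,
    pentad_window: float = 60.0,
    expected: int = 5,
) -> tuple[TriggerSet, TriggerSet]:
    """Detect the start and end trigger pentads in a scalar channel.

    The spike threshold is the channel median plus ``threshold_sd`` robust
    standard deviations (1.4826 * MAD).  Detections closer than
    ``min_separation`` seconds are merged into one.  Spikes are searched in
    the first and last ``pentad_window`` seconds of the recording; the
    maximum-amplitude spike of each pentad is marked as the anchor.

    When more than ``expected`` detections fall in a window, the
    ``expected`` largest-amplitude ones are kept (the strike count per
    pentad is part of the protocol), which rejects isolated noise
    excursions past the threshold.

    Returns the (start, end) pentads.  Raises ``ValueError`` if fewer than
    two spikes are found in either window ("pentad not found").
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValueError("t and x must be 1-D arrays of equal length")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = np.std(x)
    threshold = med + threshold_sd * robust_sd
    if robust_sd == 0:
        raise ValueError("pentad not found: flat channel")

    out = []
    for pentad, mask in (
        ("start", t <= t[0] + pentad_window),
        ("end", t >= t[-1] - pentad_window),
    ):
        idx = np.flatnonzero(mask)
        peaks = _find_spikes(t[idx], x[idx], threshold, min_separation)
        if peaks.size < 2:
            raise ValueError(f"pentad not found: {peaks.size} spike(s) in {pentad} window")
        times = t[idx][peaks]
        amps = x[idx][peaks]
        if times.size > expected:
            top = np.sort(np.argsort(amps)[-expected:])
            times, amps = times[top], amps[top]
        ts = TriggerSet(times=times, channel="", pentad=pentad)
        object.__setattr__(ts, "_anchor", float(times[np.argmax(amps)]))
        out.append(ts)
    return out[0], out[1]


def fit_clock_map(t_Bm: float, t_Bs: float, t_Em: float, t_Es: float) -> ClockMap:
    """Fit the affine slave-to-master map from two anchor pairs.

    skew m = (t_Bm - t_Em) / (t_Bs - t_Es); dt_B = t_Bm - t_Bs; the
    intercept b = t_Bs * (1 - m) makes both anchors map exactly.
    """
    if t_Bs == t_Es:
        raise ValueError("degenerate anchors: coincident slave anchor times")
    if not t_Bm < t_Em:
        raise ValueError("master anchors must be ordered t_Bm < t_Em")
    m = (t_Bm - t_Em) / (t_Bs - t_Es)
    if m <= 0:
        raise ValueError("non-positive skew: slave anchors reversed relative to master")
    delta_tB = t_Bm - t_Bs
    b = t_Bm - delta_tB - m * t_Bs  # == t_Bs * (1 - m)
    return ClockMap(skew_m=m, intercept_b=b, delta_tB=delta_tB, anchors=(t_Bm, t_Bs, t_Em, t_Es))


def apply_clock_map(clock_map: ClockMap, t_slave) -> np.ndarray:
    """Map slave timestamps onto the master clock (affine, order-preserving)."""
    return clock_map(t_slave)


def sync_residuals(spike_pairs) -> float:
    """SD of (master - mapped slave) over all trigger spikes.

    ``spike_pairs`` is a sequence of (t_master, t_slave_mapped) pairs and
    must contain at least two pairs beyond the two anchors (>= 4 total);
    the anchors contribute zero residual by construction.
    """
    pairs = np.asarray(list(spike_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 4:
        raise ValueError("need at least 2 spike pairs beyond the two anchors")
    resid = pairs[:, 0] - pairs[:, 1]
    return float(np.std(resid, ddof=1))
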