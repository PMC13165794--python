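"""Synthetic-run generator with known ground truth.

Generates complete multi-sensor recordings of the 13-section course by
inverting the processing chain: a ground-truth speed/COP trajectory is
drawn from the course statistics, wheel angular rates are derived by
inverting the cambered differential-drive model, seat-mat voltages by
inverting the piezoresistive sensor model, and GPS fixes by projecting the
true path into micro-degrees with receiver noise.

Speed model.  At distance d along the course,

    v(d) = speed_scale * [ lam * mu_v(sec d)
                           + (1 - lam) * (v_bar + a(t)) ]     (floor 0.1 m/s)

where lam is the participant's route-compliance weight, mu_v the section
mean speed, v_bar the course-wide mean speed and a(t) the participant's
individual AR(1) speed wander (phi = 0.98 at 100 Hz, stationary SD equal
to the local section speed SD).  Route-driven participants (high lam)
track the section means tightly; individualistic ones (low lam) wander
around the course average.  With lam = 1 and the noise amplitude zero,
the speed is exactly the section mean everywhere, so the full pipeline
must reproduce the course table.

COPx/COPy follow the same mixing around their section means.  Street
corners add yaw-rate episodes (smooth 90-degree heading changes over a
short arc) with a configurable speed reduction.

Clocks.  The mat samples at the same physical instants as the master but
records timestamps through its own distorted clock,
t_rec = (t_master - offset)/skew, so trigger events lie exactly on both
sample grids and a two-point fit can recover the distortion to machine
precision.  Optional timestamp jitter is applied to the four non-anchor
spikes of each pentad (the anchor spike is the "clearest and highest" one
and is modelled clean).

All randomness derives from a single integer seed through named
SeedSequence spawn keys, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .course import CourseDefinition, build_course
from .gps import GeoTrack, lat_scale, lon_scale
from .kinematics import WheelchairGeometry
from .seat_mat import MatGeometry, CELL_AREA_M2, R_REF_OHM, V_SUPPLY, PRESSURE_RANGE_PA

__all__ = [
    "SensorModel",
    "ClockDistortion",
    "ParticipantProfile",
    "SimulationOptions",
    "RawRunData",
    "simulate_run",
    "simulate_aligned_profiles",
    "allocate_mat_forces",
    "write_run",
    "read_run",
    "DEFAULT_PROFILES",
]

# Local origin for synthetic GPS tracks (suburban Melbourne), micro-degrees.
GPS_REF_UDEG = (-37_820_000.0, 145_030_000.0)


@dataclass(frozen=True)
class SensorModel:
    """Piezoresistive cell response: pressure = c1*G + c2*G**2 (G in siemens).

    Conductance rises roughly linearly with pressure (classic FSR
    behaviour) with a mild quadratic correction; the law is exactly
    invertible, and lies inside the model class of the 6th-order
    calibration fit, so a clean calibration recovers it exactly.
    Defaults give ~30 kOhm at 200 Pa and ~50 Ohm at 0.33 MPa.
    """

    c1: float = 6.0e6
    c2: float = 5.0e8
    r_ref: float = R_REF_OHM
    v_supply: float = V_SUPPLY
    cell_area: float = CELL_AREA_M2

    def conductance_to_pressure(self, g):
        g = np.asarray(g, dtype=float)
        return self.c1 * g + self.c2 * g**2

    def pressure_to_conductance(self, p):
        p = np.asarray(p, dtype=float)
        return (-self.c1 + np.sqrt(self.c1**2 + 4.0 * self.c2 * p)) / (2.0 * self.c2)

    def force_to_voltage(self, force_n):
        """Cell force (N) -> divider voltage (V); forces below the 200 Pa
        calibration floor read as the floor (sensor contact threshold)."""
        p = np.asarray(force_n, dtype=float) / self.cell_area
        p = np.clip(p, *PRESSURE_RANGE_PA)
        g = self.pressure_to_conductance(p)
        return self.v_supply * g * self.r_ref / (1.0 + g * self.r_ref)

    def calibration_cycles(
        self, n_cycles: int = 20, seed: int | None = None, noise_rel: float = 0.0
    ) -> np.ndarray:
        """Simulated loading-cycle peaks: (peak pressure Pa, peak conductance S).

        Pressures are log-spaced over the sensor's working range; optional
        relative noise perturbs the measured conductance.
        """
        p = np.geomspace(*PRESSURE_RANGE_PA, n_cycles)
        g = self.pressure_to_conductance(p)
        if noise_rel > 0:
            rng = np.random.default_rng(seed)
            g = g * (1.0 + noise_rel * rng.standard_normal(n_cycles))
        return np.column_stack([p, g])


@dataclass(frozen=True)
class ClockDistortion:
    """Slave clock model: recorded slave time = (t_master - offset)/skew."""

    skew: float = 1.0005
    offset: float = -3.2
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.skew <= 0:
            raise ValueError("skew must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def master_to_slave(self, t_m):
        return (np.asarray(t_m, dtype=float) - self.offset) / self.skew

    def slave_to_master(self, t_s):
        return self.skew * np.asarray(t_s, dtype=float) + self.offset


@dataclass(frozen=True)
class ParticipantProfile:
    """Participant behaviour knobs for the generator.

    ``compliance_lambda`` weighs the course-driven speed/COP component
    against the individual one; ``cop_offset_x`` emulates off-centre
    seating (mm, + right)."""

    participant_id: str
    compliance_lambda: float = 0.7
    speed_scale: float = 1.0
    cop_offset_x: float = 0.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.compliance_lambda <= 1.0:
            raise ValueError("compliance_lambda must be in [0, 1]")
        if self.speed_scale <= 0:
            raise ValueError("speed_scale must be > 0")


# Default 7-participant cohort: the compliance weights span the
# route-driven vs individualistic spectrum observed in the study cohort.
DEFAULT_PROFILES: tuple[ParticipantProfile, ...] = tuple(
    ParticipantProfile(participant_id=f"P{i + 1}", compliance_lambda=lam, noise_seed=i)
    for i, lam in enumerate([0.2, 0.5, 0.5, 0.5, 0.9, 0.8, 0.5])
)


@dataclass(frozen=True)
class SimulationOptions:
    """Generator noise levels and protocol details.

    Defaults are the realistic study conditions; :meth:`noise_free` is the
    analytic limiting configuration used by exactness round-trip checks.
    """

    dt: float = 0.01                  # 100 Hz
    individual_noise: float = 1.0     # scale on participant AR components
    ar_phi_time: float = 0.98         # individual AR(1) coefficient per sample
    total_seat_force: float = 600.0   # N
    turn_slowdown: float = 0.25       # fractional speed dip in turns
    turn_arc_m: float = 3.0           # heading-change arc length (m)
    ramp_s: float = 3.0               # start-up speed ramp duration (s)
    end_ramp_m: float = 2.0           # deceleration distance before stop (m)
    pad_s: float = 12.0               # standstill padding at each end (s)
    v_floor: float = 0.1              # minimum moving speed (m/s)
    gps_noise_sd: float = 2.0         # m per axis
    gps_clock_offset_s: int = 0       # planted GPS receiver clock offset
    multipath: tuple[float, float, float, float] | None = None  # (dx, dy, d0, d1)
    spike_spacing_s: float = 0.5
    spike_force_n: float = 300.0      # per-cell trigger impulse
    accel_noise_sd: float = 0.05
    sensor: SensorModel = field(default_factory=SensorModel)

    @classmethod
    def noise_free(cls, **overrides) -> "SimulationOptions":
        """All noise, ramps and turn slow-downs off (exactness limit)."""
        base = dict(
            individual_noise=0.0,
            turn_slowdown=0.0,
            ramp_s=0.0,
            end_ramp_m=0.0,
            gps_noise_sd=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class RawRunData:
    """One synthetic (or recorded) run with its ground truth."""

    t: np.ndarray                # master clock, s, 100 Hz
    gyro_left: np.ndarray        # deg/s
    gyro_right: np.ndarray      # deg/s
    wheel_accel: np.ndarray      # trigger channel (arbitrary units)
    mat_t_slave: np.ndarray      # slave clock, s
    mat_voltages: np.ndarray     # (n, 16) V
    gps: GeoTrack
    truth: pd.DataFrame          # t_s, v_mps, dist_m, copx_mm, copy_mm, section
    meta: dict

    @property
    def n_samples(self) -> int:
        return self.t.size


def _unit_ar(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1) with unit variance."""
    innov = rng.standard_normal(n) * np.sqrt(1.0 - phi**2)
    innov[0] = rng.standard_normal()
    return lfilter([1.0], [1.0, -phi], innov)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _course_lookups(course: CourseDefinition, options: SimulationOptions, res: float):
    """Fine distance-indexed lookup tables shared by the whole cohort."""
    L = course.total_length
    n = int(np.ceil(L / res)) + 2
    d = np.arange(n) * res
    sec_idx = np.clip(np.searchsorted(course.boundaries, d, side="right") - 1, 0, course.n_sections - 1)
    mu_v = course.means("v")[sec_idx]
    sd_v = course.sds("v")[sec_idx]
    mu_x = course.means("copx")[sec_idx]
    sd_x = course.sds("copx")[sec_idx]
    mu_y = course.means("copy")[sec_idx]
    sd_y = course.sds("copy")[sec_idx]

    # turn slow-down and heading profiles
    slow = np.zeros_like(d)
    heading = np.zeros_like(d)
    arc = options.turn_arc_m
    for b, dh in sorted(course.turns.items()):
        u = (d - (b - arc / 2.0)) / arc
        heading = heading + np.radians(dh) * _smoothstep(u)
        bump = np.clip(1.0 - np.abs(d - b) / (1.5 * arc), 0.0, 1.0)
        slow = np.maximum(slow, options.turn_slowdown * bump)
    return {
        "res": res, "d": d, "sec_idx": sec_idx,
        "mu_v": mu_v, "sd_v": sd_v, "mu_x": mu_x, "sd_x": sd_x,
        "mu_y": mu_y, "sd_y": sd_y,
        "slow": slow, "heading": heading,
        "v_bar": float(np.sum(course.means("v") * np.diff(course.boundaries)) / L),
    }


def allocate_mat_forces(
    copx: np.ndarray,
    copy_: np.ndarray,
    total: float,
    geometry: MatGeometry | None = None,
) -> np.ndarray:
    """Distribute a total seat force over the mat so the force-weighted
    centroid equals (copx, copy) exactly (bilinear, two cells per axis).

    Requested COP outside the centroid hull is clipped to 5 mm inside it.
    Returns an (n, 16) array of non-negative cell forces.
    """
    if geometry is None:
        geometry = MatGeometry()
    xs, ys = geometry.col_x, geometry.row_y
    cx = np.clip(np.asarray(copx, dtype=float), xs[0] + 5.0, xs[-1] - 5.0)
    cy = np.clip(np.asarray(copy_, dtype=float), ys[0] + 5.0, ys[-1] - 5.0)
    ix = np.clip(np.searchsorted(xs, cx) - 1, 0, xs.size - 2)
    iy = np.clip(np.searchsorted(ys, cy) - 1, 0, ys.size - 2)
    fx = (cx - xs[ix]) / (xs[ix + 1] - xs[ix])
    fy = (cy - ys[iy]) / (ys[iy + 1] - ys[iy])
    n = cx.size
    forces = np.zeros((n, geometry.n_cells))
    rows = np.arange(n)
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            cell = (iy + dy) * geometry.n_cols + (ix + dx)
            forces[rows, cell] += total * wx * wy
    return forces


def _spike_times(t0: float, n: int, spacing: float) -> np.ndarray:
    return t0 + spacing * np.arange(n)

# relative spike amplitudes within a pentad; the middle spike is the
# clearest/highest one and serves as the anchor
_PENTAD_AMPS = np.array([1.0, 1.1, 1.5, 1.2, 0.9])
ANCHOR_INDEX = 2


def simulate_run(
    course: CourseDefinition | None = None,
    profile: ParticipantProfile | None = None,
    geometry: WheelchairGeometry | None = None,
    distortion: ClockDistortion | None = None,
    seed: int = 0,
    options: SimulationOptions | None = None,
) -> RawRunData:
    """Simulate one complete instrumented run over the course."""
    if course is None:
        course = build_course()
    if profile is None:
        profile = DEFAULT_PROFILES[0]
    if geometry is None:
        geometry = WheelchairGeometry()
    if distortion is None:
        distortion = ClockDistortion()
    if options is None:
        options = SimulationOptions()

    dt = options.dt
    res = 0.01
    lut = _course_lookups(course, options, res)
    L = course.total_length
    lam = profile.compliance_lambda
    v_bar = lut["v_bar"]

    ss = np.random.SeedSequence(seed, spawn_key=(1, profile.noise_seed))
    rng_v, rng_x, rng_y, rng_gps, rng_acc, rng_jit = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    # generous sample budget: slowest plausible traversal plus padding
    t_total_est = L / (0.35 * v_bar * profile.speed_scale) + 2 * options.pad_s + 60.0
    n_max = int(t_total_est / dt)
    a_ind = _unit_ar(rng_v, n_max, options.ar_phi_time) * options.individual_noise

    n_pad = int(round(options.pad_s / dt))
    course_v = lut["mu_v"]
    slow = lut["slow"]
    sd_v_lut = lut["sd_v"]
    scale = profile.speed_scale
    n_ramp = int(round(options.ramp_s / dt))
    end_ramp = options.end_ramp_m
    floor = options.v_floor

    v_list = [0.0] * n_pad
    d_list = [0.0] * n_pad
    d = 0.0
    k = 0
    inv_res = 1.0 / res
    while d < L:
        if n_pad + k >= n_max:
            raise RuntimeError("simulation exceeded its sample budget")
        i = int(d * inv_res)
        ind = v_bar + a_ind[k] * sd_v_lut[i]
        v = scale * (lam * course_v[i] + (1.0 - lam) * ind)
        v *= 1.0 - slow[i]
        if k < n_ramp:
            v *= (k + 1.0) / n_ramp
        rem = L - d
        if end_ramp > 0 and rem < end_ramp:
            v *= max(rem / end_ramp, 0.3)
        v = max(v, floor)
        v_list.append(v)
        d_list.append(d)
        d += v * dt
        k += 1
    v_arr = np.asarray(v_list + [0.0] * n_pad)
    d_int = np.asarray(d_list + [d] * n_pad)  # generator-internal distance
    n = v_arr.size
    t = np.arange(n) * dt

    # ground-truth distance exactly as the pipeline integrates it
    dist = np.concatenate(([0.0], cumulative_trapezoid(v_arr, t)))

    # heading / yaw from the turn profile, indexed by internal distance
    idx = np.minimum((d_int * inv_res).astype(int), lut["heading"].size - 1)
    heading = lut["heading"][idx]
    yaw = np.concatenate(([0.0], np.diff(heading))) / dt  # rad/s

    # invert the differential-drive model
    r_eff = geometry.effective_radius
    w_g = geometry.ground_track
    wl = np.degrees((v_arr - yaw * w_g / 2.0) / r_eff)
    wr = np.degrees((v_arr + yaw * w_g / 2.0) / r_eff)

    # COP ground truth: same compliance mixing as the speed channel
    weights = np.diff(course.boundaries) / L
    x_bar = float(np.sum(course.means("copx") * weights))
    y_bar = float(np.sum(course.means("copy") * weights))
    zx = _unit_ar(rng_x, n, options.ar_phi_time) * options.individual_noise
    zy = _unit_ar(rng_y, n, options.ar_phi_time) * options.individual_noise
    copx = (
        lam * lut["mu_x"][idx]
        + (1.0 - lam) * (x_bar + zx * lut["sd_x"][idx])
        + profile.cop_offset_x
    )
    copy_ = lam * lut["mu_y"][idx] + (1.0 - lam) * (y_bar + zy * lut["sd_y"][idx])
    geometry_mat = MatGeometry()
    copx = np.clip(copx, geometry_mat.col_x[0] + 5.0, geometry_mat.col_x[-1] - 5.0)
    copy_ = np.clip(copy_, geometry_mat.row_y[0] + 5.0, geometry_mat.row_y[-1] - 5.0)
    forces = allocate_mat_forces(copx, copy_, options.total_seat_force, geometry_mat)

    # trigger pentads: 5 strikes at each end, during standstill, aligned on
    # the 100 Hz master grid
    t_start_pentad = _spike_times(2.0, 5, options.spike_spacing_s)
    t_end_pentad = _spike_times(t[-1] - options.pad_s + 2.0, 5, options.spike_spacing_s)
    t_end_pentad = np.round(t_end_pentad / dt) * dt
    spike_master = np.concatenate([t_start_pentad, t_end_pentad])
    spike_amps = np.tile(_PENTAD_AMPS, 2)

    accel = rng_acc.standard_normal(n) * options.accel_noise_sd
    base_amp = 10.0 * np.quantile(np.abs(accel), 0.99)
    mat_spike_idx = []
    for j, (tm, amp) in enumerate(zip(spike_master, spike_amps)):
        ki = int(round(tm / dt))
        accel[ki] += base_amp * amp
        kj = ki
        if distortion.jitter_sd > 0 and (j % 5) != ANCHOR_INDEX:
            kj = ki + int(round(rng_jit.normal(0.0, distortion.jitter_sd) / dt))
        mat_spike_idx.append(int(np.clip(kj, 0, n - 1)))
    for j, kj in enumerate(mat_spike_idx):
        forces[kj, :] += options.spike_force_n * spike_amps[j]

    voltages = options.sensor.force_to_voltage(forces)
    mat_t_slave = distortion.master_to_slave(t)

    # GPS: 1 Hz snapshots of the integrated true path
    x = np.concatenate(([0.0], cumulative_trapezoid(v_arr * np.cos(heading), t)))
    y = np.concatenate(([0.0], cumulative_trapezoid(v_arr * np.sin(heading), t)))
    sec_samples = np.arange(0, int(t[-1]) + 1)
    gi = np.minimum((sec_samples / dt).astype(int), n - 1)
    gx = x[gi] + rng_gps.standard_normal(sec_samples.size) * options.gps_noise_sd
    gy = y[gi] + rng_gps.standard_normal(sec_samples.size) * options.gps_noise_sd
    if options.multipath is not None:
        mdx, mdy, d0, d1 = options.multipath
        in_win = (dist[gi] >= d0) & (dist[gi] < d1)
        gx = gx + mdx * in_win
        gy = gy + mdy * in_win
    ref_lat_deg = GPS_REF_UDEG[0] * 1e-6
    lat_udeg = GPS_REF_UDEG[0] + gy / lat_scale()
    lon_udeg = GPS_REF_UDEG[1] + gx / lon_scale(ref_lat_deg)
    gps = GeoTrack(
        t=sec_samples.astype(float) + options.gps_clock_offset_s,
        lat_udeg=lat_udeg,
        lon_udeg=lon_udeg,
    )

    section = np.clip(
        np.searchsorted(course.boundaries, dist, side="right"), 1, course.n_sections
    )
    truth = pd.DataFrame(
        {
            "t_s": t,
            "v_mps": v_arr,
            "dist_m": dist,
            "copx_mm": copx,
            "copy_mm": copy_,
            "section": section,
        }
    )
    meta = {
        "profile": asdict(profile),
        "distortion": {"skew": distortion.skew, "offset": distortion.offset,
                       "jitter_sd": distortion.jitter_sd},
        "geometry": asdict(geometry),
        "seed": seed,
        "spike_times_master": spike_master.tolist(),
        "anchor_times_master": [float(spike_master[ANCHOR_INDEX]),
                                float(spike_master[5 + ANCHOR_INDEX])],
        "section_means": {
            "v": course.means("v").tolist(),
            "copx": course.means("copx").tolist(),
            "copy": course.means("copy").tolist(),
        },
        "total_seat_force": options.total_seat_force,
    }
    return RawRunData(
        t=t,
        gyro_left=wl,
        gyro_right=wr,
        wheel_accel=accel,
        mat_t_slave=mat_t_slave,
        mat_voltages=voltages,
        gps=gps,
        truth=truth,
        meta=meta,
    )


def simulate_aligned_profiles(
    course: CourseDefinition | None = None,
    profiles=None,
    seed: int = 0,
    grid_step: float = 1.0,
    individual_noise: float = 1.0,
    noise_corr_m: float = 1.0,
):
    """Fast distance-domain generator for cohort statistics.

    Draws per-participant speed/COP profiles directly on the analysis
    distance grid using the same compliance-mixing model as
    :func:`simulate_run`; the individual AR(1) wander is expressed in the
    distance domain (correlation length ``noise_corr_m``, matching the
    ~0.6 m correlation of the time-domain process at typical speeds) and
    the sensor chain is skipped.  Returns a list of
    :class:`~rollmetrics.sections.AlignedRun`.
    """
    from .sections import AlignedRun, assign_sections, make_distance_grid

    if course is None:
        course = build_course()
    if profiles is None:
        profiles = DEFAULT_PROFILES
    grid = make_distance_grid(course.total_length, grid_step)
    section = assign_sections(grid, course.boundaries)
    phi = np.exp(-grid_step / noise_corr_m)
    sec0 = section - 1
    mu = {p: course.means(p)[sec0] for p in ("v", "copx", "copy")}
    sd = {p: course.sds(p)[sec0] for p in ("v", "copx", "copy")}
    weights = np.diff(course.boundaries) / course.total_length
    bar = {p: float(np.sum(course.means(p) * weights)) for p in mu}

    runs = []
    for prof in profiles:
        lam = prof.compliance_lambda
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1, prof.noise_seed))
        )
        eta = {p: _unit_ar(rng, grid.size, phi) * sd[p] * individual_noise for p in mu}
        v = prof.speed_scale * (
            lam * mu["v"] + (1.0 - lam) * (bar["v"] + eta["v"])
        )
        v = np.maximum(v, 0.1)
        copx = lam * mu["copx"] + (1.0 - lam) * (bar["copx"] + eta["copx"]) + prof.cop_offset_x
        copy_ = lam * mu["copy"] + (1.0 - lam) * (bar["copy"] + eta["copy"])
        runs.append(
            AlignedRun(dist=grid, v=v, copx=copx, copy_=copy_, section=section,
                       participant_id=prof.participant_id)
        )
    return runs


_CSV_FILES = ("gyro.csv", "mat.csv", "gps.csv", "truth.csv")


def write_run(run: RawRunData, directory: str | Path, overwrite: bool = False) -> list[Path]:
    """Persist a run as gyro.csv, mat.csv, gps.csv, truth.csv + meta.json."""
    if run.n_samples == 0:
        raise ValueError("no samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / name for name in _CSV_FILES] + [directory / "meta.json"]
    if not overwrite:
        existing = [p.name for p in paths if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite {existing}; pass overwrite=True")

    gyro = pd.DataFrame(
        {
            "t_s": run.t,
            "omega_left_dps": run.gyro_left,
            "omega_right_dps": run.gyro_right,
            "accel_trigger": run.wheel_accel,
        }
    )
    mat = pd.DataFrame(
        run.mat_voltages, columns=[f"v{i + 1:02d}" for i in range(run.mat_voltages.shape[1])]
    )
    mat.insert(0, "t_slave_s", run.mat_t_slave)
    gps = pd.DataFrame(
        {"t_s": run.gps.t, "lat_udeg": run.gps.lat_udeg, "lon_udeg": run.gps.lon_udeg}
    )
    gyro.to_csv(paths[0], index=False)
    mat.to_csv(paths[1], index=False)
    gps.to_csv(paths[2], index=False)
    run.truth.to_csv(paths[3], index=False)
    paths[4].write_text(json.dumps(run.meta, indent=1))
    return paths


def read_run(directory: str | Path) -> RawRunData:
    """Read a run written by :func:`write_run`."""
    directory = Path(directory)
    # round_trip parsing: the CSVs are the archival format, values must
    # survive write/read without 1-ulp drift
    kw = {"float_precision": "round_trip"}
    gyro = pd.read_csv(directory / "gyro.csv", **kw)
    mat = pd.read_csv(directory / "mat.csv", **kw)
    gps = pd.read_csv(directory / "gps.csv", **kw)
    truth = pd.read_csv(directory / "truth.csv", **kw)
    meta = json.loads((directory / "meta.json").read_text())
    return RawRunData(
        t=gyro["t_s"].to_numpy(),
        gyro_left=gyro["omega_left_dps"].to_numpy(),
        gyro_right=gyro["omega_right_dps"].to_numpy(),
        wheel_accel=gyro["accel_trigger"].to_numpy(),
        mat_t_slave=mat["t_slave_s"].to_numpy(),
        mat_voltages=mat.iloc[:, 1:].to_numpy(),
        gps=GeoTrack(
            t=gps["t_s"].to_numpy(),
            lat_udeg=gps["lat_udeg"].to_numpy(),
            lon_udeg=gps["lon_udeg"].to_numpy(),
        ),
        truth=truth,
        meta=meta,
    )
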