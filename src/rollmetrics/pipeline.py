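"""End-to-end orchestration: raw sensor streams to cohort report.

Stage order per run: clock sync (trigger pentads -> affine mat clock map)
-> wheel kinematics (speed/distance) -> GPS (local path, crude speed,
clock offset) -> seat-mat COP (calibration fit, voltages -> forces ->
COP) -> synchorisation onto the distance grid.  Cohort stages: mean/SD
profiles over distance, per-parameter effect-size networks, and the
route-compliance report.

Every stage logs its name, key parameters and row counts; a failure is
re-raised as :class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clock, compliance, gps as gps_mod, seat_mat
from .course import CourseDefinition, build_course
from .kinematics import DistanceCalibration, WheelchairGeometry, frame_kinematics, apply_correction
from .sections import AlignedRun, align_run, compare_sections, effect_network, section_summary
from .simulate import RawRunData, SensorModel, read_run

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "ProcessedRun",
    "RunReport",
    "CohortReport",
    "process_run",
    "run_pipeline",
    "cohort_report",
]

log = logging.getLogger("rollmetrics")

MOVING_THRESHOLD = 0.1  # m/s, start/end of the travelled portion
FORCE_FLOOR_TOLERANCE = 1.05  # cells within 5 % of the 200 Pa floor read as unloaded


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, source: Exception):
        super().__init__(f"stage '{stage}' failed: {source}")
        self.stage = stage
        self.source = source


@dataclass
class PipelineConfig:
    course: CourseDefinition = field(default_factory=build_course)
    geometry: WheelchairGeometry = field(default_factory=WheelchairGeometry)
    sensor: SensorModel = field(default_factory=SensorModel)
    grid_step: float = 1.0
    cop_smooth_m: float = 4.0
    alpha: float = 0.05
    effect_floor: float = 0.8
    effect_cap: float = 2.0
    distance_calibration: DistanceCalibration | None = None
    calibration_cycles: int = 20
    trigger_threshold_sd: float = 6.0
    trigger_min_separation: float = 0.2

    def __post_init__(self) -> None:
        if self.effect_cap <= self.effect_floor:
            raise ValueError("effect cap must exceed the floor")
        if self.grid_step <= 0 or self.alpha <= 0:
            raise ValueError("grid_step and alpha must be positive")


@dataclass
class RunReport:
    participant_id: str
    total_distance_m: float
    duration_s: float
    mean_speed_mps: float
    gps_path_distance_m: float
    gps_clock_offset_s: int | None
    clock_skew: float
    clock_offset_s: float
    sync_residual_sd_s: float
    section_table: pd.DataFrame


@dataclass
class ProcessedRun:
    aligned: AlignedRun
    report: RunReport
    clock_map: clock.ClockMap
    cop: seat_mat.CopSeries


@dataclass
class CohortReport:
    dist: np.ndarray
    mean_profiles: dict[str, np.ndarray]
    sd_profiles: dict[str, np.ndarray]
    networks: dict[str, list]
    compliance: compliance.ComplianceReport | None  # None below 3 runs


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, e) from e
            return out

        return wrapped

    return deco


@_stage("clock_sync")
def _sync_stage(run: RawRunData, config: PipelineConfig):
    mat_sum = run.mat_voltages.sum(axis=1)
    acc_start, acc_end = clock.detect_triggers(
        run.t, np.abs(run.wheel_accel),
        threshold_sd=config.trigger_threshold_sd,
        min_separation=config.trigger_min_separation,
    )
    mat_start, mat_end = clock.detect_triggers(
        run.mat_t_slave, mat_sum,
        threshold_sd=config.trigger_threshold_sd,
        min_separation=config.trigger_min_separation,
    )
    cmap = clock.fit_clock_map(
        acc_start.anchor, mat_start.anchor, acc_end.anchor, mat_end.anchor
    )
    pairs = []
    for acc_set, mat_set in ((acc_start, mat_start), (acc_end, mat_end)):
        k = min(acc_set.times.size, mat_set.times.size)
        mapped = clock.apply_clock_map(cmap, mat_set.times[:k])
        pairs.extend(zip(acc_set.times[:k], mapped))
    resid_sd = clock.sync_residuals(pairs) if len(pairs) >= 4 else float("nan")
    mat_t_master = clock.apply_clock_map(cmap, run.mat_t_slave)
    log.info("clock_sync: skew=%.9f offset=%.4f s residual SD=%.4f s",
             cmap.skew_m, cmap.delta_tB + cmap.intercept_b, resid_sd)
    return cmap, mat_t_master, resid_sd


@_stage("kinematics")
def _kinematics_stage(run: RawRunData, config: PipelineConfig):
    kin = frame_kinematics(run.t, run.gyro_left, run.gyro_right, config.geometry)
    if config.distance_calibration is not None:
        kin = apply_correction(kin, config.distance_calibration)
    log.info("kinematics: %d samples, distance %.1f m", kin.t.size, kin.dist[-1])
    return kin


@_stage("gps")
def _gps_stage(run: RawRunData, kin, config: PipelineConfig):
    path = gps_mod.microdeg_to_metres(run.gps)
    path_dist = gps_mod.path_distance(path)
    speed = gps_mod.gps_speed(path)
    try:
        offset = gps_mod.align_gps_to_imu(path, kin.t, kin.v)
    except ValueError:
        offset = None
    log.info("gps: path %.1f m, clock offset %s s", path_dist, offset)
    return path, path_dist, offset


@_stage("seat_mat")
def _cop_stage(run: RawRunData, mat_t_master: np.ndarray, config: PipelineConfig):
    curve = seat_mat.fit_calibration(
        config.sensor.calibration_cycles(config.calibration_cycles)
    )
    n_cells = run.mat_voltages.shape[1]
    forces = np.column_stack(
        [seat_mat.voltage_to_force(run.mat_voltages[:, c], curve) for c in range(n_cells)]
    )
    # readings pinned at the calibration floor are indistinguishable from
    # an unloaded cell; tare them to zero before the centroid
    floor_force = seat_mat.PRESSURE_RANGE_PA[0] * config.sensor.cell_area
    forces = np.where(forces <= floor_force * FORCE_FLOOR_TOLERANCE, 0.0, forces)
    series = seat_mat.cop_series(mat_t_master, forces)
    log.info("seat_mat: %d frames, %d zero-force gaps",
             series.t.size, int(np.sum(series.total_force == 0)))
    return series


@_stage("synchorise")
def _align_stage(run: RawRunData, kin, cop: seat_mat.CopSeries, config: PipelineConfig,
                 participant_id: str):
    return align_run(
        kin.t, kin.v, kin.dist, cop.t, cop.copx, cop.copy_,
        config.course, grid_step=config.grid_step, cop_smooth_m=config.cop_smooth_m,
        participant_id=participant_id,
    )


def process_run(run: RawRunData | str | Path, config: PipelineConfig | None = None) -> ProcessedRun:
    """Process one raw run through every per-run stage."""
    if config is None:
        config = PipelineConfig()
    if not isinstance(run, RawRunData):
        directory = Path(run)
        for fname, stage in (
            ("gyro.csv", "kinematics"),
            ("mat.csv", "seat_mat"),
            ("gps.csv", "gps"),
        ):
            if not (directory / fname).exists():
                raise PipelineStageError(
                    stage, FileNotFoundError(f"{directory / fname} is missing")
                )
        run = read_run(directory)
    participant_id = str(run.meta.get("profile", {}).get("participant_id", ""))

    cmap, mat_t_master, resid_sd = _sync_stage(run, config)
    kin = _kinematics_stage(run, config)
    path, path_dist, gps_offset = _gps_stage(run, kin, config)
    cop = _cop_stage(run, mat_t_master, config)
    aligned = _align_stage(run, kin, cop, config, participant_id)

    moving = np.flatnonzero(kin.v > MOVING_THRESHOLD * 0.999)
    if moving.size:
        duration = float(kin.t[moving[-1]] - kin.t[moving[0]])
    else:
        duration = float(kin.t[-1] - kin.t[0])
    total = float(kin.dist[-1])
    report = RunReport(
        participant_id=participant_id,
        total_distance_m=total,
        duration_s=duration,
        mean_speed_mps=total / duration if duration > 0 else float("nan"),
        gps_path_distance_m=path_dist,
        gps_clock_offset_s=gps_offset,
        clock_skew=cmap.skew_m,
        clock_offset_s=cmap.delta_tB + cmap.intercept_b,
        sync_residual_sd_s=resid_sd,
        section_table=section_summary(aligned),
    )
    return ProcessedRun(aligned=aligned, report=report, clock_map=cmap, cop=cop)


def cohort_report(aligned_runs: list[AlignedRun], config: PipelineConfig | None = None) -> CohortReport:
    """Cohort summaries over >= 2 distance-aligned runs."""
    if config is None:
        config = PipelineConfig()
    if len(aligned_runs) < 2:
        raise ValueError("need at least 2 runs for a cohort report")
    grids = {r.dist.size for r in aligned_runs}
    if len(grids) != 1 or any(
        not np.allclose(r.dist, aligned_runs[0].dist) for r in aligned_runs
    ):
        raise ValueError("aligned runs are on different distance grids")

    mean_profiles, sd_profiles, networks = {}, {}, {}
    for p in ("v", "copx", "copy"):
        stack = np.array([r.values(p) for r in aligned_runs])
        mean_profiles[p] = stack.mean(axis=0)
        sd_profiles[p] = stack.std(axis=0, ddof=1)
        comps = [compare_sections(r, p, alpha=config.alpha)[2] for r in aligned_runs]
        networks[p] = effect_network(
            comps, d_floor=config.effect_floor, d_cap=config.effect_cap
        )
    report = compliance.compliance_report(aligned_runs) if len(aligned_runs) >= 3 else None
    return CohortReport(
        dist=aligned_runs[0].dist,
        mean_profiles=mean_profiles,
        sd_profiles=sd_profiles,
        networks=networks,
        compliance=report,
    )


def run_pipeline(runs, config: PipelineConfig | None = None):
    """Process a list of runs (RawRunData or directories) and, with >= 2
    runs, build the cohort report.  Returns (processed_runs, cohort)."""
    if config is None:
        config = PipelineConfig()
    processed = [process_run(r, config) for r in runs]
    cohort = None
    if len(processed) >= 2:
        cohort = cohort_report([p.aligned for p in processed], config)
    return processed, cohort
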