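"""Pressure-sensing seat mat: calibration, forces, and centre of pressure.

The mat is a 4 x 4 array of piezoresistive cells (50 x 65 mm each, 20 mm
gaps, 300 x 350 mm overall).  Each cell is read through a voltage divider
with a 70 ohm reference resistor on the low side; the measured voltage v
gives the sensor conductance

    G = v / (R_ref * (V_supply - v)).

A per-sensor calibration curve (6th-order polynomial, conductance ->
pressure, fitted to ~20 loading-cycle peaks between 200 Pa and 0.33 MPa)
converts conductance to pressure; force is pressure times the nominal
cell area (3.25e-3 m^2).

The centre of pressure (COP) is the force-weighted average of the cell
centroid coordinates.  Axis convention: +x right, +y forward, origin at
the mat centre; COPy is negative when the load sits rearward of centre.
Frames with zero total force yield a NaN-flagged COP (a gap, not an
error), e.g. during transient unloading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MatGeometry",
    "CalibrationCurve",
    "CopSeries",
    "AgreementReport",
    "fit_calibration",
    "voltage_to_force",
    "cop",
    "cop_series",
    "cop_agreement",
]

CELL_AREA_M2 = 0.050 * 0.065  # 50 x 65 mm
R_REF_OHM = 70.0
V_SUPPLY = 3.3
PRESSURE_RANGE_PA = (200.0, 0.33e6)


def _default_centroids() -> np.ndarray:
    # column pitch 50+20 mm, row pitch 65+20 mm, centred on the mat
    xs = np.array([-105.0, -35.0, 35.0, 105.0])
    ys = np.array([-127.5, -42.5, 42.5, 127.5])
    # sensor index runs row-major: v01..v04 = rear row left->right, etc.
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class MatGeometry:
    """Cell centroid coordinates (mm) relative to the mat centre."""

    n_rows: int = 4
    n_cols: int = 4
    cell_size_mm: tuple[float, float] = (50.0, 65.0)
    gap_mm: float = 20.0
    centroids: np.ndarray = field(default_factory=_default_centroids)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def col_x(self) -> np.ndarray:
        return np.unique(self.centroids[:, 0])

    @property
    def row_y(self) -> np.ndarray:
        return np.unique(self.centroids[:, 1])


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-sensor conductance (S) -> pressure (Pa) calibration."""

    sensor_id: int
    poly: np.polynomial.Polynomial
    conductance_range: tuple[float, float]

    def pressure(self, conductance) -> np.ndarray:
        g = np.clip(conductance, *self.conductance_range)
        p = self.poly(g)
        return np.clip(p, *PRESSURE_RANGE_PA)


@dataclass(frozen=True)
class CopSeries:
    t: np.ndarray
    copx: np.ndarray   # mm, + right; NaN where total force is zero
    copy_: np.ndarray  # mm, + forward
    total_force: np.ndarray  # N


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of COP series a with reference b: a = slope*b + intercept."""

    slope: float
    intercept: float
    pearson_r2: float
    spearman_r2: float


def fit_calibration(
    cycles, sensor_id: int = 0, degree: int = 6
) -> CalibrationCurve:
    """Fit a 6th-order conductance->pressure polynomial to loading-cycle peaks.

    ``cycles`` is a sequence of (peak_pressure_Pa, peak_conductance_S)
    pairs; at least ``degree + 2`` cycles spanning the range are required.
    The fit is weighted by 1/pressure so the relative error stays
    controlled at the soft end of the range.
    """
    arr = np.asarray(list(cycles), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < degree + 2:
        raise ValueError(f"underdetermined fit: need >= {degree + 2} loading cycles")
    pressure, conductance = arr[:, 0], arr[:, 1]
    if np.any(pressure <= 0) or np.any(conductance <= 0):
        raise ValueError("pressures and conductances must be positive")
    poly = np.polynomial.Polynomial.fit(
        conductance, pressure, deg=degree, w=1.0 / pressure
    )
    return CalibrationCurve(
        sensor_id=sensor_id,
        poly=poly,
        conductance_range=(float(conductance.min()), float(conductance.max())),
    )


def voltage_to_force(
    v,
    curve: CalibrationCurve,
    r_ref: float = R_REF_OHM,
    v_supply: float = V_SUPPLY,
    cell_area: float = CELL_AREA_M2,
) -> np.ndarray:
    """Divider voltage (V) -> cell force (N) through the calibration curve."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative divider voltage")
    if np.any(v >= v_supply):
        raise ValueError("divider saturated: v >= v_supply")
    conductance = v / (r_ref * (v_supply - v))
    return curve.pressure(conductance) * cell_area


def cop(forces, geometry: MatGeometry | None = None) -> tuple[float, float, float]:
    """Force-weighted centroid of one frame of 16 cell forces.

    Returns (copx_mm, copy_mm, total_force_N); an all-zero frame yields
    (nan, nan, 0.0) — flagged, not raised.
    """
    if geometry is None:
        geometry = MatGeometry()
    f = np.asarray(forces, dtype=float)
    if f.shape != (geometry.n_cells,):
        raise ValueError(f"expected {geometry.n_cells} forces, got {f.shape}")
    if np.any(f < 0):
        raise ValueError("forces must be non-negative")
    total = float(f.sum())
    if total == 0:
        return (np.nan, np.nan, 0.0)
    cx = float(f @ geometry.centroids[:, 0] / total)
    cy = float(f @ geometry.centroids[:, 1] / total)
    return (cx, cy, total)


def cop_series(t, forces, geometry: MatGeometry | None = None) -> CopSeries:
    """Vectorised COP over a (n_samples, 16) force array."""
    if geometry is None:
        geometry = MatGeometry()
    f = np.asarray(forces, dtype=float)
    total = f.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cx = f @ geometry.centroids[:, 0] / total
        cy = f @ geometry.centroids[:, 1] / total
    cx = np.where(total > 0, cx, np.nan)
    cy = np.where(total > 0, cy, np.nan)
    return CopSeries(t=np.asarray(t, dtype=float), copx=cx, copy_=cy, total_force=total)


def _axis_agreement(a: np.ndarray, b: np.ndarray) -> AgreementReport:
    res = stats.linregress(b, a)
    rho = stats.spearmanr(a, b).statistic
    return AgreementReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r2=float(res.rvalue**2),
        spearman_r2=float(rho**2),
    )


def cop_agreement(a: CopSeries, b: CopSeries) -> dict[str, AgreementReport]:
    """Per-axis agreement of two time-aligned COP series (a regressed on b)."""
    if a.copx.size != b.copx.size:
        raise ValueError("series must have equal length (time-aligned)")
    ok = ~(np.isnan(a.copx) | np.isnan(b.copx) | np.isnan(a.copy_) | np.isnan(b.copy_))
    if ok.sum() < 10:
        raise ValueError("need at least 10 valid shared samples")
    return {
        "x": _axis_agreement(a.copx[ok], b.copx[ok]),
        "y": _axis_agreement(a.copy_[ok], b.copy_[ok]),
    }
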