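import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rollmetrics as rm
from rollmetrics import seat_mat
from rollmetrics.seat_mat import CELL_AREA_M2, PRESSURE_RANGE_PA
from rollmetrics.simulate import SensorModel, allocate_mat_forces


@pytest.fixture(scope="module")
def geometry():
    return rm.MatGeometry()


@pytest.fixture(scope="module")
def sensor():
    return SensorModel()


@pytest.fixture(scope="module")
def curve(sensor):
    return rm.fit_calibration(sensor.calibration_cycles(20))


class TestGeometry:
    def test_centroid_grid(self, geometry):
        np.testing.assert_allclose(geometry.col_x, [-105, -35, 35, 105])
        np.testing.assert_allclose(geometry.row_y, [-127.5, -42.5, 42.5, 127.5])
        assert geometry.centroids.shape == (16, 2)


class TestCalibration:
    def test_exact_sixth_order_law_is_interpolated(self):
        # the fit's own model class: residuals vanish
        g = np.geomspace(1e-5, 2e-2, 20)
        coeffs = [50.0, 4.0e6, 8.0e8, -2e9, 5e9, -1e10, 2e10]
        p = np.polynomial.polynomial.polyval(g, coeffs)
        curve = rm.fit_calibration(np.column_stack([p, g]))
        rel = np.abs(curve.poly(g) - p) / p
        assert rel.max() < 1e-8

    def test_underdetermined_fit_rejected(self):
        cycles = [(200.0, 1e-5), (1000.0, 1e-4), (5000.0, 1e-3)]
        with pytest.raises(ValueError, match="underdetermined"):
            rm.fit_calibration(cycles)

    def test_round_trip_force_error_under_two_percent(self, sensor, curve):
        forces = np.geomspace(
            PRESSURE_RANGE_PA[0] * CELL_AREA_M2 * 1.01,
            PRESSURE_RANGE_PA[1] * CELL_AREA_M2 * 0.99,
            200,
        )
        v = sensor.force_to_voltage(forces)
        decoded = rm.voltage_to_force(v, curve)
        rel = (decoded - forces) / forces
        assert np.sqrt(np.mean(rel**2)) < 0.02

    def test_round_trip_with_noisy_calibration_points(self, sensor):
        noisy = rm.fit_calibration(sensor.calibration_cycles(20, seed=5, noise_rel=0.01))
        forces = np.geomspace(5.0, 500.0, 50)  # typical seated cell loads
        decoded = rm.voltage_to_force(sensor.force_to_voltage(forces), noisy)
        rel = (decoded - forces) / forces
        assert np.sqrt(np.mean(rel**2)) < 0.02


class TestVoltageToForce:
    def test_zero_voltage_reads_calibration_floor(self, curve):
        f = rm.voltage_to_force(np.array([0.0]), curve)
        assert f[0] == pytest.approx(PRESSURE_RANGE_PA[0] * CELL_AREA_M2)

    def test_saturated_divider_rejected(self, curve):
        with pytest.raises(ValueError, match="saturated"):
            rm.voltage_to_force(np.array([3.3]), curve)
        with pytest.raises(ValueError):
            rm.voltage_to_force(np.array([-0.1]), curve)


class TestCop:
    def test_uniform_load_is_centred(self, geometry):
        copx, copy_, total = rm.cop(np.ones(16), geometry)
        assert (copx, copy_) == (0.0, 0.0)
        assert total == 16.0

    def test_single_support(self, geometry):
        f = np.zeros(16)
        f[12] = 5.0  # front-left cell: (-105, +127.5)
        assert rm.cop(f, geometry) == (-105.0, 127.5, 5.0)

    def test_two_cell_weighted_mean(self, geometry):
        f = np.zeros(16)
        f[5] = 2.0   # (-35, -42.5)
        f[6] = 1.0   # (+35, -42.5)
        copx, copy_, total = rm.cop(f, geometry)
        assert copx == pytest.approx((2 * -35 + 1 * 35) / 3, abs=1e-12)  # -11.667 mm
        assert copy_ == -42.5

    def test_all_zero_frame_is_flagged_gap(self, geometry):
        copx, copy_, total = rm.cop(np.zeros(16), geometry)
        assert np.isnan(copx) and np.isnan(copy_) and total == 0.0

    def test_negative_force_rejected(self, geometry):
        f = np.zeros(16)
        f[0] = -1.0
        with pytest.raises(ValueError):
            rm.cop(f, geometry)

    @settings(deadline=None, max_examples=1000)
    @given(st.integers(0, 2**32 - 1))
    def test_oracle_equivalence_brute_force_loop(self, seed):
        geometry = rm.MatGeometry()
        f = np.random.default_rng(seed).uniform(0.0, 50.0, 16)
        copx, copy_, total = rm.cop(f, geometry)
        sx = sy = s = 0.0
        for i in range(16):
            sx += f[i] * geometry.centroids[i, 0]
            sy += f[i] * geometry.centroids[i, 1]
            s += f[i]
        assert abs(copx - sx / s) < 1e-12
        assert abs(copy_ - sy / s) < 1e-12

    def test_translation_covariance_and_scale_invariance(self, rng, geometry):
        f = rng.uniform(0.1, 30.0, 16)
        copx, copy_, _ = rm.cop(f, geometry)
        shifted = rm.MatGeometry(centroids=geometry.centroids + np.array([7.5, -3.25]))
        cx2, cy2, _ = rm.cop(f, shifted)
        assert cx2 - copx == pytest.approx(7.5, abs=1e-12)
        assert cy2 - copy_ == pytest.approx(-3.25, abs=1e-12)
        cx3, cy3, _ = rm.cop(f * 17.3, geometry)
        assert cx3 == pytest.approx(copx, abs=1e-12)
        assert cy3 == pytest.approx(copy_, abs=1e-12)

    def test_ischial_load_transfer_fractions(self):
        """A 10 mm lateral COP shift of a load split across two supports a
        distance d apart transfers 10/d of the total load between them."""
        for d, printed in ((134.9, 7.43), (116.5, 8.57)):
            assert 100 * 10.0 / d == pytest.approx(printed, abs=0.03)


class TestAllocatedForcesRoundTrip:
    def test_cop_of_allocated_forces_matches_plant(self, rng, geometry):
        copx = rng.uniform(-99, 99, 500)
        copy_ = rng.uniform(-121, 121, 500)
        forces = allocate_mat_forces(copx, copy_, total=600.0, geometry=geometry)
        assert np.all(forces >= 0)
        series = rm.cop_series(np.arange(500.0), forces, geometry)
        np.testing.assert_allclose(series.copx, copx, atol=1e-9)
        np.testing.assert_allclose(series.copy_, copy_, atol=1e-9)
        np.testing.assert_allclose(series.total_force, 600.0, rtol=1e-12)


class TestAgreement:
    def _series(self, x, y):
        t = np.arange(len(x), dtype=float)
        return seat_mat.CopSeries(
            t=t, copx=np.asarray(x, float), copy_=np.asarray(y, float),
            total_force=np.full(len(x), 600.0),
        )

    def test_identical_series(self, rng):
        x = rng.normal(0, 10, 200)
        y = rng.normal(-18, 8, 200)
        a = self._series(x, y)
        rep = rm.cop_agreement(a, a)
        for axis in ("x", "y"):
            assert rep[axis].slope == pytest.approx(1.0)
            assert rep[axis].intercept == pytest.approx(0.0, abs=1e-9)
            assert rep[axis].pearson_r2 == pytest.approx(1.0)
            assert rep[axis].spearman_r2 == pytest.approx(1.0)

    def test_affine_relation(self, rng):
        x = rng.normal(0, 10, 200)
        a = self._series(x, x)
        b = self._series(2 * x + 3, 2 * x + 3)
        rep = rm.cop_agreement(a, b)
        assert rep["x"].slope == pytest.approx(0.5)
        assert rep["x"].pearson_r2 == pytest.approx(1.0)

    def test_noise_degrades_pearson_monotonically(self, rng):
        x = rng.normal(0, 10, 2000)
        r2 = []
        for sd in (1.0, 5.0, 20.0):
            noisy = x + rng.normal(0, sd, x.size)
            rep = rm.cop_agreement(self._series(noisy, noisy), self._series(x, x))
            r2.append(rep["x"].pearson_r2)
        assert r2[0] > r2[1] > r2[2]

    def test_short_series_rejected(self):
        a = self._series(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            rm.cop_agreement(a, a)
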