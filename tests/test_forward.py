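"""Forward-model physics: pulse spectrum, delays, linearity, noise."""

import numpy as np
import pytest

from pavision.beamform import ReconGrid
from pavision.forward import (NoiseConfig, ProbeConfig, add_noise,
                              build_system_matrix, calibration_amplitude,
                              impulse_response, point_source_response,
                              simulate_rf)
from pavision.phantoms import AbsorptionMap


@pytest.fixture(scope="module")
def probe():
    return ProbeConfig()


class TestImpulseResponse:
    def test_spectral_peak_at_central_frequency(self, probe):
        ir = impulse_response(probe)
        freqs = np.fft.rfftfreq(8192, 1.0 / probe.fs_MHz)
        spec = np.abs(np.fft.rfft(ir, 8192))
        df = probe.fs_MHz / 8192
        assert abs(freqs[np.argmax(spec)] - 15.6) <= probe.fs_MHz / len(ir) + df

    def test_zero_mean(self, probe):
        # no DC content: the cause of the limited-bandwidth artefact
        assert abs(impulse_response(probe).sum()) < 1e-12

    def test_unit_peak(self, probe):
        # continuous-time peak is 1; the sampled grid may sit slightly off it
        assert np.max(np.abs(impulse_response(probe))) == pytest.approx(1.0, abs=0.01)

    def test_minus6dB_fractional_bandwidth(self, probe):
        ir = impulse_response(probe)
        freqs = np.fft.rfftfreq(8192, 1.0 / probe.fs_MHz)
        spec = np.abs(np.fft.rfft(ir, 8192))
        band = freqs[spec >= spec.max() * 10 ** (-6 / 20)]
        fbw = (band[-1] - band[0]) / probe.f_c_MHz
        assert fbw == pytest.approx(probe.fractional_bandwidth, rel=0.10)

    def test_sampling_criterion_enforced(self):
        with pytest.raises(ValueError, match="sampling rate"):
            ProbeConfig(fs_MHz=20.0)


class TestPointSource:
    def test_arrival_time_5us_at_7p5mm(self, probe):
        # t = r/c with c = 1500 m/s: 7.5 mm straight below the center
        rf = point_source_response(probe, (0.0, 7.5))
        mid = np.abs(rf.signals[probe.n_elements // 2 - 1])
        t_peak = np.argmax(mid) / probe.fs_MHz
        # central elements sit +-pitch/2 off-axis; allow one period of slack
        assert t_peak == pytest.approx(5.0, abs=0.1)

    def test_zero_amplitude_gives_zero_rf(self, probe):
        rf = point_source_response(probe, (1.0, 5.0), amplitude=0.0)
        assert not np.any(rf.signals)

    def test_on_axis_source_symmetric_across_aperture(self, probe):
        rf = point_source_response(probe, (0.0, 6.0)).signals
        for k in (0, 17, 50):
            np.testing.assert_allclose(rf[k], rf[probe.n_elements - 1 - k],
                                       atol=1e-12)

    def test_source_behind_probe_rejected(self, probe):
        with pytest.raises(ValueError, match="z > 0"):
            point_source_response(probe, (0.0, -1.0))

    def test_causality_no_signal_before_first_arrival(self, probe):
        src = (2.0, 9.0)
        rf = point_source_response(probe, src)
        dists = np.linalg.norm(probe.positions_mm - np.array(src), axis=1)
        t_min = dists.min() / probe.c_mm_per_us
        n_first = int((t_min - 4.5 * probe.pulse_sigma_us) * probe.fs_MHz)
        assert not np.any(rf.signals[:, :max(n_first, 0)])


class TestSimulateRF:
    def test_empty_map_gives_zero_rf(self, probe):
        amap = AbsorptionMap(np.zeros((32, 32)), 40.0, (-0.64, 4.0))
        assert not np.any(simulate_rf(amap, probe).signals)

    def test_superposition_of_two_pixels(self, probe):
        base = np.zeros((16, 16))
        a, b = base.copy(), base.copy()
        a[3, 4] = 0.7
        b[10, 12] = 0.4
        both = a + b
        origin = (-0.32, 5.0)
        rf_a = simulate_rf(AbsorptionMap(a, 40.0, origin), probe).signals
        rf_b = simulate_rf(AbsorptionMap(b, 40.0, origin), probe).signals
        rf_ab = simulate_rf(AbsorptionMap(both, 40.0, origin), probe).signals
        np.testing.assert_allclose(rf_ab, rf_a + rf_b, atol=1e-12)

    def test_homogeneity(self, probe, rng):
        vals = rng.random((12, 12)) * (rng.random((12, 12)) > 0.7)
        origin = (-0.24, 4.0)
        rf1 = simulate_rf(AbsorptionMap(vals, 40.0, origin), probe).signals
        rf3 = simulate_rf(AbsorptionMap(3.0 * vals, 40.0, origin), probe).signals
        np.testing.assert_allclose(rf3, 3.0 * rf1, rtol=1e-12, atol=1e-12)


@pytest.fixture(scope="module")
def small_setup():
    probe = ProbeConfig(n_elements=32, n_samples=256, pitch_mm=0.2)
    grid = ReconGrid.for_patch((0.0, 3.0), 1.28, 80.0)  # 16x16
    return probe, grid, build_system_matrix(probe, grid)


class TestSystemMatrix:
    def test_column_is_point_source_response(self, small_setup):
        probe, grid, A = small_setup
        j = 5 * 16 + 9  # row-major (z, x)
        rf = point_source_response(probe, (grid.x_mm[9], grid.z_mm[5]))
        np.testing.assert_allclose(A.entries[:, j], rf.signals.ravel(), atol=1e-14)

    def test_operator_matches_simulate_rf_on_random_map(self, small_setup, rng):
        probe, grid, A = small_setup
        X = rng.random((16, 16))
        amap = AbsorptionMap(X, 80.0, grid.origin_mm)
        rf = simulate_rf(amap, probe).signals.ravel()
        rel = np.linalg.norm(A.entries @ X.ravel() - rf) / np.linalg.norm(rf)
        assert rel < 1e-10

    def test_memory_guard(self, small_setup):
        probe, grid, _ = small_setup
        with pytest.raises(MemoryError):
            build_system_matrix(probe, grid, max_bytes=1000)


class TestNoise:
    def test_infinite_snr_is_identity(self, probe):
        rf = point_source_response(probe, (0.0, 5.0))
        out = add_noise(rf, NoiseConfig(np.inf), probe, calibration=1.0)
        np.testing.assert_array_equal(out.signals, rf.signals)

    def test_snr_calibration_close_to_target(self, probe):
        # empirical calibration/std ratio ~ 60 across seeds
        cal = calibration_amplitude(probe)
        zero = AbsorptionMap(np.zeros((8, 8)), 40.0, (-0.16, 5.0))
        ratios = []
        for seed in range(10):
            rf = simulate_rf(zero, probe, noise=NoiseConfig(60.0, seed=seed),
                             calibration=cal)
            ratios.append(cal / rf.signals.std())
        assert np.mean(ratios) == pytest.approx(60.0, rel=0.05)

    def test_different_seeds_different_realizations(self, probe):
        rf = point_source_response(probe, (0.0, 5.0))
        o1 = add_noise(rf, NoiseConfig(60, seed=1), probe, calibration=1.0)
        o2 = add_noise(rf, NoiseConfig(60, seed=2), probe, calibration=1.0)
        assert np.any(o1.signals != o2.signals)
        # noise is additive: subtracting the clean RF leaves pure noise
        assert (o1.signals - rf.signals).std() == pytest.approx(
            (o2.signals - rf.signals).std(), rel=0.1)
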