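"""Forward model: scan planning, impulse response, projection physics, noise."""

import numpy as np
import pytest

from patkit.forward import (
    Medium,
    Transducer,
    add_noise,
    plan_scan,
    simulate_sinogram,
    transducer_eir,
)
from patkit.grid import SOUND_SPEED, TIME_STEP
from patkit.phantoms import PressureMap


class TestPlanScan:
    @pytest.mark.parametrize(
        "duration, prr, n_ust, avg, expected",
        [
            (5.0, 10.0, 1, 1.0, 50),
            (480.0, 10.0, 1, 1.0, 4800),
            (0.3, 2000.0, 8, 2.5, 240),
            (1.5, 2000.0, 8, 2.5, 1200),
            (2.0, 2000.0, 8, 2.5, 1600),
        ],
    )
    def test_position_counts(self, duration, prr, n_ust, avg, expected):
        geo = plan_scan(duration, prr, n_ust, averaging_factor=avg)
        assert geo.n_positions == expected

    def test_eight_sectors_partition_the_circle(self):
        geo = plan_scan(0.3, 2000.0, 8, averaging_factor=2.5)
        angles = geo.angles.reshape(8, -1)
        sector = 2 * np.pi / 8
        for u in range(8):
            assert np.all(angles[u] >= u * sector - 1e-12)
            assert np.all(angles[u] < (u + 1) * sector)
        # uniform spacing overall
        assert np.allclose(np.diff(np.sort(geo.angles)), sector / 30)

    def test_no_pulses_rejected(self):
        with pytest.raises(ValueError):
            plan_scan(0.01, 10.0)


class TestImpulseResponse:
    def test_spectrum_peaks_at_centre_frequency(self):
        tr = Transducer(fc_mhz=2.25, fractional_bandwidth=0.7)
        k = transducer_eir(tr)
        nfft = 1 << 16
        freqs = np.fft.rfftfreq(nfft, TIME_STEP)
        spec = np.abs(np.fft.rfft(k, nfft))
        df = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(spec)] - 2.25e6) <= df

    def test_minus6db_width_matches_fractional_bandwidth(self):
        tr = Transducer(fc_mhz=2.25, fractional_bandwidth=0.7)
        k = transducer_eir(tr)
        nfft = 1 << 16
        freqs = np.fft.rfftfreq(nfft, TIME_STEP)
        spec = np.abs(np.fft.rfft(k, nfft))
        spec /= spec.max()
        above = freqs[spec >= 0.5]
        width = above.max() - above.min()
        assert width == pytest.approx(0.7 * 2.25e6, rel=0.05)

    def test_ideal_transducer_gives_delta_kernel(self):
        np.testing.assert_array_equal(transducer_eir(Transducer(ideal=True)), [1.0])

    def test_centre_frequency_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            transducer_eir(Transducer(fc_mhz=13.0), dt=40e-9)  # Nyquist = 12.5 MHz


class TestSimulation:
    def test_point_source_arrival_time(self, centred_point):
        geo = plan_scan(1.0, 10.0)  # 10 positions at 37 mm
        sino = simulate_sinogram(centred_point, geo, Transducer(ideal=True))
        # the "centre" pixel sits at (+0.1, +0.1) mm on the even-sized grid
        src = np.array([0.1, 0.1])
        for row, det in zip(sino.values, geo.positions_mm):
            r_mm = np.hypot(*(det - src))
            expected = round(r_mm * 1e-3 / (SOUND_SPEED * TIME_STEP))
            assert abs(int(np.argmax(np.abs(row))) - expected) <= 2

    def test_translation_shifts_arrival_consistently(self, grid_1ust):
        geo = plan_scan(0.1, 10.0)  # single detector at (37, 0)
        # the grid "centre" pixel is at (+0.1, +0.1) mm; pixel 255 sits
        # 10.1 mm along +x, i.e. 26.9 mm from the detector at (37, 0)
        for x_px, expected_mm in [(205, 36.9), (255, 26.9)]:
            vals = np.zeros((grid_1ust.ny, grid_1ust.nx))
            vals[205, x_px] = 1.0
            sino = simulate_sinogram(PressureMap(grid_1ust, vals), geo, Transducer(ideal=True))
            idx = int(np.argmax(np.abs(sino.values[0])))
            assert abs(idx - expected_mm * 1e-3 / (SOUND_SPEED * TIME_STEP)) <= 2

    def test_forward_operator_is_linear(self, grid_1ust):
        rng = np.random.default_rng(0)
        mask = grid_1ust.imaging_disc_mask()
        a = np.zeros(mask.shape)
        b = np.zeros(mask.shape)
        ys, xs = np.nonzero(mask)
        pick = rng.choice(ys.size, 40, replace=False)
        a[ys[pick[:20]], xs[pick[:20]]] = rng.uniform(0.5, 1, 20)
        b[ys[pick[20:]], xs[pick[20:]]] = rng.uniform(0.5, 1, 20)
        geo = plan_scan(1.0, 10.0)
        tr = Transducer()
        sa = simulate_sinogram(PressureMap(grid_1ust, a), geo, tr).values
        sb = simulate_sinogram(PressureMap(grid_1ust, b), geo, tr).values
        sab = simulate_sinogram(PressureMap(grid_1ust, a + b), geo, tr).values
        assert np.allclose(sab, sa + sb, atol=1e-9 * np.abs(sa + sb).max())

    def test_zero_phantom_noise_free_gives_zero_sinogram(self, grid_1ust):
        p0 = PressureMap(grid_1ust, np.zeros((grid_1ust.ny, grid_1ust.nx)))
        sino = simulate_sinogram(p0, plan_scan(1.0, 10.0), Transducer(ideal=True))
        assert not sino.values.any()

    def test_zero_phantom_with_snr_rejected(self, grid_1ust):
        p0 = PressureMap(grid_1ust, np.zeros((grid_1ust.ny, grid_1ust.nx)))
        with pytest.raises(ValueError):
            simulate_sinogram(p0, plan_scan(1.0, 10.0), Transducer(), snr_db=40.0)

    def test_subelement_discretization_converged(self, centred_point):
        geo = plan_scan(0.5, 10.0)
        tr = Transducer(aperture_mm=13.0)
        s9 = simulate_sinogram(centred_point, geo, tr, n_subelements=9).values
        s18 = simulate_sinogram(centred_point, geo, tr, n_subelements=18).values
        rel = np.sqrt(np.mean((s9 - s18) ** 2)) / np.sqrt(np.mean(s9**2))
        assert rel < 0.01

    def test_deterministic_for_fixed_seed(self, centred_point):
        geo = plan_scan(0.5, 10.0)
        a = simulate_sinogram(centred_point, geo, Transducer(), snr_db=40.0, seed=5).values
        b = simulate_sinogram(centred_point, geo, Transducer(), snr_db=40.0, seed=5).values
        np.testing.assert_array_equal(a, b)


class TestAddNoise:
    def test_measured_snr_within_half_db(self):
        t = np.arange(50000)
        sig = np.sin(2 * np.pi * t / 100.0)
        noisy = add_noise(sig, 40.0, seed=1)
        noise = noisy - sig
        measured = 20 * np.log10(np.sqrt(np.mean(sig**2)) / np.sqrt(np.mean(noise**2)))
        assert abs(measured - 40.0) <= 0.5

    def test_infinite_snr_is_identity(self):
        sig = np.ones(16)
        np.testing.assert_array_equal(add_noise(sig, np.inf, seed=0), sig)

    def test_same_seed_reproducible(self):
        sig = np.linspace(-1, 1, 64)
        np.testing.assert_array_equal(add_noise(sig, 20.0, 7), add_noise(sig, 20.0, 7))

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(8), 40.0, seed=0)
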