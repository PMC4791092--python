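"""Multi-coil RSS noise simulator: normalisation, moments, independence."""

import numpy as np
import pytest
from scipy.special import gammaln

from adapts import (
    CARDIAC_PROTOCOL,
    LIVER_PROTOCOL,
    CoilNoiseModel,
    EchoProtocol,
    SimulationConfig,
    simulate_pixel,
    simulate_roi_pixels,
    simulate_roi_signal,
)
from adapts.simulator import rng_for_cell


def chi_mean(n_coils, sigma):
    """E[RSS] at zero signal: sigma * sqrt(2) * Gamma(L + 1/2) / Gamma(L)."""
    return sigma * np.sqrt(2.0) * np.exp(gammaln(n_coils + 0.5) - gammaln(n_coils))


class TestSimulatePixel:
    @pytest.mark.parametrize("n_coils", [1, 6, 32])
    def test_noiseless_rss_equals_s0_decay(self, n_coils, rng):
        noise = CoilNoiseModel(n_coils, 0.0)
        out = simulate_pixel(10.0, 100.0, noise, CARDIAC_PROTOCOL, rng)
        np.testing.assert_allclose(
            out, 100.0 * np.exp(-CARDIAC_PROTOCOL.te_array / 10.0), rtol=1e-12
        )

    def test_rayleigh_mean_at_zero_signal(self, rng):
        # single coil, no signal: magnitudes are Rayleigh with mean
        # sigma * sqrt(pi/2) = 1.2533 for sigma = 1
        prot = EchoProtocol(tuple(np.arange(1.0, 2001.0)))
        out = simulate_pixel(1.0, 0.0, CoilNoiseModel(1, 1.0), prot, rng)
        se = np.sqrt((2 - np.pi / 2) / out.size)
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), abs=4 * se)

    @pytest.mark.parametrize("n_coils", [1, 6])
    def test_noncentral_chi_floor(self, n_coils, rng):
        sigma = 2.0
        prot = EchoProtocol(tuple(np.arange(1.0, 1001.0)))
        draws = np.stack(
            [
                simulate_pixel(1.0, 0.0, CoilNoiseModel(n_coils, sigma), prot, rng)
                for _ in range(100)
            ]
        )
        expected = chi_mean(n_coils, sigma)
        assert draws.mean() == pytest.approx(expected, rel=0.01)

    def test_second_moment_identity(self):
        # E[RSS^2] = S^2 + 2 L sigma^2, checked by simulation at 1e5 draws
        s0, t2, L, sigma = 100.0, 10.0, 6, 5.0
        rng = rng_for_cell(42, 0)
        draws = np.stack(
            [
                simulate_pixel(t2, s0, CoilNoiseModel(L, sigma), LIVER_PROTOCOL, rng)
                for _ in range(2)
            ]
        )
        # vectorised large-n version through the ROI generator
        roi = simulate_roi_pixels(
            t2, LIVER_PROTOCOL, s0 / (sigma * np.sqrt(2 * L)), L, 100_000,
            rng_for_cell(42, 1), s0=s0,
        )
        emp = np.mean(roi.pixel_signals**2, axis=0)
        s = s0 * np.exp(-LIVER_PROTOCOL.te_array / t2)
        expected = s**2 + 2 * L * sigma**2
        np.testing.assert_allclose(emp, expected, rtol=0.01)

    def test_snr_semantics_initial_magnitude_approaches_s0(self):
        # t2 >> max TE: mean RSS at the first echo tends to s0
        roi = simulate_roi_pixels(
            1e6, CARDIAC_PROTOCOL, 15.0, 6, 20_000, rng_for_cell(9, 0)
        )
        first = roi.pixel_signals[:, 0]
        assert first.mean() == pytest.approx(100.0, rel=0.01)


class TestRoiSimulation:
    def test_roi_signal_is_mean_of_roi_pixels(self):
        pixels = simulate_roi_pixels(
            8.0, LIVER_PROTOCOL, 15.0, 6, 40, rng_for_cell(1, 0)
        )
        signal = simulate_roi_signal(8.0, LIVER_PROTOCOL, 15.0, 6, 40, rng_for_cell(1, 0))
        np.testing.assert_array_equal(
            signal.values, pixels.pixel_signals.mean(axis=0)
        )

    def test_single_pixel_roi_matches_simulate_pixel(self):
        L, snr, s0 = 6, 15.0, 100.0
        sigma = s0 / (snr * np.sqrt(2 * L))
        pix = simulate_pixel(
            5.0, s0, CoilNoiseModel(L, sigma), LIVER_PROTOCOL, rng_for_cell(2, 0)
        )
        roi = simulate_roi_pixels(5.0, LIVER_PROTOCOL, snr, L, 1, rng_for_cell(2, 0))
        np.testing.assert_allclose(roi.pixel_signals[0], pix, rtol=1e-12)

    def test_seeded_determinism(self):
        a = simulate_roi_pixels(5.0, LIVER_PROTOCOL, 15.0, 6, 40, rng_for_cell(3, 1))
        b = simulate_roi_pixels(5.0, LIVER_PROTOCOL, 15.0, 6, 40, rng_for_cell(3, 1))
        np.testing.assert_array_equal(a.pixel_signals, b.pixel_signals)

    def test_variance_of_mean_scales_with_pixel_count(self):
        rng = rng_for_cell(4, 0)
        n_reps, n_px = 4000, 25
        pixels = np.stack(
            [
                simulate_roi_pixels(10.0, LIVER_PROTOCOL, 15.0, 1, n_px, rng)
                .pixel_signals
                for _ in range(n_reps)
            ]
        )  # (reps, px, te)
        var_single = pixels[:, 0, 0].var()
        var_mean = pixels.mean(axis=1)[:, 0].var()
        assert var_mean == pytest.approx(var_single / n_px, rel=0.15)

    def test_pixels_statistically_independent(self):
        # zero signal isolates the noise: any shared decaying mean would
        # otherwise dominate the inter-pixel correlation estimate
        prot = EchoProtocol(tuple(np.arange(1.0, 10_001.0)))
        rng = rng_for_cell(5, 0)
        noise = CoilNoiseModel(1, 1.0)
        pixel_signals = np.stack(
            [simulate_pixel(5.0, 0.0, noise, prot, rng) for _ in range(12)]
        )
        corr = np.corrcoef(pixel_signals)
        off_diag = corr[~np.eye(12, dtype=bool)]
        assert np.mean(np.abs(off_diag)) < 0.02


class TestSimulationConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(t2_grid=(), snr=15, protocol=CARDIAC_PROTOCOL)
        with pytest.raises(ValueError):
            SimulationConfig(t2_grid=(5.0,), snr=-1, protocol=CARDIAC_PROTOCOL)

    def test_channel_sigma_scaling(self):
        cfg = SimulationConfig(t2_grid=(5.0,), snr=20.0, protocol=CARDIAC_PROTOCOL)
        assert cfg.channel_sigma(1) == pytest.approx(100 / (20 * np.sqrt(2)))
        assert cfg.channel_sigma(8) == pytest.approx(100 / (20 * 4.0))
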