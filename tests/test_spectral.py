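"""Time-resolved spectral parametrization: STFT, aperiodic and peak fits."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from conftest import planted_spectrum
from alphadyn.simulate import (
    AlphaDynamicsSpec,
    AperiodicSpec,
    Recording,
    simulate_aperiodic_signal,
    simulate_channel,
)
from alphadyn.spectral import (
    SpectralSettings,
    WindowSpectrum,
    PeakFit,
    fit_aperiodic,
    fit_peaks,
    parameterize_recording,
    parameterize_window,
    select_alpha_peak,
    stft_log_psd,
)

GRID = np.arange(1.0, 40.01, 0.5)


def _noise_recording(duration, fs=250.0, n_ch=1, seed=0):
    data = np.stack(
        [
            simulate_aperiodic_signal(AperiodicSpec(0.0, 0.0), duration, fs, seed=seed + i)
            for i in range(n_ch)
        ]
    )
    return Recording(data, fs, [f"c{i}" for i in range(n_ch)], "s", "pre", "high")


class TestSTFT:
    def test_window_count_without_averaging(self):
        rec = _noise_recording(300.0)
        s = SpectralSettings(n_avg=1)
        _, times, logp = stft_log_psd(rec, s)
        assert logp.shape[1] == 599  # floor((300-1)/0.5)+1

    def test_averaging_reduces_window_count(self):
        rec = _noise_recording(300.0)
        _, _, logp = stft_log_psd(rec, SpectralSettings(n_avg=5))
        assert logp.shape[1] == 599 - 4

    def test_pure_sinusoid_peaks_at_10hz(self):
        t = np.arange(0, 30.0, 1 / 250.0)
        rec = Recording(np.sin(2 * np.pi * 10.0 * t)[None, :], 250.0, ["c0"], "s", "pre", "high")
        freqs, _, logp = stft_log_psd(rec, SpectralSettings(debias=False))
        assert np.all(freqs[np.argmax(logp[0], axis=1)] == 10.0)

    def test_white_noise_mean_spectrum_is_flat(self):
        rec = _noise_recording(120.0)
        freqs, _, logp = stft_log_psd(rec, SpectralSettings())
        mean_spec = logp[0].mean(axis=0)
        slope = np.polyfit(np.log10(freqs), mean_spec, 1)[0]
        assert abs(slope) < 0.1

    def test_frequency_range_restricted(self):
        freqs, _, _ = stft_log_psd(_noise_recording(10.0), SpectralSettings())
        assert freqs[0] >= 1.0 and freqs[-1] <= 40.0

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError):
            stft_log_psd(_noise_recording(0.5), SpectralSettings())

    def test_low_sampling_rate_raises(self):
        rec = Recording(np.zeros((1, 500)) + 1e-9 * np.arange(500), 60.0, ["c0"], "s", "pre", "high")
        with pytest.raises(ValueError):
            stft_log_psd(rec, SpectralSettings())


class TestAperiodicFit:
    def test_exact_noiseless_closed_form(self):
        spec = WindowSpectrum(GRID, 1.5 - 1.0 * np.log10(GRID))
        for robust in (True, False):
            fit = fit_aperiodic(spec, robust=robust)
            assert abs(fit.offset - 1.5) < 1e-6
            assert abs(fit.exponent - 1.0) < 1e-6

    def test_robust_fit_resists_planted_peak(self):
        """Robust fit matches an oracle fit restricted to bins far from the peak."""
        logp = planted_spectrum(GRID, 0.0, 1.0, [(10.0, 0.8, 2.0)])
        fit = fit_aperiodic(WindowSpectrum(GRID, logp), robust=True)
        far = np.abs(GRID - 10.0) > 6.0  # > 3w from the peak center
        slope, intercept = np.polyfit(np.log10(GRID[far]), logp[far], 1)
        assert abs(fit.offset - intercept) < 0.05
        assert abs(fit.exponent - (-slope)) < 0.05

    def test_degenerate_grid_raises(self):
        with pytest.raises(ValueError):
            fit_aperiodic(WindowSpectrum(GRID[:3], np.zeros(3)))


class TestPeakFit:
    def test_subthreshold_flat_spectrum_yields_no_peaks(self):
        rng = np.random.default_rng(0)
        noise = np.clip(rng.normal(0, 0.05, GRID.size), -0.09, 0.09)
        assert fit_peaks(WindowSpectrum(GRID, noise)) == []

    def test_single_planted_gaussian_recovered(self):
        flat = planted_spectrum(GRID, 0.0, 0.0, [(10.0, 0.6, 2.0)])
        peaks = fit_peaks(WindowSpectrum(GRID, flat))
        assert len(peaks) == 1
        p = peaks[0]
        assert abs(p.center_frequency - 10.0) < 0.1
        assert abs(p.amplitude - 0.6) < 0.05
        assert abs(p.width - 2.0) < 0.2

    def test_agrees_with_scipy_curve_fit_oracle(self):
        """Dual route: the numba refit matches dense nonlinear least squares."""
        flat = planted_spectrum(GRID, 0.0, 0.0, [(10.0, 0.6, 2.0), (22.0, 0.4, 1.5)])
        peaks = sorted(fit_peaks(WindowSpectrum(GRID, flat)), key=lambda p: p.center_frequency)

        def model(f, c1, a1, w1, c2, a2, w2):
            return a1 * np.exp(-((f - c1) ** 2) / (2 * w1**2)) + a2 * np.exp(
                -((f - c2) ** 2) / (2 * w2**2)
            )

        popt, _ = curve_fit(model, GRID, flat, p0=[9.0, 0.5, 1.5, 21.0, 0.3, 1.5])
        oracle = [popt[:3], popt[3:]]
        for mine, ref in zip(peaks, oracle):
            assert abs(mine.center_frequency - ref[0]) < 0.1
            assert abs(mine.amplitude - ref[1]) < 0.05
            assert abs(mine.width - ref[2]) < 0.2

    def test_at_most_three_peaks_returned(self):
        flat = planted_spectrum(
            GRID, 0.0, 0.0, [(6.0, 0.9, 1.0), (12.0, 0.8, 1.0), (20.0, 0.7, 1.0), (30.0, 0.6, 1.0)]
        )
        assert len(fit_peaks(WindowSpectrum(GRID, flat))) <= 3

    def test_overlapping_smaller_peak_dropped(self):
        flat = planted_spectrum(GRID, 0.0, 0.0, [(10.0, 0.8, 2.0)])
        peaks = fit_peaks(WindowSpectrum(GRID, flat))
        centers = [p.center_frequency for p in peaks]
        # a single true bump must not be reported as several nearby Gaussians
        assert len(centers) == 1


class TestParameterizeWindow:
    def test_pure_power_law(self):
        logp = planted_spectrum(GRID, 1.0, 1.5, [])
        fit = parameterize_window(WindowSpectrum(GRID, logp))
        assert fit.peaks == []
        assert abs(fit.aperiodic.offset - 1.0) < 1e-6
        assert abs(fit.aperiodic.exponent - 1.5) < 1e-6
        assert fit.r_squared > 0.999

    def test_planted_model_full_round_trip(self):
        logp = planted_spectrum(GRID, 1.0, 1.0, [(10.0, 0.6, 2.0)])
        fit = parameterize_window(WindowSpectrum(GRID, logp))
        assert abs(fit.aperiodic.offset - 1.0) < 0.05
        assert abs(fit.aperiodic.exponent - 1.0) < 0.05
        assert len(fit.peaks) == 1
        assert abs(fit.peaks[0].center_frequency - 10.0) < 0.1

    def test_reported_mse_is_self_consistent(self):
        """Reported mse equals the residual recomputed from the returned model."""
        rng = np.random.default_rng(4)
        logp = planted_spectrum(GRID, 0.5, 1.0, [(10.0, 0.7, 2.0)]) + rng.normal(0, 0.1, GRID.size)
        fit = parameterize_window(WindowSpectrum(GRID, logp))
        model = fit.aperiodic.offset - fit.aperiodic.exponent * np.log10(GRID)
        for p in fit.peaks:
            model += p.amplitude * np.exp(-((GRID - p.center_frequency) ** 2) / (2 * p.width**2))
        assert abs(fit.mse - np.mean((model - logp) ** 2)) < 1e-10


class TestAlphaSelection:
    def test_out_of_band_peak_ignored(self):
        peaks = [PeakFit(6.0, 0.9, 2.0), PeakFit(10.0, 0.5, 2.0)]
        assert select_alpha_peak(peaks).center_frequency == 10.0

    def test_no_peaks_returns_none(self):
        assert select_alpha_peak([]) is None

    def test_largest_amplitude_wins_exhaustively(self):
        peaks = [PeakFit(9.0, 0.5, 2.0), PeakFit(11.0, 0.7, 2.0), PeakFit(12.5, 0.6, 2.0)]
        chosen = select_alpha_peak(peaks)
        oracle = max(
            (p for p in peaks if 8 <= p.center_frequency <= 13), key=lambda p: p.amplitude
        )
        assert chosen == oracle


class TestParameterizeRecording:
    def test_shapes_match_window_count(self, parameterized_null):
        pts = parameterized_null
        n_win = pts.window_times.size
        for name in pts.PARAMETERS:
            assert pts.parameter(name).shape == (8, n_win)

    def test_stable_alpha_recovered_with_low_jitter(self):
        sig = simulate_channel(
            AperiodicSpec(0.0, 1.0), AlphaDynamicsSpec(cf_jitter_sd=0.0), 120.0, 250.0, seed=3
        )
        pts = parameterize_recording(Recording(sig[None, :], 250.0, ["c0"], "s", "pre", "high"))
        cf = pts.alpha_cf[0]
        assert pts.alpha_coverage[0] > 0.9
        assert abs(np.nanmedian(cf) - 10.0) < 0.3
        assert np.nanstd(cf, ddof=1) < 0.3

    def test_flattening_reduces_peak_bias_on_exponent(self):
        """The final peak-subtracted aperiodic fit is closer to truth than a
        plain OLS on the peaked spectrum."""
        logp = planted_spectrum(GRID, 0.0, 1.0, [(10.0, 0.8, 2.0)])
        plain = fit_aperiodic(WindowSpectrum(GRID, logp), robust=False)
        full = parameterize_window(WindowSpectrum(GRID, logp))
        assert abs(full.aperiodic.exponent - 1.0) < abs(plain.exponent - 1.0)


def test_optional_reference_implementation_cross_check():
    fooof = pytest.importorskip("fooof")
    logp = planted_spectrum(GRID, 0.5, 1.0, [(10.0, 0.6, 2.0)])
    fm = fooof.FOOOF(max_n_peaks=3, peak_width_limits=(1.5, 6.0), verbose=False)
    fm.fit(GRID, 10.0**logp)
    fit = parameterize_window(WindowSpectrum(GRID, logp))
    b_ref, x_ref = fm.aperiodic_params_
    assert abs(fit.aperiodic.offset - b_ref) <= 0.1 * max(abs(b_ref), 0.5)
    assert abs(fit.aperiodic.exponent - x_ref) <= 0.1 * abs(x_ref)
    cf_ref = fm.peak_params_[0][0]
    assert abs(fit.peaks[0].center_frequency - cf_ref) <= 0.1 * cf_ref
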