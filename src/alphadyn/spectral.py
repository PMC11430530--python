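"""Time-resolved parametrization of EEG power spectra.

Each channel's signal is short-time Fourier transformed (1-s Hann windows,
50% overlap), optionally averaged over ``n_avg`` consecutive periodograms,
and each windowed log10 spectrum over 1-40 Hz is decomposed into an aperiodic
component (offset ``b``, exponent ``x``; no knee) plus up to three Gaussian
peaks (center ``c`` in Hz, height ``a`` in log10 power above the aperiodic
fit, width ``w`` = Gaussian SD in Hz).  The alpha peak is the largest-height
peak with center inside 8-13 Hz; its parameters, the aperiodic parameters and
the goodness of fit form per-channel time series for downstream variability
features.

Numerical notes
---------------
* With ``debias=True`` (default) the known chi-square bias of the log
  periodogram, ``E[log10(chi2_2k / 2k)]`` with ``k`` the effective number of
  averaged periodograms, is subtracted so the log spectrum estimates
  ``log10 S(f)`` without offset bias even for small ``n_avg``.
* Printed peak-width limits (1.5-6 Hz) are interpreted as limits on ``2 w``,
  the full-width-like convention; the Gaussian SD is therefore bounded to
  [0.75, 3] Hz by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import get_window
from scipy.special import digamma

from . import _fitcore
from .simulate import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralSettings",
    "WindowSpectrum",
    "AperiodicFit",
    "PeakFit",
    "WindowFit",
    "ParameterTimeSeries",
    "compute_stft_psd",
    "fit_aperiodic",
    "fit_peaks",
    "parameterize_window",
    "select_alpha_peak",
    "parameterize_recording",
]


@dataclass(frozen=True)
class SpectralSettings:
    """All tunables of the time-resolved parametrization stage."""

    win_len: float = 1.0  # s
    overlap: float = 0.5
    f_range: Tuple[float, float] = (1.0, 40.0)
    n_avg: int = 5  # consecutive periodograms averaged per output spectrum
    pad_factor: int = 2  # zero-padding; 2 -> 0.5 Hz grid on 1-s windows
    max_n_peaks: int = 3
    min_peak_height: float = 0.1  # log10 power units (1 dB)
    peak_threshold: float = 2.0  # x SD of the flattened spectrum
    width_limits: Tuple[float, float] = (1.5, 6.0)  # on 2*w
    proximity_threshold: float = 0.75
    robust_percentile: float = 2.5
    debias: bool = True
    alpha_band: Tuple[float, float] = (8.0, 13.0)
    coverage_floor: float = 0.25

    @property
    def gauss_std_limits(self) -> Tuple[float, float]:
        return (self.width_limits[0] / 2.0, self.width_limits[1] / 2.0)


@dataclass
class WindowSpectrum:
    """One window's power spectrum on the restricted frequency grid."""

    freqs: np.ndarray
    log_power: np.ndarray
    window_index: int = 0
    window_time: float = 0.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.log_power = np.asarray(self.log_power, dtype=np.float64)
        if self.freqs.shape != self.log_power.shape:
            raise ValueError("freqs and log_power must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not (np.all(np.isfinite(self.freqs)) and np.all(np.isfinite(self.log_power))):
            raise ValueError("spectrum contains non-finite values")


@dataclass(frozen=True)
class AperiodicFit:
    offset: float
    exponent: float


@dataclass(frozen=True)
class PeakFit:
    center_frequency: float
    amplitude: float
    width: float


@dataclass
class WindowFit:
    aperiodic: AperiodicFit
    peaks: List[PeakFit]
    mse: float
    r_squared: float


@dataclass
class ParameterTimeSeries:
    """Per-channel time courses of the fitted spectral parameters.

    Alpha entries are NaN for windows without an in-band peak; ``status``
    is nonzero for windows whose fit failed (all parameters NaN there).
    """

    channel_names: List[str]
    window_times: np.ndarray
    offset: np.ndarray  # channels x windows
    exponent: np.ndarray
    alpha_cf: np.ndarray
    alpha_amplitude: np.ndarray
    alpha_width: np.ndarray
    mse: np.ndarray
    r_squared: np.ndarray
    alpha_coverage: np.ndarray  # per channel, fraction of windows with alpha
    flagged_channels: List[str] = field(default_factory=list)

    PARAMETERS = (
        "offset",
        "exponent",
        "alpha_cf",
        "alpha_amplitude",
        "alpha_width",
        "mse",
    )

    def parameter(self, name: str) -> np.ndarray:
        if name not in self.PARAMETERS and name != "r_squared":
            raise KeyError(f"unknown parameter {name!r}")
        return getattr(self, name)


def _log_bias(n_avg: int, overlap: float) -> float:
    """E[log10(mean of k overlapping Hann periodograms / S)].

    Overlapping (50%) Hann periodograms are correlated; the effective number
    of independent chi2_2 averages is reduced by the standard Welch factor
    (~0.167 lag-one power correlation for Hann at 50% overlap).
    """
    if n_avg <= 1:
        k_eff = 1.0
    else:
        rho = 0.167 if overlap > 0 else 0.0
        k_eff = n_avg / (1.0 + 2.0 * rho * (1.0 - 1.0 / n_avg))
    return float(np.log10(np.e) * (digamma(k_eff) - np.log(k_eff)))


def stft_log_psd(
    recording: Recording, settings: SpectralSettings = SpectralSettings()
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed log10 PSD for every channel.

    Returns ``(freqs, times, log_psd)`` with ``log_psd`` of shape
    (channels, windows, freqs); ``times`` are window centers in seconds.
    """
    fs = recording.fs
    if fs < 2 * settings.f_range[1]:
        raise ValueError(
            f"sampling rate {fs} Hz too low to resolve {settings.f_range[1]} Hz"
        )
    wl = int(round(settings.win_len * fs))
    if recording.n_samples < wl:
        raise ValueError("recording shorter than one analysis window")
    hop = int(round(wl * (1.0 - settings.overlap)))
    nfft = wl * settings.pad_factor
    win = get_window("hann", wl, fftbins=True)
    scale = 2.0 / (fs * np.dot(win, win))

    n_win = (recording.n_samples - wl) // hop + 1
    segs = np.lib.stride_tricks.sliding_window_view(recording.data, wl, axis=1)
    segs = segs[:, ::hop][:, :n_win]  # channels x windows x wl
    spec = np.fft.rfft(segs * win, n=nfft, axis=2)
    psd = (spec.real**2 + spec.imag**2) * scale

    k = settings.n_avg
    if k > 1:
        if n_win < k:
            raise ValueError("recording too short for the configured n_avg")
        csum = np.cumsum(psd, axis=1)
        psd = np.empty((psd.shape[0], n_win - k + 1, psd.shape[2]))
        psd[:, 0] = csum[:, k - 1] / k
        psd[:, 1:] = (csum[:, k:] - csum[:, : n_win - k]) / k

    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    fmask = (freqs >= settings.f_range[0]) & (freqs <= settings.f_range[1])
    logp = np.log10(psd[:, :, fmask])
    if settings.debias:
        logp -= _log_bias(k, settings.overlap)
    centers = (np.arange(logp.shape[1]) * hop + (wl + (k - 1) * hop) / 2.0) / fs
    return freqs[fmask], centers, logp


def compute_stft_psd(
    recording: Recording, settings: SpectralSettings = SpectralSettings()
) -> List[List[WindowSpectrum]]:
    """Spec-level STFT API: per channel, a list of `WindowSpectrum`."""
    freqs, times, logp = stft_log_psd(recording, settings)
    return [
        [
            WindowSpectrum(freqs, logp[ch, w], window_index=w, window_time=times[w])
            for w in range(logp.shape[1])
        ]
        for ch in range(logp.shape[0])
    ]


def fit_aperiodic(
    spectrum: WindowSpectrum,
    robust: bool = True,
    robust_percentile: float = 2.5,
) -> AperiodicFit:
    """Least-squares fit of ``log_power ~ b - x*log10(f)`` (no knee)."""
    if spectrum.freqs.size < 4:
        raise ValueError("need at least 4 frequency bins")
    if np.unique(spectrum.freqs).size < 2:
        raise ValueError("degenerate frequency grid")
    lf = np.log10(spectrum.freqs)
    if robust:
        b, x = _fitcore.robust_aperiodic(lf, spectrum.log_power, robust_percentile)
    else:
        b, x = _fitcore._ols(lf, spectrum.log_power)
    if x < 0:
        logger.warning("fitted aperiodic exponent is negative (%.3f)", x)
    return AperiodicFit(float(b), float(x))


def fit_peaks(
    flattened: WindowSpectrum,
    max_n: int = 3,
    min_height: float = 0.1,
    peak_threshold: float = 2.0,
    width_limits: Tuple[float, float] = (1.5, 6.0),
    proximity_threshold: float = 0.75,
) -> List[PeakFit]:
    """Extract up to ``max_n`` Gaussian peaks from a flattened spectrum.

    ``flattened`` must already have the aperiodic fit subtracted.  Iterative
    guessing, joint Gauss-Newton refit, then edge/overlap pruning; an empty
    list is a valid result.
    """
    w_lo, w_hi = width_limits[0] / 2.0, width_limits[1] / 2.0
    guesses = np.zeros((max_n, 3))
    k = _fitcore.guess_peaks(
        flattened.freqs,
        np.ascontiguousarray(flattened.log_power),
        max_n,
        min_height,
        peak_threshold,
        w_lo,
        w_hi,
        guesses,
    )
    if k == 0:
        return []
    ok = _fitcore.refit_peaks_gn(
        flattened.freqs, np.ascontiguousarray(flattened.log_power), guesses, k,
        w_lo, w_hi, 40,
    )
    if not ok:
        return []
    k = _fitcore.prune_peaks(flattened.freqs, guesses, k, proximity_threshold)
    return [PeakFit(*guesses[i]) for i in range(k)]


def parameterize_window(
    spectrum: WindowSpectrum, settings: SpectralSettings = SpectralSettings()
) -> WindowFit:
    """Full decomposition of one window into aperiodic fit plus peaks."""
    w_lo, w_hi = settings.gauss_std_limits
    peaks = np.zeros((settings.max_n_peaks, 3))
    lf = np.log10(spectrum.freqs)
    b, x, k, mse, r2, status = _fitcore.fit_window(
        spectrum.freqs,
        lf,
        np.ascontiguousarray(spectrum.log_power),
        settings.max_n_peaks,
        settings.min_peak_height,
        settings.peak_threshold,
        w_lo,
        w_hi,
        settings.proximity_threshold,
        settings.robust_percentile,
        peaks,
    )
    if status != _fitcore.OK:
        logger.warning("window fit failed; parameters set missing")
        return WindowFit(AperiodicFit(np.nan, np.nan), [], np.nan, np.nan)
    return WindowFit(
        AperiodicFit(float(b), float(x)),
        [PeakFit(*peaks[i]) for i in range(k)],
        float(mse),
        float(r2),
    )


def select_alpha_peak(
    peaks: Sequence[PeakFit], band: Tuple[float, float] = (8.0, 13.0)
) -> Optional[PeakFit]:
    """Largest-amplitude peak with center inside the alpha band, else None."""
    in_band = [p for p in peaks if band[0] <= p.center_frequency <= band[1]]
    if not in_band:
        return None
    return max(in_band, key=lambda p: p.amplitude)


def parameterize_recording(
    recording: Recording, settings: SpectralSettings = SpectralSettings()
) -> ParameterTimeSeries:
    """Per-channel, per-window parametrization of a whole recording.

    Channels whose alpha coverage (fraction of windows with a detected
    in-band peak) falls below ``settings.coverage_floor`` are flagged for
    exclusion reporting; no window is ever interpolated.
    """
    freqs, times, logp = stft_log_psd(recording, settings)
    n_ch, n_win = logp.shape[0], logp.shape[1]
    w_lo, w_hi = settings.gauss_std_limits
    lo, hi = settings.alpha_band

    shape = (n_ch, n_win)
    out = {
        name: np.full(shape, np.nan)
        for name in (
            "offset",
            "exponent",
            "alpha_cf",
            "alpha_amplitude",
            "alpha_width",
            "mse",
            "r_squared",
        )
    }
    coverage = np.zeros(n_ch)
    for ch in range(n_ch):
        offs, exps, nps, mses, r2s, status, peaks = _fitcore.fit_windows(
            np.ascontiguousarray(freqs),
            np.ascontiguousarray(logp[ch]),
            settings.max_n_peaks,
            settings.min_peak_height,
            settings.peak_threshold,
            w_lo,
            w_hi,
            settings.proximity_threshold,
            settings.robust_percentile,
        )
        good = status == _fitcore.OK
        out["offset"][ch, good] = offs[good]
        out["exponent"][ch, good] = exps[good]
        out["mse"][ch, good] = mses[good]
        out["r_squared"][ch, good] = r2s[good]
        # vectorized alpha selection: largest height among in-band peaks
        cf = peaks[:, :, 0]
        amp = peaks[:, :, 1].copy()
        valid = np.zeros_like(amp, dtype=bool)
        for w in range(n_win):
            valid[w, : nps[w]] = good[w]
        amp[~valid | (cf < lo) | (cf > hi)] = -np.inf
        best = np.argmax(amp, axis=1)
        has_alpha = amp[np.arange(n_win), best] > -np.inf
        rows = np.nonzero(has_alpha)[0]
        out["alpha_cf"][ch, rows] = peaks[rows, best[rows], 0]
        out["alpha_amplitude"][ch, rows] = peaks[rows, best[rows], 1]
        out["alpha_width"][ch, rows] = peaks[rows, best[rows], 2]
        coverage[ch] = has_alpha.mean()

    flagged = [
        recording.channel_names[ch]
        for ch in range(n_ch)
        if coverage[ch] < settings.coverage_floor
    ]
    if flagged:
        logger.warning(
            "subject %s/%s: %d channel(s) below alpha coverage floor %.2f: %s",
            recording.subject_id,
            recording.condition,
            len(flagged),
            settings.coverage_floor,
            ",".join(flagged),
        )
    return ParameterTimeSeries(
        channel_names=list(recording.channel_names),
        window_times=times,
        offset=out["offset"],
        exponent=out["exponent"],
        alpha_cf=out["alpha_cf"],
        alpha_amplitude=out["alpha_amplitude"],
        alpha_width=out["alpha_width"],
        mse=out["mse"],
        r_squared=out["r_squared"],
        alpha_coverage=coverage,
        flagged_channels=flagged,
    )
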