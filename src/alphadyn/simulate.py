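"""Synthetic resting-state EEG with known periodic and aperiodic ground truth.

Each channel is the sum of two parts:

* an aperiodic (1/f-like) process whose one-sided power spectral density
  follows ``S(f) = 10**offset * f**(-exponent)`` over the analysis range,
  synthesized by frequency-domain shaping of uniform random phases, and
* an alpha-band oscillation realized as a phase-continuous frequency-modulated
  sinusoid whose instantaneous frequency follows a piecewise-constant center
  frequency (CF) trajectory drawn from a configurable stochastic process.

The CF trajectory is the controlled ground truth for the pipeline's headline
quantity: the standard deviation of the alpha peak center frequency over time.
Cohorts pair two groups (high/low hypnotic susceptibility) with two recording
conditions (pre/post induction); the group-x-condition parameter map encodes
the planted effect, e.g. larger post-induction CF jitter in the high group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Tuple

import numpy as np

__all__ = [
    "AperiodicSpec",
    "AlphaDynamicsSpec",
    "CohortDesign",
    "Recording",
    "CF_BOUNDS",
    "simulate_aperiodic_signal",
    "make_cf_trajectory",
    "simulate_channel",
    "simulate_subject",
    "simulate_cohort",
    "null_design",
    "hypnosis_contrast_design",
]

#: Allowed range for alpha center frequencies, Hz.
CF_BOUNDS: Tuple[float, float] = (8.0, 13.0)

#: Low-frequency plateau edge, Hz.  Below this the synthesized aperiodic PSD is
#: held constant at S(_PLATEAU_HZ).  Real EEG is high-pass filtered, so the
#: 1/f law does not extend to DC; without the plateau, sub-Hz power for steep
#: exponents leaks through the 1-s analysis window into the lowest fitted bins
#: and biases exponent recovery.
_PLATEAU_HZ = 1.0

#: Calibration constant mapping requested log10 peak height `a` to sinusoid
#: amplitude: A = _PEAK_CAL * sqrt(S_ap(cf) * (10**a - 1)).  sqrt(3) is the
#: analytic value for a Hann-window ENBW of 1.5 Hz; the extra 10**(-0.075)
#: compensates the Gaussian-vs-Hann line-shape mismatch of the downstream fit
#: (the fitted Gaussian height otherwise reads ~0.15 decades high).  Checked
#: empirically by a round-trip unit test.
_PEAK_CAL = np.sqrt(3.0) * 10.0 ** (-0.075)

Group = Literal["high", "low"]
Condition = Literal["pre", "post"]


@dataclass(frozen=True)
class AperiodicSpec:
    """Broadband 1/f-like component: ``log10 S(f) = offset - exponent*log10 f``."""

    offset: float = 0.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.offset) and np.isfinite(self.exponent)):
            raise ValueError("aperiodic offset and exponent must be finite")
        if self.exponent < 0:
            raise ValueError("aperiodic exponent must be >= 0")


@dataclass(frozen=True)
class AlphaDynamicsSpec:
    """Alpha-peak parameters and the stochastic process of its center frequency.

    Parameters
    ----------
    mean_cf
        Mean center frequency, Hz; must lie within ``CF_BOUNDS``.
    cf_jitter_sd
        SD of the CF process, Hz.  For ``iid_gaussian`` this is the marginal
        SD before clipping; for ``bounded_random_walk`` the per-step SD.
    amplitude
        Peak height above the aperiodic component at the peak, log10(power).
        0 disables the oscillation entirely.
    width
        Nominal Gaussian SD of the peak, Hz (descriptive; the synthesized
        oscillation is a narrow FM line whose analysis width is set by the
        spectral window).
    trajectory_kind
        ``iid_gaussian`` (independent draws per state) or
        ``bounded_random_walk`` (reflected walk within ``CF_BOUNDS``).
    dwell
        Duration each drawn CF value is held, seconds.  Default 3 s: IAPF
        drift in real EEG is autocorrelated over seconds, and states shorter
        than the spectral estimator's temporal resolution are attenuated by
        any windowed method.
    """

    mean_cf: float = 10.0
    cf_jitter_sd: float = 0.4
    amplitude: float = 1.0
    width: float = 2.0
    trajectory_kind: str = "iid_gaussian"
    dwell: float = 3.0

    def __post_init__(self) -> None:
        if not (CF_BOUNDS[0] <= self.mean_cf <= CF_BOUNDS[1]):
            raise ValueError(f"mean_cf must lie within {CF_BOUNDS}")
        if self.cf_jitter_sd < 0:
            raise ValueError("cf_jitter_sd must be >= 0")
        if not (1.5 <= self.width <= 6.0):
            raise ValueError("width must lie within [1.5, 6] Hz")
        if self.trajectory_kind not in ("iid_gaussian", "bounded_random_walk"):
            raise ValueError(f"unknown trajectory_kind {self.trajectory_kind!r}")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")


@dataclass
class Recording:
    """One subject-condition multichannel time series."""

    data: np.ndarray  # channels x samples
    fs: float
    channel_names: List[str]
    subject_id: str
    condition: str
    group: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class CohortDesign:
    """Two-group, two-condition cohort layout and generative parameters."""

    n_high: int = 19
    n_low: int = 19
    n_channels: int = 64
    duration: float = 300.0
    fs: float = 250.0
    group_condition_params: Dict[
        Tuple[str, str], Tuple[AperiodicSpec, AlphaDynamicsSpec]
    ] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 2 or self.n_low < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.fs <= 80:
            raise ValueError("fs must exceed 80 Hz so 40 Hz is resolvable")
        if self.duration < 10:
            raise ValueError("duration must be at least 10 s")


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_aperiodic_signal(
    spec: AperiodicSpec, duration: float, fs: float, seed=None
) -> np.ndarray:
    """Synthesize a signal whose PSD follows the aperiodic model.

    Frequency-domain shaping: deterministic amplitudes proportional to
    ``sqrt(S(f))`` with uniform random phases, inverse-transformed.  The
    Welch-estimated PSD of the output, regressed in log10-log10 space over
    1-40 Hz, recovers slope ``-exponent`` and intercept ``offset``.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration * fs must be at least 2 samples")
    rng = _rng_from(seed)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    f_eff = np.maximum(freqs[pos], _PLATEAU_HZ)
    psd = 10.0 ** spec.offset * f_eff ** (-spec.exponent)
    # |X_k| such that the one-sided periodogram equals the target density
    amp[pos] = np.sqrt(fs * n * psd / 2.0)
    phases = np.exp(2j * np.pi * rng.random(freqs.size))
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 1.0  # Nyquist bin must be real
    return np.fft.irfft(amp * phases, n=n)


def make_cf_trajectory(
    spec: AlphaDynamicsSpec, n_windows: int, seed=None
) -> np.ndarray:
    """Draw the per-state center-frequency trajectory, clipped to ``CF_BOUNDS``."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = _rng_from(seed)
    lo, hi = CF_BOUNDS
    if spec.trajectory_kind == "iid_gaussian":
        traj = rng.normal(spec.mean_cf, spec.cf_jitter_sd, n_windows)
        return np.clip(traj, lo, hi)
    if spec.trajectory_kind == "bounded_random_walk":
        steps = rng.normal(0.0, spec.cf_jitter_sd, n_windows)
        steps[0] = 0.0
        walk = spec.mean_cf + np.cumsum(steps)
        # reflect into [lo, hi]: fold the walk at the boundaries
        span = hi - lo
        folded = np.mod(walk - lo, 2 * span)
        return lo + np.where(folded > span, 2 * span - folded, folded)
    raise ValueError(f"unknown trajectory_kind {spec.trajectory_kind!r}")


def simulate_channel(
    ap: AperiodicSpec,
    alpha: AlphaDynamicsSpec,
    duration: float,
    fs: float,
    seed=None,
    return_trajectory: bool = False,
):
    """Aperiodic background plus a phase-continuous FM alpha oscillation.

    The oscillation's instantaneous frequency is the CF trajectory held for
    ``alpha.dwell`` seconds per state; its amplitude is calibrated so the
    fitted spectral peak height above the aperiodic component is
    approximately ``alpha.amplitude`` log10 units.  With
    ``return_trajectory=True`` also returns the generating CF trajectory —
    the ground truth against which recovered alpha dynamics are judged.
    """
    rng = _rng_from(seed)
    n = int(round(duration * fs))
    sig = simulate_aperiodic_signal(ap, duration, fs, rng)
    if alpha.amplitude == 0:
        return (sig, np.empty(0)) if return_trajectory else sig
    n_states = int(np.ceil(duration / alpha.dwell))
    traj = make_cf_trajectory(alpha, n_states, rng)
    samples_per_state = int(round(alpha.dwell * fs))
    inst_f = np.repeat(traj, samples_per_state)[:n]
    if inst_f.size < n:  # trailing partial state
        inst_f = np.pad(inst_f, (0, n - inst_f.size), mode="edge")
    phase = 2.0 * np.pi * (np.cumsum(inst_f) / fs) + 2.0 * np.pi * rng.random()
    s_ap_cf = 10.0 ** ap.offset * alpha.mean_cf ** (-ap.exponent)
    amp = _PEAK_CAL * np.sqrt(s_ap_cf * (10.0 ** alpha.amplitude - 1.0))
    out = sig + amp * np.sin(phase)
    return (out, traj) if return_trajectory else out


def _child_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))


def simulate_subject(
    design: CohortDesign,
    subject_id: str,
    group: str,
    condition: str,
    subject_index: int,
    condition_index: int,
) -> Recording:
    """Simulate one subject-condition recording with per-channel child seeds.

    Channels are statistically independent (no volume conduction); child
    seeds derive deterministically from (design.seed, subject, condition,
    channel) so cohorts reproduce subject-by-subject.
    """
    try:
        ap, alpha = design.group_condition_params[(group, condition)]
    except KeyError as exc:
        raise KeyError(
            f"design has no parameters for group={group!r}, condition={condition!r}"
        ) from exc
    data = np.empty(
        (design.n_channels, int(round(design.duration * design.fs))), dtype=np.float64
    )
    for ch in range(design.n_channels):
        ss = _child_seed(design.seed, subject_index, condition_index, ch)
        data[ch] = simulate_channel(
            ap, alpha, design.duration, design.fs, np.random.default_rng(ss)
        )
    names = [f"ch{ch:02d}" for ch in range(design.n_channels)]
    return Recording(data, design.fs, names, subject_id, condition, group)


def simulate_cohort(design: CohortDesign) -> List[Recording]:
    """All subjects, both conditions: ``2 * (n_high + n_low)`` recordings."""
    recs: List[Recording] = []
    groups = ["high"] * design.n_high + ["low"] * design.n_low
    for idx, group in enumerate(groups):
        sid = f"{group}{idx:02d}"
        for cidx, condition in enumerate(("pre", "post")):
            recs.append(
                simulate_subject(design, sid, group, condition, idx, cidx)
            )
    return recs


def _uniform_params(ap: AperiodicSpec, alpha: AlphaDynamicsSpec):
    return {
        (g, c): (ap, alpha) for g in ("high", "low") for c in ("pre", "post")
    }


def null_design(
    n_high: int = 20,
    n_low: int = 20,
    n_channels: int = 8,
    duration: float = 120.0,
    fs: float = 250.0,
    seed: int = 0,
    ap: AperiodicSpec | None = None,
    alpha: AlphaDynamicsSpec | None = None,
) -> CohortDesign:
    """Cohort with identical generative parameters in every group x condition.

    Downstream decoding of any feature from such a cohort is at chance.
    """
    ap = ap or AperiodicSpec()
    alpha = alpha or AlphaDynamicsSpec()
    return CohortDesign(
        n_high, n_low, n_channels, duration, fs, _uniform_params(ap, alpha), seed
    )


def hypnosis_contrast_design(
    n_high: int = 20,
    n_low: int = 20,
    n_channels: int = 8,
    duration: float = 120.0,
    fs: float = 250.0,
    seed: int = 0,
    jitter_high_post: float = 1.0,
    jitter_base: float = 0.4,
) -> CohortDesign:
    """The study-like effect: groups identical pre-induction; post-induction
    CF jitter is larger in the high-susceptibility group, all else equal."""
    ap = AperiodicSpec()
    base = AlphaDynamicsSpec(cf_jitter_sd=jitter_base)
    boosted = replace(base, cf_jitter_sd=jitter_high_post)
    params = {
        ("high", "pre"): (ap, base),
        ("low", "pre"): (ap, base),
        ("high", "post"): (ap, boosted),
        ("low", "post"): (ap, base),
    }
    return CohortDesign(n_high, n_low, n_channels, duration, fs, params, seed)
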