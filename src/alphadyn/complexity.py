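"""Lempel-Ziv (LZ76) complexity of binarized EEG epochs.

The recording is cut into non-overlapping epochs (default 60 s), each epoch
is binarized around a per-epoch threshold (median by default; values at or
above the threshold map to 1), and the LZ76 exhaustive production history is
parsed: scanning left to right, the current phrase is extended while it can
be reproduced from the prior history, and every non-reproducible extension
closes a component.  The raw complexity is the component count; the
normalized value ``c * log2(n) / n`` approaches 1 for incompressible
(fair-coin) sequences and is the per-channel feature fed to decoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
from numba import njit

from .simulate import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "BinarySequence",
    "LZResult",
    "binarize_epoch",
    "lz76_complexity",
    "normalized_lz",
    "compute_lz_features",
]


@dataclass
class BinarySequence:
    bits: np.ndarray
    source_channel: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.size == 0:
            raise ValueError("binary sequence must be non-empty")
        if np.any(self.bits > 1):
            raise ValueError("sequence contains non-binary symbols")


@dataclass
class LZResult:
    channel_names: List[str]
    raw: np.ndarray  # channels x epochs, component counts
    normalized: np.ndarray  # channels x epochs
    mean_raw: np.ndarray  # per channel
    mean_normalized: np.ndarray  # per channel


def binarize_epoch(signal: np.ndarray, threshold_rule: str = "median") -> BinarySequence:
    """Threshold one epoch into bits: values >= threshold map to 1.

    Ties at the threshold deterministically map to 1, so a constant signal
    becomes all ones (logged).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 2:
        raise ValueError("epoch must have at least 2 samples")
    if threshold_rule == "median":
        thr = np.median(signal)
    elif threshold_rule == "mean":
        thr = np.mean(signal)
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    if np.ptp(signal) == 0:
        logger.warning("constant epoch: binarizes to all ones")
    return BinarySequence((signal >= thr).astype(np.uint8))


@njit(cache=False)
def _lz76(bits):
    """Exhaustive-history LZ76 component count (Kaspar-Schuster scan)."""
    n = bits.size
    c = 1
    l = 1
    if l >= n:
        return c
    i = 0
    k = 1
    kmax = 1
    while True:
        if bits[i + k - 1] == bits[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


def lz76_complexity(seq: BinarySequence | np.ndarray) -> int:
    """Number of components in the exhaustive LZ76 parsing."""
    bits = seq.bits if isinstance(seq, BinarySequence) else np.asarray(seq)
    if bits.size == 0:
        raise ValueError("empty sequence")
    if np.any((bits != 0) & (bits != 1)):
        raise ValueError("sequence contains non-binary symbols")
    return int(_lz76(np.ascontiguousarray(bits, dtype=np.uint8)))


def normalized_lz(raw: float, n: int) -> float:
    """Shannon normalization ``c * log2(n) / n``."""
    return float(raw) * np.log2(n) / n


def compute_lz_features(
    recording: Recording,
    epoch_len: float = 60.0,
    threshold_rule: str = "median",
) -> LZResult:
    """Per-channel LZ76 complexity over non-overlapping epochs.

    A trailing partial epoch is dropped; the recording must contain at least
    one full epoch.
    """
    samples = int(round(epoch_len * recording.fs))
    n_epochs = recording.n_samples // samples
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    raw = np.empty((recording.n_channels, n_epochs))
    norm = np.empty_like(raw)
    for ch in range(recording.n_channels):
        for e in range(n_epochs):
            seg = recording.data[ch, e * samples : (e + 1) * samples]
            bits = binarize_epoch(seg, threshold_rule)
            c = lz76_complexity(bits)
            raw[ch, e] = c
            norm[ch, e] = normalized_lz(c, samples)
    return LZResult(
        channel_names=list(recording.channel_names),
        raw=raw,
        normalized=norm,
        mean_raw=raw.mean(axis=1),
        mean_normalized=norm.mean(axis=1),
    )
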