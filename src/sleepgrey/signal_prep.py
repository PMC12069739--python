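"""Raw EEG/EOG preprocessing for the staging pipeline.

The pipeline applied to every channel, in order, is: zero-phase bandpass
(0.3–32 Hz), band-limited resampling to 64 Hz, and robust amplitude
normalization (subtract the median, divide by the interquartile range,
computed per channel per recording).  IQR normalization makes the pipeline
invariant to affine rescaling of the raw input, which is what lets one model
serve recordings whose peak-to-peak amplitudes differ by orders of
magnitude (e.g. self-applied forehead montages vs. standard derivations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import EPOCH_SECONDS, EpochGrid

__all__ = [
    "SignalChannel",
    "bandpass",
    "resample",
    "iqr_normalize",
    "epoch_slice",
    "preprocess",
    "read_edf",
    "DEFAULT_BAND",
    "TARGET_FS",
]

#: Default bandpass corner frequencies in Hz.
DEFAULT_BAND = (0.3, 32.0)

#: Sampling rate the staging models expect, in Hz.
TARGET_FS = 64.0


@dataclass(frozen=True)
class SignalChannel:
    """A single EEG/EOG derivation: samples (µV), sampling rate, label."""

    samples: np.ndarray = field(repr=False)
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.isfinite(samples).all():
            raise ValueError(f"non-finite samples in channel {self.label!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


def bandpass(
    ch: SignalChannel,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = 8,
) -> SignalChannel:
    """Zero-phase Butterworth bandpass.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    output has no phase lag and epoch alignment is preserved; the effective
    magnitude response is the squared response of the designed filter.
    """
    nyq = ch.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for fs={ch.fs} Hz "
            f"(need 0 < low < high < {nyq})"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=ch.fs, output="sos")
    out = sps.sosfiltfilt(sos, ch.samples)
    return SignalChannel(out, ch.fs, ch.label)


def resample(ch: SignalChannel, target_fs: float = TARGET_FS) -> SignalChannel:
    """Band-limited (polyphase) resampling to *target_fs*."""
    if not (target_fs > 0):
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == ch.fs:
        return ch
    frac = Fraction(target_fs / ch.fs).limit_denominator(1000)
    out = sps.resample_poly(ch.samples, frac.numerator, frac.denominator)
    return SignalChannel(out, target_fs, ch.label)


def iqr_normalize(ch: SignalChannel, center: bool = True) -> SignalChannel:
    """Robust per-recording normalization: (x - median) / IQR.

    Median subtraction is configurable (``center=False`` divides only); a
    constant signal has zero IQR and is rejected.
    """
    q1, med, q3 = np.percentile(ch.samples, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError(
            f"channel {ch.label!r} has zero interquartile range; "
            "cannot normalize a (near-)constant signal"
        )
    out = (ch.samples - med) / iqr if center else ch.samples / iqr
    return SignalChannel(out, ch.fs, ch.label)


def epoch_slice(ch: SignalChannel, grid: EpochGrid | None = None) -> np.ndarray:
    """Cut a channel into per-epoch blocks of exactly ``fs * 30`` samples.

    Returns an ``(n_epochs, fs*30)`` array.  A trailing partial epoch is
    dropped with a warning; a recording shorter than one epoch is an error.
    If *grid* is given, the channel must cover at least ``grid.n_epochs``
    epochs and exactly that many blocks are returned.
    """
    spe = ch.fs * EPOCH_SECONDS
    if spe != int(spe):
        raise ValueError(f"fs={ch.fs} Hz does not give a whole number of samples per epoch")
    spe = int(spe)
    n_full = ch.samples.size // spe
    if n_full == 0:
        raise ValueError(
            f"channel {ch.label!r} is shorter than one {EPOCH_SECONDS:.0f}-s epoch"
        )
    if grid is not None:
        if n_full < grid.n_epochs:
            raise ValueError(
                f"channel {ch.label!r} covers {n_full} epochs, "
                f"grid requires {grid.n_epochs}"
            )
        n_full = grid.n_epochs
    if ch.samples.size > n_full * spe:
        warnings.warn(
            f"dropping {ch.samples.size - n_full * spe} trailing samples of "
            f"channel {ch.label!r} (partial epoch)",
            stacklevel=2,
        )
    return ch.samples[: n_full * spe].reshape(n_full, spe)


def preprocess(
    ch: SignalChannel,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    target_fs: float = TARGET_FS,
    center: bool = True,
) -> SignalChannel:
    """Full pipeline: bandpass -> resample -> IQR-normalize."""
    return iqr_normalize(resample(bandpass(ch, low_hz, high_hz), target_fs), center=center)


def read_edf(path: str | Path, channels: list[str] | None = None) -> list[SignalChannel]:
    """Optional EDF/EDF+ ingest (requires ``mne``); raw arrays are the
    primary interface."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(path, include=channels, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    return [
        SignalChannel(data[i] * 1e6, fs, name)  # mne returns volts
        for i, name in enumerate(raw.ch_names)
    ]
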