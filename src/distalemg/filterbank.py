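"""Preprocessing and feature extraction for the envelope-estimation pipeline.

The per-sample "muscle activity" throughout is the MAV (mean absolute
value): a trailing window average of the rectified signal,

    S(k) = (1/tau) * sum_{j=0..tau-1} |x(k-j)|,

with tau the window width in samples (0.1 s by default).  Target-muscle
channels yield a 6-row envelope matrix L(k).  Distal channels are
expanded through a multi-bandpass filter bank — the full 20-500 Hz band
followed by a 150 Hz window slid in 10 Hz steps, 35 bands in all — and
the MAV of every band of every channel forms the 175-row feature matrix
A(k).  Restricting the bank to the single full band reproduces the
plain single-bandpass baseline features.

Filters: 4th-order Butterworth applied forward-backward (zero phase, so
activation-onset timing is preserved) and a quality-30 IIR notch at the
mains frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import DISTAL_LABELS, MUSCLE_LABELS, ParameterError, SignalRecord


@dataclass(frozen=True)
class FilterBankSpec:
    """Band layout: the full band, then sliding windows across the search range."""

    full_band: tuple[float, float] = (20.0, 500.0)
    window_width: float = 150.0
    step: float = 10.0
    search_low: float = 20.0
    search_high: float = 500.0

    def __post_init__(self) -> None:
        if self.window_width <= 0 or self.step <= 0:
            raise ParameterError("window_width and step must be positive")
        lo, hi = self.full_band
        if not 0 < lo < hi:
            raise ParameterError("full_band must satisfy 0 < low < high")

    @classmethod
    def single_band(cls, band: tuple[float, float] = (20.0, 500.0)) -> "FilterBankSpec":
        """Degenerate spec whose band list is just the full band (the baseline)."""
        lo, hi = band
        return cls(full_band=band, window_width=hi - lo, step=hi - lo, search_low=lo, search_high=lo)


def build_band_list(spec: FilterBankSpec) -> list[tuple[float, float]]:
    """Ordered band list: full band first, then the shifted windows.

    With the defaults this yields 35 bands: (20, 500), (20, 170),
    (30, 180), ..., (350, 500).
    """
    bands = [tuple(spec.full_band)]
    p = spec.search_low
    while p + spec.window_width <= spec.search_high + 1e-9:
        bands.append((p, p + spec.window_width))
        p += spec.step
    return bands


def window_samples(sampling_rate: float, window_seconds: float = 0.1) -> int:
    """MAV window width tau in samples (0.1 s at 2 kHz -> 200)."""
    tau = int(round(sampling_rate * window_seconds))
    if tau < 1:
        raise ParameterError("MAV window shorter than one sample")
    return tau


def mav(signal, tau: int) -> np.ndarray:
    """Trailing-window mean absolute value; same length as the input.

    For the first tau-1 samples the average runs over the k+1 samples
    available so far (partial window), avoiding the startup bias that
    zero-padding would introduce.  Works on 1-D signals or (channels, n)
    matrices (windowed along the last axis).
    """
    if tau < 1 or int(tau) != tau:
        raise ParameterError("tau must be a positive integer")
    tau = int(tau)
    x = np.abs(np.asarray(signal, dtype=float))
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]
    csum = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x, axis=-1)], axis=-1)
    k = np.arange(n)
    lo = np.maximum(0, k + 1 - tau)
    out = (csum[:, k + 1] - csum[:, lo]) / np.minimum(k + 1, tau)
    return out[0] if one_d else out


def notch_filter(record: SignalRecord, mains_hz: float = 50.0, quality: float = 30.0) -> SignalRecord:
    """Zero-phase IIR notch at the mains frequency on every channel."""
    nyq = record.sampling_rate / 2
    if not 0 < mains_hz < nyq:
        raise ParameterError(f"mains frequency {mains_hz} Hz outside (0, Nyquist={nyq})")
    b, a = sps.iirnotch(mains_hz, quality, fs=record.sampling_rate)
    filtered = sps.filtfilt(b, a, record.samples, axis=-1)
    return record.copy_with(filtered)


def bandpass_filter(
    signal, low_hz: float, high_hz: float, sampling_rate: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, no group delay).

    A high edge at or above Nyquist is clipped to 0.99 x Nyquist with a
    warning; recordings sampled at 1 kHz therefore still accept the
    default 20-500 Hz band.
    """
    nyq = sampling_rate / 2
    if not 0 < low_hz < high_hz:
        raise ParameterError(f"invalid band ({low_hz}, {high_hz})")
    if high_hz > nyq:
        raise ParameterError(f"band high edge {high_hz} Hz above Nyquist {nyq} Hz")
    if high_hz >= 0.999 * nyq:
        clipped = 0.99 * nyq
        warnings.warn(
            f"band high edge {high_hz} Hz collides with Nyquist {nyq} Hz; "
            f"clipping to {clipped} Hz",
            stacklevel=2,
        )
        high_hz = clipped
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


@dataclass(frozen=True)
class PreprocessConfig:
    mains_hz: float = 50.0
    notch_quality: float = 30.0
    target_band: tuple[float, float] = (20.0, 500.0)
    window_seconds: float = 0.1


@dataclass
class TargetEnvelopeMatrix:
    """MAV envelopes of the six target muscles, L(k): (6, n)."""

    values: np.ndarray
    tau: int
    sampling_rate: float
    labels: list[str] = field(default_factory=lambda: list(MUSCLE_LABELS))


@dataclass
class FeatureMatrix:
    """Per-band MAV features of the distal channels, A(k): (channels x bands, n).

    Rows are channel-major, band-minor: all 35 bands of A1, then of A2, ...
    Row labels read e.g. ``A3_150-300Hz``.
    """

    values: np.ndarray
    bands: list[tuple[float, float]]
    channel_labels: list[str]
    tau: int
    sampling_rate: float

    @property
    def row_labels(self) -> list[str]:
        return [
            f"{ch}_{lo:g}-{hi:g}Hz"
            for ch in self.channel_labels
            for (lo, hi) in self.bands
        ]


def extract_target_envelopes(
    record: SignalRecord,
    tau: int | None = None,
    preprocess: PreprocessConfig = PreprocessConfig(),
) -> TargetEnvelopeMatrix:
    """Notch -> 20-500 Hz bandpass -> MAV for the six target channels."""
    if record.n_channels != len(MUSCLE_LABELS):
        raise ParameterError(f"expected 6 target channels, got {record.n_channels}")
    if tau is None:
        tau = window_samples(record.sampling_rate, preprocess.window_seconds)
    clean = notch_filter(record, preprocess.mains_hz, preprocess.notch_quality)
    banded = bandpass_filter(clean.samples, *preprocess.target_band, record.sampling_rate)
    return TargetEnvelopeMatrix(mav(banded, tau), tau, record.sampling_rate, list(record.channel_labels))


def extract_distal_features(
    record: SignalRecord,
    spec: FilterBankSpec = FilterBankSpec(),
    tau: int | None = None,
    preprocess: PreprocessConfig = PreprocessConfig(),
) -> FeatureMatrix:
    """Per distal channel: notch, then MAV of every band in the bank.

    Rows are concatenated channel-major (all bands of A1, then A2, ...).
    """
    if record.n_channels != len(DISTAL_LABELS):
        raise ParameterError(f"expected 5 distal channels, got {record.n_channels}")
    if tau is None:
        tau = window_samples(record.sampling_rate, preprocess.window_seconds)
    bands = build_band_list(spec)
    nyq = record.sampling_rate / 2
    for lo, hi in bands:
        if hi > nyq:
            raise ParameterError(
                f"band ({lo}, {hi}) Hz exceeds Nyquist {nyq} Hz at fs={record.sampling_rate}"
            )
    clean = notch_filter(record, preprocess.mains_hz, preprocess.notch_quality)
    rows = []
    for ch in clean.samples:
        for lo, hi in bands:
            rows.append(mav(bandpass_filter(ch, lo, hi, record.sampling_rate), tau))
    return FeatureMatrix(
        np.vstack(rows), bands, list(record.channel_labels), tau, record.sampling_rate
    )
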