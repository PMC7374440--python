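"""EMG conditioning: filtering, envelope extraction and normalization.

Surface EMG is a broadband interference signal whose amplitude envelope
indexes muscle activation. The pipeline here mirrors common practice for
biofeedback and coherence work: a 15-450 Hz band-pass isolates the
physiological band, rectify-and-average (causal moving window) yields the
real-time feedback envelope, and the Hilbert analytic magnitude yields the
envelope used for spectral analysis. Two normalizations are supported:
division by the amplitude recorded during a maximal power grip (producing
fraction-of-maximum units) and Z-scoring against a reference session's
mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import SignalRecord


@dataclass
class EnvelopeSeries:
    """Amplitude envelope sampled at ``output_rate``.

    ``values[k]`` is the envelope at time ``(k + 1) / output_rate`` seconds
    (a causal convention: each tick summarizes the window ending at it).
    """

    values: np.ndarray
    output_rate: float
    window_length: float
    source_channel: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 1) / self.output_rate

    def slice(self, start: float, end: float) -> np.ndarray:
        """Envelope samples with time in (start, end]."""
        t = self.times
        return self.values[(t > start + 1e-9) & (t <= end + 1e-9)]


@dataclass
class NormalizationReference:
    """Per-channel scale/offset for envelope normalization.

    ``power_grip_max``: divide by ``scale`` (offset fixed at 0), giving
    fraction-of-maximum. ``session_zscore``: ``(x - offset) / scale`` with
    the reference session's mean and SD.
    """

    kind: str
    scale: dict[str, float]
    offset: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("power_grip_max", "session_zscore"):
            raise ValueError(f"unknown normalization kind {self.kind!r}")
        for ch, s in self.scale.items():
            if s <= 0:
                raise ValueError(f"scale for channel {ch!r} must be positive")
        if self.kind == "power_grip_max":
            self.offset = {ch: 0.0 for ch in self.scale}


def design_bandpass(low: float, high: float, order: int, sampling_rate: float) -> np.ndarray:
    """Butterworth band-pass as second-order sections."""
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band corners ({low}, {high}) must satisfy 0 < low < high < Nyquist ({nyq})"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(
    record: SignalRecord,
    low: float,
    high: float,
    order: int = 4,
    zero_phase: bool = True,
    channels: list[str] | None = None,
) -> SignalRecord:
    """Band-pass filter a record (all channels, or a subset of roles).

    ``zero_phase`` applies the filter forward and backward (``sosfiltfilt``),
    doubling the magnitude roll-off and cancelling phase distortion — the
    convention for offline analysis. With ``zero_phase=False`` the causal
    single-pass filter is used.
    """
    sos = design_bandpass(low, high, order, record.sampling_rate)
    out = record.samples.copy()
    cols = (
        range(record.n_channels)
        if channels is None
        else [record.channel_index(r) for r in channels]
    )
    for j in cols:
        if zero_phase:
            out[:, j] = sps.sosfiltfilt(sos, record.samples[:, j])
        else:
            out[:, j] = sps.sosfilt(sos, record.samples[:, j])
    return record.with_samples(out)


def moving_envelope(
    record: SignalRecord,
    channel: str,
    window: float,
    output_rate: float | None = None,
) -> EnvelopeSeries:
    """Causal rectified moving-average envelope.

    Each output tick at time t holds the mean of ``|x|`` over the trailing
    window ``(t - window, t]``. Ticks earlier than one full window average
    over the samples available so far (no padding). The envelope is emitted
    at ``output_rate`` (default: the input rate), matching a real-time
    feedback loop that polls the smoothed amplitude at its own rate.
    """
    fs = record.sampling_rate
    if window <= 0:
        raise ValueError("window must be positive")
    if output_rate is None:
        output_rate = fs
    if output_rate > fs:
        raise ValueError("output_rate cannot exceed the sampling rate")
    n = record.n_samples
    w_samples = int(round(window * fs))
    if w_samples < 1 or w_samples > n:
        raise ValueError("window must contain at least 1 sample and fit in the record")

    x = np.abs(record.channel(channel))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n_out = int(np.floor(n / fs * output_rate + 1e-9))
    ticks = (np.arange(1, n_out + 1)) / output_rate
    ends = np.minimum(np.floor(ticks * fs + 1e-9).astype(int), n)
    starts = np.maximum(ends - w_samples, 0)
    values = (csum[ends] - csum[starts]) / (ends - starts)
    return EnvelopeSeries(values, output_rate, window, channel)


def hilbert_envelope(record: SignalRecord, channel: str) -> EnvelopeSeries:
    """Magnitude of the analytic signal (Hilbert transform envelope).

    The channel should already be band-passed; the analytic magnitude of a
    narrow-to-moderate-band signal tracks its instantaneous amplitude.
    """
    x = record.channel(channel)
    env = np.abs(sps.hilbert(x))
    return EnvelopeSeries(env, record.sampling_rate, 0.0, channel)


def standardize(env: EnvelopeSeries) -> EnvelopeSeries:
    """Zero-mean, unit-variance version of an envelope (for coherence)."""
    v = env.values
    sd = float(np.std(v))
    if sd == 0:
        raise ValueError("cannot standardize a constant envelope (zero variance)")
    return EnvelopeSeries((v - np.mean(v)) / sd, env.output_rate, env.window_length, env.source_channel)


def normalize_to_reference(env: EnvelopeSeries, ref: NormalizationReference) -> EnvelopeSeries:
    """Apply a power-grip or session Z-score normalization to an envelope."""
    ch = env.source_channel
    if ch not in ref.scale:
        raise KeyError(f"normalization reference has no entry for channel {ch!r}")
    values = (env.values - ref.offset.get(ch, 0.0)) / ref.scale[ch]
    return EnvelopeSeries(values, env.output_rate, env.window_length, ch)
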