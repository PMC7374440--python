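"""Corticomuscular coherence: pooled spectra, confidence limits, Z statistics.

Coherence between EEG and the EMG amplitude envelope is estimated with
Welch-averaged periodograms (512 ms Hann segments, 75% overlap by default)
over concatenated task epochs; segments are tiled within epochs and never
straddle an epoch boundary. Pooling across channel pairs or participants is
done by extending the epoch lists, which makes the single-record and
group-level analyses share one code path and one statistical treatment.

The 95% confidence level for a coherence profile estimated from L
(effectively independent) segments is ``CL = 1 - 0.05**(1/(L-1))``; for
overlapping tapered segments L is the variance-equivalent segment count
(raw count divided by the inflation factor implied by the taper's overlap
correlations). Pre/post change is assessed per frequency with a Z score of
the difference of Fisher-transformed coherences, ``FZ = atanh(sqrt(Coh))``
(variance 1/(2L)), and summarized per frequency band with Stouffer's
composite Z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .records import SignalRecord

#: Frequency bands (Hz) used for composite statistics.
BANDS = {"alpha": (8.0, 12.0), "beta": (12.0, 30.0), "gamma": (30.0, 50.0)}

#: Two-sided 5% standard-normal critical value for composite significance.
Z_CRITICAL = 1.96

DEFAULT_SEGMENT = 0.512  # s
DEFAULT_OVERLAP = 0.75


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence on a frequency grid with its confidence limit."""

    frequencies: np.ndarray
    coherence: np.ndarray
    L: float               # effective (variance-equivalent) segment count
    confidence_level: float
    n_segments: int        # raw segment count before the overlap correction

    def band_mask(self, low: float, high: float) -> np.ndarray:
        return (self.frequencies >= low) & (self.frequencies < high)


@dataclass
class ZDiffSpectrum:
    """Per-frequency Z score of a post-minus-pre coherence difference."""

    frequencies: np.ndarray
    z: np.ndarray
    L_pre: float
    L_post: float
    mode: str

    def band_mask(self, low: float, high: float) -> np.ndarray:
        return (self.frequencies >= low) & (self.frequencies < high)


@dataclass
class BandZResult:
    """Stouffer composite Z over one frequency band."""

    band: tuple[float, float]
    name: str
    composite_z: float
    n_bins: int
    significant: bool


def preprocess_eeg(record: SignalRecord, bad_channels: Sequence[int | str] = ()) -> SignalRecord:
    """Drop bad channels, band-pass 5-100 Hz, re-reference to the common average.

    All channels of the record are treated as EEG. ``bad_channels`` may mix
    integer column indices and role names (the first channel with that role).
    The filter is a 6th-order Butterworth applied forward-backward (zero
    net phase shift); the common average is recomputed from the retained
    channels only.
    """
    bad = set()
    for b in bad_channels:
        bad.add(b if isinstance(b, (int, np.integer)) else record.channel_index(b))
    keep = [j for j in range(record.n_channels) if j not in bad]
    if len(keep) < 2:
        raise ValueError("common-average referencing needs >= 2 retained channels")

    sos = sps.butter(6, [5.0, 100.0], btype="bandpass", fs=record.sampling_rate, output="sos")
    filtered = np.column_stack(
        [sps.sosfiltfilt(sos, record.samples[:, j]) for j in keep]
    )
    referenced = filtered - filtered.mean(axis=1, keepdims=True)
    return SignalRecord(
        samples=referenced,
        sampling_rate=record.sampling_rate,
        channel_roles=[record.channel_roles[j] for j in keep],
        annotations=list(record.annotations),
        meta=dict(record.meta),
    )


def effective_segments(
    segment_counts: Sequence[int], nperseg: int, noverlap: int, window: str
) -> float:
    """Variance-equivalent number of independent segments.

    Overlapping tapered segments are correlated; the variance of the
    averaged periodogram is inflated by ``1 + 2 * sum_m rho_m`` where
    ``rho_m`` is the squared normalized overlap correlation of the taper at
    lag ``m`` hops. The effective count is the raw count divided by that
    factor. Non-overlapping segments give exactly the raw count.
    """
    n_total = int(np.sum(segment_counts))
    step = nperseg - noverlap
    if step >= nperseg or n_total <= 1:
        return float(n_total)
    w = sps.get_window(window, nperseg)
    denom = float(np.sum(w**2))
    inflation = 1.0
    m = 1
    while m * step < nperseg:
        rho = (float(np.sum(w[: nperseg - m * step] * w[m * step :])) / denom) ** 2
        inflation += 2.0 * rho
        m += 1
    return n_total / inflation


def confidence_level(L: float, alpha: float = 0.05) -> float:
    """95% (by default) confidence limit for coherence from L segments."""
    if L <= 1:
        raise ValueError("confidence level requires L > 1 segments")
    return 1.0 - alpha ** (1.0 / (L - 1.0))


def pooled_coherence(
    x_epochs: Sequence[np.ndarray],
    y_epochs: Sequence[np.ndarray],
    sampling_rate: float,
    segment: float = DEFAULT_SEGMENT,
    overlap: float = DEFAULT_OVERLAP,
    window: str = "hann",
) -> CoherenceSpectrum:
    """Pooled magnitude-squared coherence over matched epoch lists.

    Auto- and cross-spectra are Welch-averaged within each epoch pair and
    pooled across the list with segment-count weights, so segments never
    straddle an epoch (or participant) boundary. To pool several signal
    pairs, extend both lists in step.
    """
    if len(x_epochs) != len(y_epochs) or len(x_epochs) == 0:
        raise ValueError("x_epochs and y_epochs must be non-empty and matched")
    nperseg = int(round(segment * sampling_rate))
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    noverlap = int(round(nperseg * overlap))
    step = nperseg - noverlap

    sxx = syy = sxy = None
    freqs = None
    counts = []
    for x, y in zip(x_epochs, y_epochs):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) != len(y):
            raise ValueError("each epoch pair must have equal length")
        if len(x) < nperseg:
            raise ValueError(
                f"epoch of {len(x)} samples shorter than one {nperseg}-sample segment"
            )
        n_seg = 1 + (len(x) - nperseg) // step
        counts.append(n_seg)
        kw = dict(
            fs=sampling_rate, window=window, nperseg=nperseg, noverlap=noverlap,
            detrend=False, return_onesided=True, average="mean",
        )
        freqs, pxy = sps.csd(x, y, **kw)
        _, pxx = sps.welch(x, **kw)
        _, pyy = sps.welch(y, **kw)
        if sxx is None:
            sxx = n_seg * pxx
            syy = n_seg * pyy
            sxy = n_seg * pxy
        else:
            sxx += n_seg * pxx
            syy += n_seg * pyy
            sxy += n_seg * pxy

    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    coh = np.nan_to_num(np.clip(coh.real, 0.0, 1.0))

    L = effective_segments(counts, nperseg, noverlap, window)
    cl = confidence_level(L)
    return CoherenceSpectrum(
        frequencies=freqs, coherence=coh, L=L, confidence_level=cl,
        n_segments=int(np.sum(counts)),
    )


def fisher_z(coherence: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform of coherence: atanh(sqrt(Coh))."""
    c = np.clip(np.asarray(coherence, float), 0.0, 1.0 - 1e-12)
    return np.arctanh(np.sqrt(c))


def z_difference(
    pre: CoherenceSpectrum, post: CoherenceSpectrum, mode: str = "two_sample"
) -> ZDiffSpectrum:
    """Z score of the post-minus-pre coherence difference per frequency.

    ``mode='two_sample'`` (default): the difference of Fisher-transformed
    coherences, each with variance 1/(2L), is divided by
    ``sqrt(1/(2*L_pre) + 1/(2*L_post))``; for equal segment counts this is
    exactly ``diff / sqrt(1/L)``. ``mode='single'`` uses the conservative
    single-L form ``diff / sqrt(1/min(L_pre, L_post))``.
    """
    if pre.frequencies.shape != post.frequencies.shape or not np.allclose(
        pre.frequencies, post.frequencies
    ):
        raise ValueError("pre and post spectra must share one frequency grid")
    diff = fisher_z(post.coherence) - fisher_z(pre.coherence)
    if mode == "two_sample":
        se = np.sqrt(1.0 / (2.0 * pre.L) + 1.0 / (2.0 * post.L))
    elif mode == "single":
        se = np.sqrt(1.0 / min(pre.L, post.L))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ZDiffSpectrum(
        frequencies=pre.frequencies.copy(), z=diff / se,
        L_pre=pre.L, L_post=post.L, mode=mode,
    )


def band_composite(zdiff: ZDiffSpectrum, band: tuple[float, float], name: str = "") -> BandZResult:
    """Stouffer composite Z over the band's frequency bins.

    ``sum(z) / sqrt(n)``; |composite| > 1.96 flags a two-sided 5% change.
    Assumes approximately independent bins (see package docs for when the
    segmentation delivers that).
    """
    low, high = band
    mask = zdiff.band_mask(low, high)
    n = int(mask.sum())
    if n < 1:
        raise ValueError(f"band ({low}, {high}) Hz contains no frequency bins")
    comp = float(np.sum(zdiff.z[mask]) / np.sqrt(n))
    return BandZResult(
        band=(low, high), name=name, composite_z=comp, n_bins=n,
        significant=bool(abs(comp) > Z_CRITICAL),
    )


def band_table(zdiff: ZDiffSpectrum, bands: dict[str, tuple[float, float]] = BANDS) -> list[BandZResult]:
    """Composite Z for each named band."""
    return [band_composite(zdiff, b, name) for name, b in bands.items()]


def extract_epochs(
    record: SignalRecord, kind: str, role: str
) -> list[np.ndarray]:
    """Channel samples for every annotation of the given kind, in order."""
    return [
        record.slice_samples(a.start, a.end, role)
        for a in record.annotations_of(kind)
    ]
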