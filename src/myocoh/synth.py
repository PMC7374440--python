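"""Synthetic EMG/EEG generation with analytically known ground truth.

Three generators emulate the recordings the analysis stages consume:

* :func:`generate_coherent_pair` — an EEG channel and a raw EMG channel
  whose amplitude envelope shares a band-limited cortical drive with the
  EEG, at a closed-form magnitude-squared coherence set by two
  signal-to-noise ratios.
* :func:`generate_training_session` — four forearm EMG channels following
  a rest/attempt trial schedule with controllable extensor activation and
  flexor co-activation.
* :func:`generate_static_hold` — an EMG channel whose envelope tracks a
  trapezoid target (4 s plateau at a configurable fraction of maximum) with
  calibrated tracking noise.

The EMG model is ``x(t) = A(t) * c(t)`` where ``A`` is the (nonnegative)
activation envelope and ``c`` is a constant-modulus random-phase carrier
(a phase-diffusion process centered at 150 Hz). Because ``|c(t)| = 1``,
the Hilbert analytic magnitude of ``x`` recovers ``A`` exactly and the
rectified moving average converges to ``A * 2 / pi`` — so normalization and
coherence ground truths are exact, not approximate. A Gaussian-noise
carrier would instead superimpose its own Rayleigh envelope fluctuations
on ``A`` and break the closed-form coherence contract.

All randomness flows from one ``numpy`` Generator seeded in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .emg import NormalizationReference
from .records import SignalRecord, TrialAnnotation

# Simulated per-channel maximal power-grip envelope amplitudes (arbitrary
# units). Fixed known constants so normalization has exact ground truth.
GRIP_MAX = {"ECR": 1.0, "ECU": 0.9, "FCR": 1.1, "FCU": 0.95}

#: rectified-mean of a unit-modulus carrier: mean(|cos|) = 2/pi
RECTIFIED_CARRIER_MEAN = 2.0 / np.pi

_CARRIER_CENTER_HZ = 150.0
#: (modulation index, modulation frequency Hz) pairs of the FM carrier;
#: Carson bandwidth ~ 2*sum((beta+1)*fm) keeps the carrier clear of the
#: envelope band so the analytic magnitude recovers the envelope cleanly
_CARRIER_FM = ((3.0, 8.0), (2.0, 5.0))
_ENV_NOISE_CUTOFF_HZ = 45.0  # envelope noise bandwidth (below carrier band)
_REST_LEVEL = 0.005           # baseline muscle tone, fraction of maximum
_MODULATION_DEPTH = 0.25      # envelope fluctuation scale for coherent pairs


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording setup.

    drive_power_ratio_* are in-band power ratios of the shared cortical
    drive over the channel's independent noise; together they fix the
    theoretical in-band coherence r1*r2 / ((1+r1)*(1+r2)).
    """

    sampling_rate: float = 1000.0
    duration: float = 60.0
    drive_band: tuple[float, float] = (12.0, 30.0)
    drive_power_ratio_eeg: float = 1.0
    drive_power_ratio_emg: float = 1.0
    activation_level: float = 0.5
    coactivation_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        lo, hi = self.drive_band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError("drive_band must satisfy 0 < low < high < Nyquist")
        if self.drive_power_ratio_eeg < 0 or self.drive_power_ratio_emg < 0:
            raise ValueError("drive power ratios must be >= 0")
        if not (0 <= self.activation_level <= 1):
            raise ValueError("activation_level must lie in [0, 1]")
        if self.coactivation_ratio < 0:
            raise ValueError("coactivation_ratio must be >= 0")
        coh = self.theoretical_inband_coherence
        if not (0 <= coh <= 1):
            raise ValueError(f"theoretical coherence {coh} outside [0, 1]")

    @property
    def theoretical_inband_coherence(self) -> float:
        r1, r2 = self.drive_power_ratio_eeg, self.drive_power_ratio_emg
        return (r1 / (1 + r1)) * (r2 / (1 + r2))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class CoherenceTheory:
    """Closed-form coherence spectrum of a generated EEG/EMG pair.

    The in-band plateau is r1*r2/((1+r1)(1+r2)); the exact spectrum follows
    the realized (squared, forward-backward) magnitude responses of the
    drive band-pass and the envelope-noise low-pass.
    """

    config: SynthConfig
    _bp_sos: np.ndarray = field(repr=False, default=None)
    _lp_sos: np.ndarray = field(repr=False, default=None)

    def coherence(self, freqs: np.ndarray) -> np.ndarray:
        fs = self.config.sampling_rate
        freqs = np.asarray(freqs, dtype=float)
        _, h_bp = sps.sosfreqz(self._bp_sos, worN=freqs, fs=fs)
        _, h_lp = sps.sosfreqz(self._lp_sos, worN=freqs, fs=fs)
        g_bp = np.abs(h_bp) ** 4  # filtfilt power gain
        g_lp = np.abs(h_lp) ** 4
        r1 = self.config.drive_power_ratio_eeg
        r2 = self.config.drive_power_ratio_emg
        num = r1 * r2 * g_bp**2
        den = (r1 * g_bp + 1.0) * (r2 * g_bp + g_lp)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.where(den > 0, num / den, 0.0)
        return np.clip(coh, 0.0, 1.0)

    @property
    def inband(self) -> float:
        return self.config.theoretical_inband_coherence


@dataclass
class CoherentPair:
    """A generated EEG/EMG record plus its ground truth."""

    record: SignalRecord
    theory: CoherenceTheory
    envelope: np.ndarray  # true EMG activation envelope, fraction of maximum


def _carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Constant-modulus phase-modulated carrier with random modulation phases.

    ``cos(2*pi*f0*t + sum_i beta_i*sin(2*pi*fm_i*t + phi_i))`` has unit
    modulus and a compact (Carson-band) spectrum around f0, so the Hilbert
    magnitude of an amplitude-modulated copy recovers the modulation
    envelope essentially exactly.
    """
    t = np.arange(n) / fs
    phase = 2 * np.pi * _CARRIER_CENTER_HZ * t
    for beta, fm in _CARRIER_FM:
        phase = phase + beta * np.sin(2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi))
    return np.cos(phase)


def _drive_sos(config: SynthConfig) -> np.ndarray:
    lo, hi = config.drive_band
    return sps.butter(4, [lo, hi], btype="bandpass", fs=config.sampling_rate, output="sos")


def _lowpass_sos(cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    return sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")


def grip_reference(record: SignalRecord) -> NormalizationReference:
    """Power-grip normalization reference from a synthetic record's ground truth.

    The stored scale is the *rectified-mean envelope* at maximal grip,
    ``M * 2/pi``, i.e. the same units the moving-average pipeline produces.
    """
    grip = record.meta.get("grip_max")
    if grip is None:
        raise ValueError("record carries no grip_max ground truth")
    return NormalizationReference(
        kind="power_grip_max",
        scale={ch: m * RECTIFIED_CARRIER_MEAN for ch, m in grip.items()},
    )


# ---------------------------------------------------------------------------
# coherent EEG/EMG pair
# ---------------------------------------------------------------------------

def generate_coherent_pair(config: SynthConfig) -> CoherentPair:
    """EEG + raw EMG sharing a band-limited drive at known coherence.

    EEG = sqrt(r1) * s + white noise; EMG = A * carrier with
    A proportional to 1 + depth * (sqrt(r2) * s + low-pass noise), where s is
    the band-limited shared drive. In-band coherence between the EEG and the
    EMG envelope is r1*r2 / ((1+r1)(1+r2)); out of band it vanishes.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    rng = config.rng()

    bp = _drive_sos(config)
    lp = _lowpass_sos(_ENV_NOISE_CUTOFF_HZ, fs)

    s = sps.sosfiltfilt(bp, rng.standard_normal(n))       # shared drive
    n_eeg = rng.standard_normal(n)                        # EEG-side noise
    n_env = sps.sosfiltfilt(lp, rng.standard_normal(n))   # envelope-side noise

    r1 = config.drive_power_ratio_eeg
    r2 = config.drive_power_ratio_emg
    eeg = np.sqrt(r1) * s + n_eeg

    fluct = np.sqrt(r2) * s + n_env
    m = GRIP_MAX["ECR"]
    frac = np.clip(
        config.activation_level * (1.0 + _MODULATION_DEPTH * fluct), _REST_LEVEL, None
    )
    emg = (m * frac) * _carrier(n, fs, rng)

    record = SignalRecord(
        samples=np.column_stack([eeg, emg]),
        sampling_rate=fs,
        channel_roles=["EEG_contra", "ECR"],
        annotations=[],
        meta={
            "generator": "coherent_pair",
            "seed": config.seed,
            "grip_max": {"ECR": m},
            "drive_band": list(config.drive_band),
            "drive_power_ratio_eeg": r1,
            "drive_power_ratio_emg": r2,
            "theoretical_inband_coherence": config.theoretical_inband_coherence,
        },
    )
    theory = CoherenceTheory(config, _bp_sos=bp, _lp_sos=lp)
    return CoherentPair(record=record, theory=theory, envelope=frac)


# ---------------------------------------------------------------------------
# training task: rest / attempt trials
# ---------------------------------------------------------------------------

REST_DURATION = 7.0     # seconds of rest per trial
ATTEMPT_DURATION = 5.0  # seconds of movement attempt per trial
_EDGE_RAMP = 0.15       # envelope on/offset ramp, s
_SKILL_SIGMA = 0.4      # log-amplitude SD of trial-to-trial variability at skill 0
_WITHIN_TRIAL_CV = 0.05  # within-trial envelope noise, coefficient of variation


def _smooth_gate(n_trial: int, n_attempt_offset: int, n_attempt: int, fs: float) -> np.ndarray:
    """0/1 gate over one trial with raised-cosine edges inside the attempt."""
    gate = np.zeros(n_trial)
    n_ramp = max(int(_EDGE_RAMP * fs), 1)
    i0, i1 = n_attempt_offset, n_attempt_offset + n_attempt
    gate[i0:i1] = 1.0
    up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    gate[i0 : i0 + n_ramp] = up[: max(0, min(n_ramp, n_trial - i0))]
    gate[i1 - n_ramp : i1] = up[::-1][: max(0, n_ramp)]
    return gate


def generate_training_session(
    config: SynthConfig,
    agent_skill: float = 0.5,
    n_blocks: int = 6,
    n_trials_per_block: int = 20,
) -> SignalRecord:
    """Four-channel EMG record following the rest(7 s)/attempt(5 s) schedule.

    During each attempt the extensor envelope is drawn around
    ``config.activation_level`` and the flexor envelope around
    ``coactivation_ratio`` times the extensor draw; trial-to-trial
    variability is Gaussian on log-amplitude with SD shrinking linearly to
    zero as ``agent_skill`` approaches 1.
    """
    if not (0 <= agent_skill <= 1):
        raise ValueError("agent_skill must lie in [0, 1]")
    if n_blocks < 1 or n_trials_per_block < 1:
        raise ValueError("n_blocks and n_trials_per_block must be >= 1")

    fs = config.sampling_rate
    rng = config.rng()
    n_trials = n_blocks * n_trials_per_block
    trial_len = REST_DURATION + ATTEMPT_DURATION
    n_trial = int(round(trial_len * fs))
    n_rest = int(round(REST_DURATION * fs))
    n_attempt = n_trial - n_rest
    n_total = n_trial * n_trials

    sigma = _SKILL_SIGMA * (1.0 - agent_skill)
    roles = ["ECR", "ECU", "FCR", "FCU"]
    lp_within = _lowpass_sos(3.0, fs, order=2)

    fractions = {r: np.full(n_total, _REST_LEVEL) for r in roles}
    annotations: list[TrialAnnotation] = []
    gate = _smooth_gate(n_trial, n_rest, n_attempt, fs)

    for k in range(n_trials):
        t0 = k * trial_len
        annotations.append(TrialAnnotation("rest", t0, t0 + REST_DURATION, k))
        annotations.append(
            TrialAnnotation("attempt", t0 + REST_DURATION, t0 + trial_len, k)
        )
        ext_level = config.activation_level * np.exp(sigma * rng.standard_normal())
        flex_level = (
            config.coactivation_ratio * ext_level * np.exp(sigma * rng.standard_normal())
        )
        i0 = k * n_trial
        for role in roles:
            level = ext_level if role in ("ECR", "ECU") else flex_level
            if level <= 0:
                continue
            fractions[role][i0 : i0 + n_trial] += level * gate

    samples = np.empty((n_total, len(roles)))
    for j, role in enumerate(roles):
        within = sps.sosfiltfilt(lp_within, rng.standard_normal(n_total))
        within /= max(np.std(within), 1e-12)
        frac = np.clip(fractions[role] * (1.0 + _WITHIN_TRIAL_CV * within), 0.0, None)
        samples[:, j] = (GRIP_MAX[role] * frac) * _carrier(n_total, fs, rng)

    return SignalRecord(
        samples=samples,
        sampling_rate=fs,
        channel_roles=roles,
        annotations=annotations,
        meta={
            "generator": "training_session",
            "seed": config.seed,
            "grip_max": dict(GRIP_MAX),
            "agent_skill": agent_skill,
            "n_blocks": n_blocks,
            "n_trials_per_block": n_trials_per_block,
            "activation_level": config.activation_level,
            "coactivation_ratio": config.coactivation_ratio,
        },
    )


# ---------------------------------------------------------------------------
# static hold task: trapezoid tracking
# ---------------------------------------------------------------------------

HOLD_REST = 4.0     # rest before each trapezoid, s
HOLD_RAMP = 1.0     # trapezoid ramp up and down, s
HOLD_PLATEAU = 4.0  # plateau duration, s
_TRACKING_NOISE_CUTOFF_HZ = 2.0
_CURSOR_WINDOW = 1.0  # downstream cursor smoothing window the noise is calibrated for


def _boxcar_power_gain(cutoff: float, fs: float, window: float, order: int = 4) -> float:
    """Fraction of low-pass noise variance surviving a trailing boxcar mean."""
    f = np.linspace(0, fs / 2, 4096)
    sos = _lowpass_sos(cutoff, fs, order)
    _, h = sps.sosfreqz(sos, worN=f, fs=fs)
    psd = np.abs(h) ** 4  # filtfilt
    box = np.sinc(f * window) ** 2
    return float(np.trapezoid(psd * box, f) / np.trapezoid(psd, f))


def generate_static_hold(
    config: SynthConfig,
    target_fraction: float = 0.15,
    n_holds: int = 16,
    tracking_noise: float = 0.0,
) -> SignalRecord:
    """EMG whose envelope tracks a trapezoid target with calibrated noise.

    ``tracking_noise`` is the standard deviation (fraction-of-maximum) of
    the cursor's deviation from the target *after* the downstream 1 s
    moving-average smoothing; the injected low-pass noise is pre-scaled by
    the smoother's analytic attenuation so the realized cursor error has
    the requested SD.
    """
    if not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must lie in (0, 1]")
    if n_holds < 1:
        raise ValueError("n_holds must be >= 1")
    if tracking_noise < 0:
        raise ValueError("tracking_noise must be >= 0")

    fs = config.sampling_rate
    rng = config.rng()
    hold_len = HOLD_REST + 2 * HOLD_RAMP + HOLD_PLATEAU
    n_hold = int(round(hold_len * fs))
    n_total = n_hold * n_holds
    t_local = np.arange(n_hold) / fs

    # trapezoid target for one hold cycle
    target_one = np.interp(
        t_local,
        [0, HOLD_REST, HOLD_REST + HOLD_RAMP,
         HOLD_REST + HOLD_RAMP + HOLD_PLATEAU, hold_len],
        [0, 0, target_fraction, target_fraction, 0],
    )
    target = np.tile(target_one, n_holds)

    if tracking_noise > 0:
        u = sps.sosfiltfilt(
            _lowpass_sos(_TRACKING_NOISE_CUTOFF_HZ, fs), rng.standard_normal(n_total)
        )
        gain = _boxcar_power_gain(_TRACKING_NOISE_CUTOFF_HZ, fs, _CURSOR_WINDOW)
        noise = u * (tracking_noise / (np.std(u) * np.sqrt(gain)))
    else:
        noise = np.zeros(n_total)

    active = target > 0
    frac = np.where(active, np.clip(target + noise, 0.0, None), 0.0)
    frac = np.maximum(frac, _REST_LEVEL)

    m = GRIP_MAX["ECR"]
    emg = (m * frac) * _carrier(n_total, fs, rng)

    annotations = []
    for k in range(n_holds):
        p0 = k * hold_len + HOLD_REST + HOLD_RAMP
        annotations.append(TrialAnnotation("hold_plateau", p0, p0 + HOLD_PLATEAU, k))

    return SignalRecord(
        samples=emg[:, None],
        sampling_rate=fs,
        channel_roles=["ECR"],
        annotations=annotations,
        meta={
            "generator": "static_hold",
            "seed": config.seed,
            "grip_max": {"ECR": m},
            "target_fraction": target_fraction,
            "n_holds": n_holds,
            "tracking_noise": tracking_noise,
        },
    )
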