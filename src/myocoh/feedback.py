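"""Extensor-ratio biofeedback engine with an adaptive-threshold staircase.

The trained quantity is the extensor ratio
``ER = EMG_extensors / (EMG_extensors + EMG_flexors)`` computed on summed,
grip-normalized envelope amplitudes at the feedback rate (250 Hz, 480 ms
rectified moving window). A movement-attempt trial succeeds when, for a
contiguous 2 s, the summed extensor activity exceeds 30% of its power-grip
maximum AND the ER exceeds an adaptive threshold. The threshold starts each
session at 0.5 and moves in steps of 0.3 within [0.3, 0.97] after three
consecutive successes (up) or failures (down); the three-trial counter
resets after every adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .emg import NormalizationReference, moving_envelope, normalize_to_reference
from .records import EXTENSOR_ROLES, FLEXOR_ROLES, SignalRecord


@dataclass(frozen=True)
class FeedbackParams:
    """Training-task parameters (defaults: the studied protocol)."""

    activation_threshold: float = 0.30   # fraction of power-grip maximum
    required_duration: float = 2.0       # s of sustained criterion
    er_start: float = 0.5
    er_step: float = 0.3
    er_bounds: tuple[float, float] = (0.3, 0.97)
    er_floor: float = 0.01               # activity floor below which ER is undefined
    feedback_rate: float = 250.0         # Hz
    envelope_window: float = 0.48        # s
    contiguous: bool = True              # require one contiguous 2 s run


@dataclass(frozen=True)
class StaircaseState:
    """Adaptive ER threshold plus the outcomes since the last adjustment."""

    threshold: float = 0.5
    step: float = 0.3
    lower_bound: float = 0.3
    upper_bound: float = 0.97
    history: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not (self.lower_bound <= self.threshold <= self.upper_bound):
            raise ValueError("threshold outside staircase bounds")


def staircase_update(state: StaircaseState, outcome: bool) -> StaircaseState:
    """Append one trial outcome and adapt the threshold on a run of three.

    Three consecutive successes since the last adjustment raise the
    threshold by one step, three failures lower it; the result is clipped
    to the bounds and the counter clears. Mixed outcomes leave the
    threshold unchanged (the counter keeps accumulating: a change of
    direction merely delays the next adjustment, it does not reset it).
    """
    history = state.history + (bool(outcome),)
    if len(history) < 3:
        return replace(state, history=history)
    last3 = history[-3:]
    if all(last3):
        new = min(state.threshold + state.step, state.upper_bound)
        return replace(state, threshold=new, history=())
    if not any(last3):
        new = max(state.threshold - state.step, state.lower_bound)
        return replace(state, threshold=new, history=())
    return replace(state, history=history)


def compute_er(
    extensor_sum: float | np.ndarray,
    flexor_sum: float | np.ndarray,
    floor: float = 0.01,
) -> float | np.ndarray:
    """Extensor ratio of summed amplitudes; NaN where activity is below floor.

    ER = extensor / (extensor + flexor), defined only when the total
    activity exceeds ``floor`` (avoids 0/0 at rest).
    """
    ext = np.asarray(extensor_sum, dtype=float)
    flx = np.asarray(flexor_sum, dtype=float)
    if np.any(ext < 0) or np.any(flx < 0):
        raise ValueError("summed amplitudes must be nonnegative")
    total = ext + flx
    with np.errstate(invalid="ignore", divide="ignore"):
        er = np.where(total > floor, ext / total, np.nan)
    if er.ndim == 0:
        return float(er)
    return er


@dataclass
class TrialResult:
    """Outcome of one movement-attempt trial."""

    trial_index: int
    success: bool
    max_sustained: float        # s, longest contiguous criterion-meeting run
    er_threshold_used: float
    mean_er: float              # mean over defined ER samples (NaN if none)
    mean_extensor: float        # fraction of grip maximum
    mean_flexor: float


def longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest contiguous run of True values."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return 0
    padded = np.concatenate(([False], mask, [False])).astype(int)
    edges = np.flatnonzero(np.diff(padded))
    if edges.size == 0:
        return 0
    return int(np.max(edges[1::2] - edges[::2]))


def evaluate_trial(
    er_series: np.ndarray,
    extensor_series: np.ndarray,
    er_threshold: float,
    params: FeedbackParams = FeedbackParams(),
    trial_index: int = 0,
) -> TrialResult:
    """Score one attempt window sampled at the feedback rate.

    A sample meets criteria iff the summed extensor amplitude exceeds the
    activation threshold AND the ER is defined and exceeds the adaptive
    threshold. Success requires the criterion to hold for
    ``required_duration`` — contiguously by default, cumulatively if
    ``params.contiguous`` is False.
    """
    er = np.asarray(er_series, dtype=float)
    ext = np.asarray(extensor_series, dtype=float)
    if er.shape != ext.shape:
        raise ValueError("er_series and extensor_series must align")
    needed = int(np.ceil(params.required_duration * params.feedback_rate - 1e-9))
    if er.size < needed:
        raise ValueError(
            f"series of {er.size} samples cannot span the required "
            f"{params.required_duration} s at {params.feedback_rate} Hz"
        )
    meets = (ext > params.activation_threshold) & np.where(
        np.isnan(er), False, er > er_threshold
    )
    if params.contiguous:
        sustained = longest_true_run(meets)
    else:
        sustained = int(np.sum(meets))
    defined = ~np.isnan(er)
    return TrialResult(
        trial_index=trial_index,
        success=sustained >= needed,
        max_sustained=sustained / params.feedback_rate,
        er_threshold_used=er_threshold,
        mean_er=float(np.mean(er[defined])) if defined.any() else float("nan"),
        mean_extensor=float(np.mean(ext)),
        mean_flexor=float("nan"),  # filled by run_session, which has the flexor sum
    )


@dataclass
class SessionSummary:
    """Per-session aggregates of the training metrics."""

    n_trials: int
    percent_success: float
    mean_threshold: float
    mean_er: float
    mean_extensor: float
    mean_flexor: float
    final_threshold: float


@dataclass
class SessionResult:
    trials: list[TrialResult]
    summary: SessionSummary
    threshold_trajectory: list[float] = field(default_factory=list)


def run_session(
    record: SignalRecord,
    reference: NormalizationReference,
    params: FeedbackParams = FeedbackParams(),
) -> SessionResult:
    """Replay the staircase over every annotated attempt of a session.

    Envelopes are extracted per channel at the feedback rate, normalized to
    the power-grip reference, summed within the extensor and flexor groups,
    and scored trial by trial; the threshold used for trial k reflects all
    staircase updates through trial k-1.
    """
    attempts = sorted(record.annotations_of("attempt"), key=lambda a: a.start)
    if not attempts:
        raise ValueError("record carries no attempt annotations")

    ext_roles = [r for r in EXTENSOR_ROLES if record.has_role(r)]
    flex_roles = [r for r in FLEXOR_ROLES if record.has_role(r)]
    if not ext_roles or not flex_roles:
        raise ValueError("record needs at least one extensor and one flexor channel")

    def summed(roles: list[str]) -> np.ndarray:
        # summed group activity, expressed as a fraction of the group's own
        # power-grip maximum (sum of normalized envelopes / channel count):
        # "30% of maximal summed activity" then reads directly as 0.30
        total = None
        for role in roles:
            env = moving_envelope(
                record, role, params.envelope_window, params.feedback_rate
            )
            env = normalize_to_reference(env, reference)
            total = env.values if total is None else total + env.values
        return total / len(roles)

    ext_sum = summed(ext_roles)
    flex_sum = summed(flex_roles)
    er_all = compute_er(ext_sum, flex_sum, params.er_floor)
    ticks = (np.arange(len(ext_sum)) + 1) / params.feedback_rate

    state = StaircaseState(
        threshold=params.er_start,
        step=params.er_step,
        lower_bound=params.er_bounds[0],
        upper_bound=params.er_bounds[1],
    )
    trials: list[TrialResult] = []
    trajectory = [state.threshold]
    for ann in attempts:
        sel = (ticks > ann.start + 1e-9) & (ticks <= ann.end + 1e-9)
        result = evaluate_trial(
            er_all[sel], ext_sum[sel], state.threshold, params, ann.trial_index
        )
        result.mean_flexor = float(np.mean(flex_sum[sel]))
        trials.append(result)
        state = staircase_update(state, result.success)
        trajectory.append(state.threshold)

    mean_er_vals = [t.mean_er for t in trials if not np.isnan(t.mean_er)]
    summary = SessionSummary(
        n_trials=len(trials),
        percent_success=100.0 * np.mean([t.success for t in trials]),
        mean_threshold=float(np.mean([t.er_threshold_used for t in trials])),
        mean_er=float(np.mean(mean_er_vals)) if mean_er_vals else float("nan"),
        mean_extensor=float(np.mean([t.mean_extensor for t in trials])),
        mean_flexor=float(np.mean([t.mean_flexor for t in trials])),
        final_threshold=state.threshold,
    )
    return SessionResult(trials=trials, summary=summary, threshold_trajectory=trajectory)
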