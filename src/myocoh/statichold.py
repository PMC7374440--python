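"""Static-hold assessment: trapezoid tracking error and pre/post comparison.

Participants hold a constant EMG level: the feedback cursor is the tracked
channel's 1 s rectified moving-average envelope, normalized to the
power-grip maximum, and the target is the 4 s plateau (15% of maximum by
default) of a 6 s trapezoid. Tracking accuracy per hold is the median
absolute deviation of the cursor from the plateau level over the last 3 s
of the hold — the median of ``|cursor - target|``, i.e. deviation about the
target, not about the sample median. Pre/post change is tested with paired
t-tests: per participant over hold pairs (hold k before vs hold k after),
and at the group level over participant means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emg import EnvelopeSeries, NormalizationReference, moving_envelope, normalize_to_reference
from .records import SignalRecord
from .stats import PairedComparison, paired_t


@dataclass(frozen=True)
class HoldTarget:
    """Trapezoid target profile for one hold."""

    plateau_level: float = 0.15  # fraction of power-grip maximum
    ramp_up: float = 1.0         # s
    plateau: float = 4.0         # s
    ramp_down: float = 1.0       # s
    sweep: float = 10.0          # s, full cursor sweep containing the trapezoid

    def __post_init__(self) -> None:
        span = self.ramp_up + self.plateau + self.ramp_down
        if self.sweep < span:
            raise ValueError("sweep must contain the full trapezoid span")
        if not (0 < self.plateau_level <= 1):
            raise ValueError("plateau_level must lie in (0, 1]")


@dataclass
class HoldError:
    """Per-hold median-absolute-deviation tracking errors (fraction of max)."""

    per_hold_error: np.ndarray
    analysis_window: float = 3.0

    def __post_init__(self) -> None:
        self.per_hold_error = np.asarray(self.per_hold_error, dtype=float)

    @property
    def n_holds(self) -> int:
        return len(self.per_hold_error)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_hold_error))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_hold_error, ddof=1)) if self.n_holds > 1 else 0.0


def cursor_series(
    record: SignalRecord,
    channel: str,
    reference: NormalizationReference,
    window: float = 1.0,
) -> EnvelopeSeries:
    """Feedback-cursor height: 1 s rectified moving average, grip-normalized."""
    env = moving_envelope(record, channel, window)
    return normalize_to_reference(env, reference)


def hold_error(
    cursor: EnvelopeSeries,
    target: HoldTarget,
    record: SignalRecord,
    analysis_window: float = 3.0,
) -> HoldError:
    """MAD tracking error per annotated plateau.

    For each ``hold_plateau`` annotation, the error is the median of
    ``|cursor - plateau_level|`` over the last ``analysis_window`` seconds
    of the plateau.
    """
    plateaus = sorted(record.annotations_of("hold_plateau"), key=lambda a: a.start)
    if not plateaus:
        raise ValueError("record carries no hold_plateau annotations")
    errors = []
    for ann in plateaus:
        if ann.duration < analysis_window - 1e-9:
            raise ValueError(
                f"plateau of {ann.duration:.2f} s shorter than the "
                f"{analysis_window} s analysis window"
            )
        values = cursor.slice(ann.end - analysis_window, ann.end)
        errors.append(float(np.median(np.abs(values - target.plateau_level))))
    return HoldError(np.array(errors), analysis_window)


@dataclass
class HoldComparison:
    """Pre/post static-hold comparison at individual and group level."""

    individual: list[PairedComparison]
    group: PairedComparison | None
    pre_means: np.ndarray
    post_means: np.ndarray


def compare_sessions(
    pre: HoldError | list[HoldError], post: HoldError | list[HoldError]
) -> HoldComparison:
    """Paired t-tests of tracking error before vs after training.

    Individual level: hold k pre vs hold k post for each participant
    (requires equal hold counts). Group level: paired t over participant
    mean errors, reported only when >= 2 participants are supplied.
    """
    pre_list = [pre] if isinstance(pre, HoldError) else list(pre)
    post_list = [post] if isinstance(post, HoldError) else list(post)
    if len(pre_list) != len(post_list):
        raise ValueError("need one post HoldError per pre HoldError")
    individual = []
    for p, q in zip(pre_list, post_list):
        if p.n_holds != q.n_holds:
            raise ValueError("pre and post hold counts must match for pairing")
        individual.append(paired_t(p.per_hold_error, q.per_hold_error))
    pre_means = np.array([p.mean for p in pre_list])
    post_means = np.array([q.mean for q in post_list])
    group = paired_t(pre_means, post_means) if len(pre_list) >= 2 else None
    return HoldComparison(
        individual=individual, group=group, pre_means=pre_means, post_means=post_means
    )
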