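"""Core data containers: multichannel signal records and trial annotations.

A :class:`SignalRecord` is the unit of exchange between the synthetic
generators, the EMG conditioning stage, the biofeedback engine and the
coherence analysis: a uniformly sampled time-by-channel matrix with a role
label per channel (which forearm muscle, or which EEG electrode group) and a
list of task annotations (rest / movement-attempt / hold-plateau intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: Channel roles understood by the pipeline. ECR/ECU are wrist extensors,
#: FCR/FCU are wrist flexors; EEG roles distinguish the hemisphere relative
#: to the (simulated) lesion.
CHANNEL_ROLES = ("ECR", "ECU", "FCR", "FCU", "EEG_ipsi", "EEG_contra", "other")

EXTENSOR_ROLES = ("ECR", "ECU")
FLEXOR_ROLES = ("FCR", "FCU")
EEG_ROLES = ("EEG_ipsi", "EEG_contra")

ANNOTATION_KINDS = ("rest", "attempt", "hold_plateau", "grip")


@dataclass(frozen=True)
class TrialAnnotation:
    """One labelled task interval, in seconds from record start."""

    kind: str
    start: float
    end: float
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"annotation start {self.start} must precede end {self.end}")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SignalRecord:
    """Uniformly sampled multichannel time series with channel roles.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal amplitudes in arbitrary (consistent) units.
    sampling_rate : float
        Samples per second, shared by all channels.
    channel_roles : sequence of str
        One role from :data:`CHANNEL_ROLES` per column.
    annotations : list of TrialAnnotation
        Task structure; every interval must lie within the record.
    meta : dict
        Free-form metadata (ground-truth parameters for synthetic records,
        normalization references, seeds).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_roles: Sequence[str]
    annotations: list[TrialAnnotation] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_samples, n_channels) matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_roles = list(self.channel_roles)
        if len(self.channel_roles) != self.samples.shape[1]:
            raise ValueError("one channel role required per column")
        for role in self.channel_roles:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        dur = self.duration
        for ann in self.annotations:
            if ann.start < 0 or ann.end > dur + 1e-9:
                raise ValueError(
                    f"annotation [{ann.start}, {ann.end}] outside record of {dur:.3f} s"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    # -- channel access -------------------------------------------------
    def channel_index(self, role: str) -> int:
        """Index of the first channel with the given role."""
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}") from None

    def channel(self, role: str) -> np.ndarray:
        """1-D samples of the first channel with the given role."""
        return self.samples[:, self.channel_index(role)]

    def channels(self, roles: Sequence[str]) -> np.ndarray:
        """(n_samples, len(roles)) view in the requested role order."""
        idx = [self.channel_index(r) for r in roles]
        return self.samples[:, idx]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles

    # -- annotations ----------------------------------------------------
    def annotations_of(self, kind: str) -> list[TrialAnnotation]:
        return [a for a in self.annotations if a.kind == kind]

    def slice_samples(self, start: float, end: float, role: str) -> np.ndarray:
        """Channel samples whose time lies in [start, end)."""
        i0 = int(np.ceil(start * self.sampling_rate - 1e-9))
        i1 = int(np.floor(end * self.sampling_rate - 1e-9)) + 1
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        return self.channel(role)[i0:i1]

    def with_samples(self, samples: np.ndarray, roles: Sequence[str] | None = None) -> "SignalRecord":
        """Copy of this record with replaced sample matrix (same rate/annotations)."""
        return SignalRecord(
            samples=samples,
            sampling_rate=self.sampling_rate,
            channel_roles=list(roles) if roles is not None else list(self.channel_roles),
            annotations=list(self.annotations),
            meta=dict(self.meta),
        )


def annotations_to_dicts(annotations: Sequence[TrialAnnotation]) -> list[dict]:
    return [asdict(a) for a in annotations]


def annotations_from_dicts(dicts: Sequence[dict]) -> list[TrialAnnotation]:
    return [TrialAnnotation(**d) for d in dicts]
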