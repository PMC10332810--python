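"""Core containers for trial-aligned fluorescence data and stimulus schedules.

The analyses in this package all operate on two objects: a :class:`TrialTensor`
holding cell x frame x trial fluorescence (raw or dF/F), and a
:class:`StimulusSchedule` describing the ordered odor epochs of every trial.
Odors are referred to by *role* rather than chemical identity: ``A`` is the
odor paired with reinforcement, ``A_prime`` the perceptually similar unpaired
odor, ``B`` the dissimilar odor, and ``air`` clean air.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: The four recognized odor roles.
ODOR_ROLES = ("A", "A_prime", "B", "air")

#: Separator used in transition stimulus labels, e.g. ``"A>A_prime"``.
TRANSITION_SEP = ">"


def parse_stimulus(label: str) -> tuple[str, ...]:
    """Split a stimulus label into its ordered odor roles.

    ``"A"`` -> ``("A",)``; ``"A>A_prime"`` -> ``("A", "A_prime")``.
    Raises ``ValueError`` for unknown roles or transitions involving air.
    """
    roles = tuple(label.split(TRANSITION_SEP))
    for r in roles:
        if r not in ODOR_ROLES:
            raise ValueError(f"unknown odor role {r!r} in stimulus {label!r}")
    if len(roles) > 1 and "air" in roles:
        raise ValueError(f"transitions must be ordered pairs of non-air odors: {label!r}")
    if len(roles) > 2:
        raise ValueError(f"at most two odors per stimulus: {label!r}")
    return roles


@dataclass(frozen=True)
class Epoch:
    """One odor epoch within a trial, in seconds from trial start."""

    role: str
    onset_s: float
    offset_s: float

    def __post_init__(self):
        if self.role not in ODOR_ROLES:
            raise ValueError(f"unknown odor role {self.role!r}")
        if not self.onset_s < self.offset_s:
            raise ValueError("epoch onset must precede offset")


@dataclass
class StimulusSchedule:
    """Ordered odor epochs for every trial.

    Parameters
    ----------
    trials
        One tuple of :class:`Epoch` per trial, ordered and non-overlapping.
    labels
        Stimulus id per trial (``"A"``, ``"B"``, ``"A>A_prime"``, ...).
    """

    trials: list[tuple[Epoch, ...]]
    labels: list[str]

    def __post_init__(self):
        if len(self.trials) != len(self.labels):
            raise ValueError("one label per trial required")
        for epochs in self.trials:
            for a, b in zip(epochs, epochs[1:]):
                if b.onset_s < a.offset_s:
                    raise ValueError("epochs must be ordered and non-overlapping")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def epochs(self, trial: int) -> tuple[Epoch, ...]:
        return self.trials[trial]

    def is_transition(self, trial: int) -> bool:
        """True when the trial is two odor epochs with zero gap."""
        eps = [e for e in self.trials[trial] if e.role != "air"]
        return (
            len(eps) == 2
            and np.isclose(eps[0].offset_s, eps[1].onset_s)
        )

    def epoch(self, trial: int, selector: int | str = "first") -> Epoch:
        """Select an epoch of a trial by index or ``first``/``second``/``last``."""
        eps = self.trials[trial]
        if isinstance(selector, str):
            idx = {"first": 0, "second": 1, "last": len(eps) - 1}.get(selector)
            if idx is None:
                raise ValueError(f"unknown epoch selector {selector!r}")
        else:
            idx = selector
        try:
            return eps[idx]
        except IndexError:
            raise ValueError(
                f"trial {trial} ({self.labels[trial]!r}) has no epoch {selector!r}"
            ) from None

    def first_onset(self, trial: int) -> float:
        return self.trials[trial][0].onset_s

    def trials_for(self, label: str) -> np.ndarray:
        """Indices of all trials carrying the given stimulus label."""
        return np.flatnonzero([lab == label for lab in self.labels])

    @property
    def stimuli(self) -> list[str]:
        """Unique stimulus labels in order of first appearance."""
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class TrialTensor:
    """Cell x frame x trial fluorescence with acquisition metadata.

    ``kind`` is ``"raw"`` (arbitrary fluorescence units) or ``"dff"``
    (dimensionless dF/F). A dff tensor forbids further background handling;
    ``background_subtracted`` tracks whether the raw field background has
    already been removed, so the subtraction cannot be applied twice.
    """

    values: np.ndarray
    frame_rate_hz: float
    kind: str = "raw"
    trial_labels: list[str] = field(default_factory=list)
    background: float = 0.0
    background_subtracted: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be cell x frame x trial (3-D)")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.kind not in ("raw", "dff"):
            raise ValueError("kind must be 'raw' or 'dff'")
        if self.trial_labels and len(self.trial_labels) != self.values.shape[2]:
            raise ValueError("one trial label per trial required")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def replace(self, **kwargs) -> "TrialTensor":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ResponseWindow:
    """Quantification window relative to an epoch onset (seconds)."""

    start_s: float = 0.0
    duration_s: float = 8.0

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")


def window_frames(
    start_s: float, stop_s: float, frame_rate_hz: float, n_frames: int
) -> tuple[int, int]:
    """Map a half-open time window [start_s, stop_s) to frame indices.

    The window covers frames ``floor(start*rate) .. floor(stop*rate)-1``
    (half-open, alignment-stable). Windows partially outside the trial are
    clipped with a warning; a window entirely outside raises ``ValueError``.
    """
    lo = int(np.floor(start_s * frame_rate_hz))
    hi = int(np.floor(stop_s * frame_rate_hz))
    if hi <= 0 or lo >= n_frames:
        raise ValueError(
            f"window [{start_s}, {stop_s}) s lies entirely outside the trial"
        )
    if lo < 0 or hi > n_frames:
        warnings.warn("response window truncated to trial bounds", stacklevel=2)
    return max(lo, 0), min(hi, n_frames)
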