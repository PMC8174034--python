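"""Domain types, validation, and press-outcome labeling for the hold-down task.

The behavioral unit of analysis is a self-paced lever press: the animal
depresses the lever at ``onset``, holds it, and releases at ``offset``.
A press is a *success* when its duration strictly exceeds the session's
hold-down criterion (800 or 1600 ms); reward is delivered at the offset of
successful presses only. Sessions end when 60 rewards have been earned or
after 90 minutes, whichever comes first. Behavioral events are logged on a
10-ms grid; spike times are unconstrained within the session.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MS_PER_MIN = 60_000
#: behavioral timestamp resolution (ms)
EVENT_GRID_MS = 10
#: default session termination rules
MAX_REWARDS = 60
MAX_SESSION_MS = 90 * MS_PER_MIN
#: default unit inclusion threshold (spike count over the whole session)
MIN_SPIKES_PER_UNIT = 1000


class Group(str, Enum):
    """Treatment group: air controls vs chronic intermittent ethanol."""

    AIR = "air"
    CIE = "CIE"


class Outcome(str, Enum):
    SUCCESS = "success"
    FAILURE = "failure"


class ValidationError(ValueError):
    """A dataset violated a structural invariant."""


class FormatError(ValueError):
    """An input table did not match the documented column dialect."""


@dataclass(frozen=True)
class BehavioralSession:
    """One self-paced hold-down session for one mouse.

    Press intervals are half-open ``[onset, offset)``: a spike exactly at
    the offset belongs to the post-press epoch. Reward timestamps coincide
    with the offsets of the presses that earned them (zero delivery latency
    in the data model).
    """

    session_id: str
    mouse_id: str
    group: Group
    criterion_ms: int
    press_onsets: np.ndarray
    press_offsets: np.ndarray
    reward_times: np.ndarray
    session_end_ms: float
    press_outcomes: Optional[tuple[Outcome, ...]] = None

    def __post_init__(self):
        object.__setattr__(self, "press_onsets", np.asarray(self.press_onsets, dtype=float))
        object.__setattr__(self, "press_offsets", np.asarray(self.press_offsets, dtype=float))
        object.__setattr__(self, "reward_times", np.asarray(self.reward_times, dtype=float))

    @property
    def n_presses(self) -> int:
        return len(self.press_onsets)

    @property
    def durations_ms(self) -> np.ndarray:
        return self.press_offsets - self.press_onsets

    @property
    def n_rewards(self) -> int:
        return len(self.reward_times)

    def validate(self, enforce_task_limits: bool = True) -> None:
        """Check every structural invariant; raise ValidationError on the first failure.

        With ``enforce_task_limits`` the session must also respect the
        task termination rules (<= 60 rewards, <= 90 min); disable for
        configurations that override them.
        """
        sid = self.session_id
        on, off, rew = self.press_onsets, self.press_offsets, self.reward_times
        if len(on) != len(off):
            raise ValidationError(f"{sid}: onset/offset length mismatch")
        if self.criterion_ms <= 0:
            raise ValidationError(f"{sid}: criterion_ms must be positive")
        if len(on):
            if np.any(np.diff(on) <= 0):
                raise ValidationError(f"{sid}: press onsets not strictly increasing")
            if np.any(off <= on):
                i = int(np.argmax(off <= on))
                raise ValidationError(
                    f"{sid}: press {i}: offset precedes onset "
                    f"(onset {on[i]:g}, offset {off[i]:g})"
                )
            if np.any(on[1:] < off[:-1]):
                raise ValidationError(f"{sid}: presses overlap")
        for name, ts in (("onset", on), ("offset", off), ("reward", rew)):
            if np.any(ts < 0):
                raise ValidationError(f"{sid}: negative {name} timestamp")
            if np.any(ts > self.session_end_ms):
                raise ValidationError(f"{sid}: {name} timestamp after session end")
            if np.any(np.mod(ts, EVENT_GRID_MS) != 0):
                raise ValidationError(
                    f"{sid}: {name} timestamps off the {EVENT_GRID_MS}-ms grid"
                )
        # every reward must sit on the offset of a strictly-supra-criterion press
        durations = off - on
        for r in rew:
            matches = np.flatnonzero(off == r)
            if len(matches) != 1:
                raise ValidationError(f"{sid}: orphan reward at {r:g} ms")
            if durations[matches[0]] <= self.criterion_ms:
                raise ValidationError(
                    f"{sid}: reward at {r:g} ms on a press that did not exceed "
                    f"the {self.criterion_ms}-ms criterion"
                )
        if self.press_outcomes is not None:
            if len(self.press_outcomes) != len(on):
                raise ValidationError(f"{sid}: press_outcomes length mismatch")
            expected = durations > self.criterion_ms
            for i, out in enumerate(self.press_outcomes):
                if (out is Outcome.SUCCESS) != bool(expected[i]):
                    raise ValidationError(
                        f"{sid}: press {i} labeled {out.value} but duration "
                        f"{durations[i]:g} vs criterion {self.criterion_ms}"
                    )
        if enforce_task_limits:
            if self.n_rewards > MAX_REWARDS:
                raise ValidationError(f"{sid}: more than {MAX_REWARDS} rewards")
            if self.session_end_ms > MAX_SESSION_MS:
                raise ValidationError(f"{sid}: session longer than 90 min")


@dataclass(frozen=True)
class UnitRecording:
    """Sorted spike times (ms) for one isolated unit in one session."""

    unit_id: str
    session_id: str
    spike_times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "spike_times", np.asarray(self.spike_times, dtype=float))

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def validate(self, session: Optional[BehavioralSession] = None) -> None:
        st = self.spike_times
        if np.any(np.diff(st) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
        if np.any(st < 0):
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        if session is not None and np.any(st > session.session_end_ms):
            raise ValidationError(
                f"unit {self.unit_id}: spike after end of session {session.session_id}"
            )


@dataclass(frozen=True)
class Dataset:
    """A cohort of sessions with their recorded units."""

    sessions: tuple[BehavioralSession, ...]
    units: tuple[UnitRecording, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sessions", tuple(self.sessions))
        object.__setattr__(self, "units", tuple(self.units))

    def session(self, session_id: str) -> BehavioralSession:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)

    def units_of(self, session_id: str) -> list[UnitRecording]:
        return [u for u in self.units if u.session_id == session_id]

    def validate(self, enforce_task_limits: bool = True) -> None:
        by_id: dict[str, BehavioralSession] = {}
        for s in self.sessions:
            if s.session_id in by_id:
                raise ValidationError(f"duplicate session_id {s.session_id}")
            by_id[s.session_id] = s
            s.validate(enforce_task_limits=enforce_task_limits)
        for u in self.units:
            if u.session_id not in by_id:
                raise ValidationError(
                    f"unit {u.unit_id}: unknown session {u.session_id}"
                )
            u.validate(by_id[u.session_id])


def label_press_outcomes(session: BehavioralSession) -> BehavioralSession:
    """Label each press success/failure by strict exceedance of the criterion.

    A press is a success iff ``offset - onset > criterion_ms`` (strictly: a
    press exactly at criterion is a failure). Idempotent. Raises
    ValidationError if existing reward times contradict the labels.
    """
    durations = session.durations_ms
    outcomes = tuple(
        Outcome.SUCCESS if d > session.criterion_ms else Outcome.FAILURE
        for d in durations
    )
    labeled = replace(session, press_outcomes=outcomes)
    for r in session.reward_times:
        matches = np.flatnonzero(session.press_offsets == r)
        if len(matches) != 1 or outcomes[matches[0]] is not Outcome.SUCCESS:
            raise ValidationError(
                f"{session.session_id}: reward at {r:g} ms inconsistent with "
                "press outcomes"
            )
    return labeled


def success_mask(session: BehavioralSession) -> np.ndarray:
    """Boolean success indicator per press (labels the session if needed)."""
    if session.press_outcomes is None:
        session = label_press_outcomes(session)
    return np.array([o is Outcome.SUCCESS for o in session.press_outcomes])


def filter_units(dataset: Dataset, min_spikes: int = MIN_SPIKES_PER_UNIT) -> Dataset:
    """Drop units with fewer than ``min_spikes`` spikes; sessions untouched."""
    if min_spikes < 0:
        raise ValueError("min_spikes must be >= 0")
    kept = tuple(u for u in dataset.units if u.n_spikes >= min_spikes)
    dropped = len(dataset.units) - len(kept)
    if dropped:
        logger.info("filter_units: dropped %d unit(s) below %d spikes", dropped, min_spikes)
    return replace(dataset, units=kept)


def select_analysis_sessions(
    dataset: Dataset, criterion_ms: int, n_last: int = 2
) -> Dataset:
    """Keep, per mouse, the last ``n_last`` sessions at the given criterion.

    Session order within the dataset is taken as chronological. A mouse
    with fewer matching sessions keeps all of them (at least one session
    per mouse that has any); a mouse with none is dropped with a warning.
    Units belonging to dropped sessions are dropped with their sessions.
    """
    if n_last < 1:
        raise ValueError("n_last must be >= 1")
    by_mouse: dict[str, list[BehavioralSession]] = {}
    for s in dataset.sessions:
        by_mouse.setdefault(s.mouse_id, []).append(s)
    keep_ids: set[str] = set()
    kept_sessions: list[BehavioralSession] = []
    for mouse, sessions in by_mouse.items():
        matching = [s for s in sessions if s.criterion_ms == criterion_ms]
        if not matching:
            warnings.warn(
                f"mouse {mouse}: no sessions at criterion {criterion_ms} ms; dropped"
            )
            continue
        for s in matching[-n_last:]:
            keep_ids.add(s.session_id)
    for s in dataset.sessions:  # preserve original order
        if s.session_id in keep_ids:
            kept_sessions.append(s)
    kept_units = tuple(u for u in dataset.units if u.session_id in keep_ids)
    return replace(dataset, sessions=tuple(kept_sessions), units=kept_units)
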