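"""Experimental design: trial schedules for the verbal-repetition paradigm.

The paradigm presents auditory stimuli from five categories — natural sounds,
animal vocalizations, human non-speech sounds, pseudowords and words.  One
trial spans 16 s: 2 s of sound presentation, 2 s of overt repetition (speech
categories only) and rest.  A run starts with a 16-s dummy period followed by
25 trials, so a full run spans 416 s.  Twenty stimuli per category are pooled
and presented in randomized order over four runs (100 trials per subject).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError

#: The five stimulus categories, in canonical order.
CONDITIONS: tuple[str, ...] = (
    "natural",
    "animal",
    "human_nonspeech",
    "pseudoword",
    "word",
)

#: Categories with an overt production (repetition) phase.
SPEECH_CONDITIONS: tuple[str, ...] = ("pseudoword", "word")

#: Categories listened to passively.
NONSPEECH_CONDITIONS: tuple[str, ...] = ("natural", "animal", "human_nonspeech")

TRIAL_DURATION: float = 16.0
DUMMY_DURATION: float = 16.0
PERCEPTION_DURATION: float = 2.0
PRODUCTION_DELAY: float = 2.0  # production starts 2 s after stimulus onset


@dataclass(frozen=True)
class ScheduleEntry:
    """One trial: onset in seconds from run start, category label, 1-based run."""

    onset: float
    condition: str
    run_index: int


@dataclass(frozen=True)
class EventSchedule:
    """Ordered trial list driving both simulation and epoching.

    Invariants checked at construction: within every run onsets are strictly
    increasing with spacing exactly ``trial_duration`` and the first onset is
    at least ``dummy_duration`` after run start.
    """

    entries: tuple[ScheduleEntry, ...]
    trial_duration: float = TRIAL_DURATION
    dummy_duration: float = DUMMY_DURATION

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("schedule has no entries")
        if self.trial_duration <= 0 or self.dummy_duration < 0:
            raise ConfigurationError("durations must be positive")
        for run in self.run_indices:
            onsets = self.onsets(run)
            if onsets[0] < self.dummy_duration:
                raise ConfigurationError(
                    f"run {run}: first onset {onsets[0]} precedes the "
                    f"{self.dummy_duration}-s dummy period"
                )
            spacing = np.diff(onsets)
            if len(spacing) and not np.allclose(spacing, self.trial_duration):
                raise ConfigurationError(
                    f"run {run}: onsets are not spaced by {self.trial_duration} s"
                )

    @property
    def run_indices(self) -> tuple[int, ...]:
        return tuple(sorted({e.run_index for e in self.entries}))

    @property
    def n_runs(self) -> int:
        return len(self.run_indices)

    @property
    def n_trials(self) -> int:
        return len(self.entries)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted({e.condition for e in self.entries}))

    def run_entries(self, run_index: int) -> tuple[ScheduleEntry, ...]:
        return tuple(e for e in self.entries if e.run_index == run_index)

    def onsets(self, run_index: int) -> np.ndarray:
        return np.array([e.onset for e in self.run_entries(run_index)], dtype=float)

    def run_span(self, run_index: int) -> float:
        """Duration of a run in seconds: dummy period plus its trials."""
        return self.dummy_duration + len(self.run_entries(run_index)) * self.trial_duration

    def condition_counts(self) -> Counter:
        return Counter(e.condition for e in self.entries)


def generate_schedule(
    n_runs: int = 4,
    trials_per_run: int = 25,
    conditions: Sequence[str] = CONDITIONS,
    trials_per_condition: int = 20,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    trial_duration: float = TRIAL_DURATION,
    dummy_duration: float = DUMMY_DURATION,
) -> EventSchedule:
    """Pool the per-category trial multiset and deal it into runs at random.

    The pooled list of ``len(conditions) * trials_per_condition`` labels is
    permuted with a seeded generator and cut into ``n_runs`` consecutive runs of
    ``trials_per_run`` trials each; onsets follow the fixed 16-s grid after the
    dummy period.  The permutation conserves per-category counts for every seed.

    Raises
    ------
    ConfigurationError
        If ``n_runs * trials_per_run != len(conditions) * trials_per_condition``.
    """
    conditions = tuple(conditions)
    total = n_runs * trials_per_run
    pooled = len(conditions) * trials_per_condition
    if total != pooled:
        raise ConfigurationError(
            f"{n_runs} runs x {trials_per_run} trials = {total} does not match "
            f"{len(conditions)} conditions x {trials_per_condition} trials = {pooled}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(conditions)), trials_per_condition)
    order = rng.permutation(pool)
    entries = []
    for i, label_idx in enumerate(order):
        run_index = i // trials_per_run + 1
        slot = i % trials_per_run
        onset = dummy_duration + slot * trial_duration
        entries.append(ScheduleEntry(onset, conditions[label_idx], run_index))
    return EventSchedule(
        tuple(entries), trial_duration=trial_duration, dummy_duration=dummy_duration
    )
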