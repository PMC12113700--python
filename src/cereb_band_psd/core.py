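"""Core domain types shared by the generator, I/O and analysis layers.

The vocabulary is fixed by the recording protocol: five annotated
behaviors, three recorded structures, two experimental groups, weekly
sessions.  Episode times are in seconds, half-open ``[onset, offset)``,
signals in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

#: The five behaviors that are analyzed.
BEHAVIORS: tuple[str, ...] = ("resting", "grooming", "locomotion", "rearing", "sniffing")

#: Rare behaviors that may appear in annotation files; accepted but not analyzed.
RARE_BEHAVIORS: tuple[str, ...] = ("yawning", "scratching", "mandibular_tremor")

#: The three recorded structures (cerebellar cortex lobule, inferior olive,
#: dentate nucleus).
STRUCTURES: tuple[str, ...] = ("CrusII", "IO", "DN")

GROUPS: tuple[str, ...] = ("control", "experimental")

QC_OK = "ok"
QC_SATURATION = "excluded_saturation"
QC_EXCURSION = "excluded_excursion"
QC_STATES = (QC_OK, QC_SATURATION, QC_EXCURSION)


class Episode(NamedTuple):
    """One annotated behavioral episode, ``[onset_s, offset_s)`` in seconds."""

    behavior: str
    onset_s: float
    offset_s: float

    @property
    def duration(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class BehaviorSchedule:
    """Ordered, non-overlapping list of behavioral episodes for one session."""

    episodes: list[Episode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.episodes = [Episode(*e) for e in self.episodes]

    def validate(self, duration: float | None = None) -> None:
        """Raise ``ValueError`` on out-of-order, inverted or overlapping episodes."""
        bad = [i for i, e in enumerate(self.episodes) if not e.onset_s < e.offset_s]
        if bad:
            raise ValueError(f"episodes with onset >= offset at rows {bad}")
        order = sorted(range(len(self.episodes)), key=lambda i: self.episodes[i].onset_s)
        overlaps = []
        for a, b in zip(order, order[1:]):
            if self.episodes[b].onset_s < self.episodes[a].offset_s - 1e-5:
                overlaps.append((a, b))
        if overlaps:
            raise ValueError(f"overlapping episode pairs (row indices): {overlaps}")
        if duration is not None:
            out = [
                i
                for i, e in enumerate(self.episodes)
                if e.onset_s < -1e-5 or e.offset_s > duration + 1e-5
            ]
            if out:
                raise ValueError(f"episodes outside [0, {duration}] at rows {out}")

    def for_behavior(self, behavior: str) -> list[Episode]:
        return [e for e in self.episodes if e.behavior == behavior]

    @property
    def behaviors(self) -> set[str]:
        return {e.behavior for e in self.episodes}

    def total_time(self) -> float:
        return float(sum(e.duration for e in self.episodes))

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self) -> Iterable[Episode]:
        return iter(self.episodes)


class ArtifactEvent(NamedTuple):
    """Bookkeeping record of one injected artifact (generator side)."""

    structure: str
    kind: str  # "excursion" | "saturation"
    t_start: float
    t_end: float


@dataclass
class RecordingSession:
    """One rat x week recording: per-structure signal plus behavior episodes.

    Parameters
    ----------
    rat_id : str
        Animal identifier (e.g. ``"E03"``).
    group : str
        ``"control"`` or ``"experimental"``.
    week : int
        Session index, 1-based.
    fs : float
        Sample rate in Hz.
    channels : dict
        Mapping structure label -> signal array (microvolts).
    episodes : BehaviorSchedule
        Annotated behavioral episodes.
    rail : float, optional
        Known saturation level of the acquisition chain (microvolts).
    seed : int, optional
        Creation seed, carried through serialization when present.
    artifacts : list of ArtifactEvent
        Generator bookkeeping; not serialized.
    """

    rat_id: str
    group: str
    week: int
    fs: float
    channels: dict[str, np.ndarray]
    episodes: BehaviorSchedule
    rail: float | None = None
    seed: int | None = None
    artifacts: list[ArtifactEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.week < 1:
            raise ValueError(f"week must be >= 1, got {self.week}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def validate(self, strict_duration: bool = False) -> None:
        """Check channel/episode invariants.

        ``strict_duration=True`` additionally enforces the 500-800 s
        protocol session length (relaxed for fixtures).
        """
        if not self.channels:
            raise ValueError("session has no channels")
        unknown = set(self.channels) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown structure labels {sorted(unknown)}; expected subset of {STRUCTURES}")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channels differ in length: {lengths}")
        if strict_duration and not 500.0 - 1e-6 <= self.duration <= 800.0 + 1e-6:
            raise ValueError(f"session duration {self.duration:.1f} s outside [500, 800] s")
        self.episodes.validate(duration=self.duration)
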