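"""Domain types for heart cycles and cycle sequences.

A *heart cycle* is one systole+diastole unit — in ECG terms, an RR
interval.  A *heart beating process* is a contiguous aggregate of such
cycles: any part of it is again a beating process, and the cycles are its
grains.  The types here enforce that structure: every cycle carries exactly
one positive duration, and a sequence of cycles tiles time without gaps
(the ``follows`` ordering is adjacency).

Times are seconds throughout.  Abstract, unitless duration lists (such as
worked pedagogical examples) are accepted as abstract seconds; rate
thresholds are per-60-seconds regardless of the unit label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Absolute tolerance (seconds) for the contiguity check between cycles.
CONTIGUITY_TOL = 1e-9


class CycleType(enum.Enum):
    """Origin/kind of one heart cycle (input metadata, never detected here)."""

    SA_NODE = "SA_NODE"
    ATRIAL_FIBRILLATION = "ATRIAL_FIBRILLATION"
    VENTRICULAR_ECTOPIC = "VENTRICULAR_ECTOPIC"
    OTHER = "OTHER"


class ValidationError(ValueError):
    """A structural invariant of the cycle model is violated."""


@dataclass(frozen=True)
class CycleEvent:
    """One heart cycle: onset time, duration, and cycle type.

    Every cycle carries exactly one duration, and that duration is
    strictly positive.
    """

    onset: float
    duration: float
    cycle_type: CycleType = CycleType.SA_NODE

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValidationError(f"onset must be non-negative, got {self.onset}")
        if not self.duration > 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class CycleSequence:
    """A contiguous, onset-ordered sequence of cycles.

    Cycles tile time: each cycle starts exactly where its predecessor ends
    (within :data:`CONTIGUITY_TOL`).  Gaps in a recording must be modelled
    explicitly as ``OTHER``-type filler cycles.
    """

    events: tuple[CycleEvent, ...]
    start: float = 0.0

    def __post_init__(self) -> None:
        prev_end = self.start
        prev_onset = -np.inf
        for k, ev in enumerate(self.events):
            if ev.onset <= prev_onset:
                raise ValidationError(
                    f"onsets must be strictly increasing (index {k})"
                )
            if abs(ev.onset - prev_end) > CONTIGUITY_TOL:
                raise ValidationError(
                    f"cycle {k} is not contiguous: onset {ev.onset} != "
                    f"previous end {prev_end}"
                )
            prev_onset = ev.onset
            prev_end = ev.end

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def durations(self) -> list[float]:
        return [ev.duration for ev in self.events]

    @property
    def types(self) -> list[CycleType]:
        return [ev.cycle_type for ev in self.events]

    @property
    def end(self) -> float:
        return self.events[-1].end if self.events else self.start

    @property
    def total_duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class RunSegment:
    """A maximal run of consecutive same-type cycles.

    Runs realise typed sub-beatings (e.g. an atrial-fibrillation episode
    inside an otherwise sinus-driven sequence).
    """

    start_index: int
    length: int
    cycle_type: CycleType

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("run length must be >= 1")


@dataclass
class ValidationReport:
    """Report-style result of beating-process validation; never raises."""

    valid: bool
    issues: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.valid


def build_sequence(
    durations: Sequence[float],
    types: Sequence[CycleType] | None = None,
    start: float = 0.0,
) -> CycleSequence:
    """Build a contiguous :class:`CycleSequence` from durations.

    Onsets are the cumulative sums of *durations* from *start*; the default
    cycle type is ``SA_NODE``.

    Raises
    ------
    ValidationError
        If any duration is non-positive (the message names the offending
        index) or *types* has a different length than *durations*.
    """
    if types is not None and len(types) != len(durations):
        raise ValidationError(
            f"types length {len(types)} != durations length {len(durations)}"
        )
    for k, d in enumerate(durations):
        if not d > 0:
            raise ValidationError(f"non-positive duration {d} at index {k}")
    events = []
    onset = float(start)
    for k, d in enumerate(durations):
        ct = types[k] if types is not None else CycleType.SA_NODE
        events.append(CycleEvent(onset=onset, duration=float(d), cycle_type=ct))
        onset += float(d)
    return CycleSequence(events=tuple(events), start=float(start))


def validate_beating_process(
    seq: CycleSequence | Iterable[CycleEvent],
) -> ValidationReport:
    """Check whether *seq* qualifies as a beating process.

    A beating process must have at least 2 cycles as granular parts, and
    its cycles must be contiguous.  Contiguity is enforced at construction
    for :class:`CycleSequence`; raw event collections assembled by other
    means (e.g. hand-edited recordings) are accepted here and checked
    report-style instead of raising.
    """
    if isinstance(seq, CycleSequence):
        events, start = seq.events, seq.start
    else:
        events = tuple(seq)
        start = events[0].onset if events else 0.0
    issues: list[str] = []
    if len(events) < 2:
        issues.append(
            f"not a beating process (min 2 granular parts, got {len(events)})"
        )
    prev_end = start
    for k, ev in enumerate(events):
        if abs(ev.onset - prev_end) > CONTIGUITY_TOL:
            issues.append(
                f"contiguity violation at cycle {k}: onset {ev.onset} vs "
                f"expected {prev_end}"
            )
        prev_end = ev.end
    return ValidationReport(valid=not issues, issues=issues)


def segment_runs(seq: CycleSequence) -> list[RunSegment]:
    """Run-length encode the cycle types into maximal same-type runs.

    The returned runs partition the index range; concatenating them
    restores the type list.

    Raises
    ------
    ValidationError
        If *seq* is empty.
    """
    if len(seq) == 0:
        raise ValidationError("cannot segment an empty sequence")
    runs: list[RunSegment] = []
    run_start = 0
    run_type = seq.events[0].cycle_type
    for k, ev in enumerate(seq.events[1:], start=1):
        if ev.cycle_type is not run_type:
            runs.append(RunSegment(run_start, k - run_start, run_type))
            run_start, run_type = k, ev.cycle_type
    runs.append(RunSegment(run_start, len(seq) - run_start, run_type))
    return runs


# ---------------------------------------------------------------------------
# CSV interchange: columns onset_s, duration_s, cycle_type (header required)
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("onset_s", "duration_s", "cycle_type")


def to_frame(seq: CycleSequence) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [ev.onset for ev in seq.events],
            "duration_s": [ev.duration for ev in seq.events],
            "cycle_type": [ev.cycle_type.value for ev in seq.events],
        }
    )


def write_csv(seq: CycleSequence, path) -> None:
    to_frame(seq).to_csv(path, index=False)


def read_csv(path) -> CycleSequence:
    """Read a cycle series from CSV; validates header and contiguity."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"CSV missing required columns: {sorted(missing)}")
    if len(df) == 0:
        return CycleSequence(events=(), start=0.0)
    try:
        types = [CycleType(t) for t in df["cycle_type"]]
    except ValueError as exc:
        raise ValidationError(f"unknown cycle_type in CSV: {exc}") from exc
    events = tuple(
        CycleEvent(onset=float(o), duration=float(d), cycle_type=ct)
        for o, d, ct in zip(df["onset_s"], df["duration_s"], types)
    )
    return CycleSequence(events=events, start=float(df["onset_s"].iloc[0]))
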