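"""Process-attribute classifiers for cyclic (heart beating) processes.

A *process attribute* is a fully defined label describing a process
through patterns over its repeated parts: how many cycles fit in a fiat
measuring window (rate), how similar consecutive cycle durations are
(rhythm), how durations trend (accelerating / decelerating / even
patterns), whether cycles come in short/long pairs (bigeminy), and how
typed runs of cycles compose the sequence (chronic vs paroxysmal atrial
fibrillation).

Everything here is deterministic; all randomness lives in
:mod:`cycleont.simulate`.

Threshold provenance
--------------------
The 60/100 cycles-per-minute bounds on the normal rate band are the
standard adult clinical convention; the band is closed (60 and 100 are
both normal) and the fast class starts strictly above 100.  Only adult
defaults are shipped; age-stratified tables are a configuration extension
point.  The rhythm CV threshold, the tolerant-pattern violation fraction,
and the bigeminy ratio are extrinsic engineering defaults — the clinical
vocabulary ("similar intervals", "great variation", "a certain amount of
exceptions") gives no numbers — and each is flagged as such in
:data:`THRESHOLD_PROVENANCE`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .model import (
    CycleSequence,
    CycleType,
    RunSegment,
    ValidationError,
    segment_runs,
    validate_beating_process,
)
from .windows import MeasuringWindow, tile_windows


class AttributeLabel(enum.Enum):
    SLOW_RATE = "SLOW_RATE"
    NORMAL_RATE = "NORMAL_RATE"
    FAST_RATE = "FAST_RATE"
    REGULAR_RHYTHM = "REGULAR_RHYTHM"
    IRREGULAR_RHYTHM = "IRREGULAR_RHYTHM"
    IDEAL_ACCELERATING = "IDEAL_ACCELERATING"
    IDEAL_DECELERATING = "IDEAL_DECELERATING"
    IDEAL_EVEN = "IDEAL_EVEN"
    TOLERANT_ACCELERATING = "TOLERANT_ACCELERATING"
    TOLERANT_DECELERATING = "TOLERANT_DECELERATING"
    BIGEMINAL = "BIGEMINAL"
    CHRONIC_AF = "CHRONIC_AF"
    PAROXYSMAL_AF = "PAROXYSMAL_AF"
    SUDDEN_ONSET = "SUDDEN_ONSET"


@dataclass(frozen=True)
class ProcessAttribute:
    """A classified attribute with the target it describes and the
    threshold values that produced it (for auditability)."""

    label: AttributeLabel
    target: str
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PatternDistanceProfile:
    """Distances of a duration sequence to the three ideal patterns.

    By construction of the metric (sums of signed adjacent increments,
    split by sign), ``even == accel + decel`` always holds.
    """

    accel: float
    decel: float
    even: float


#: Which defaults come from the clinical convention the model encodes and
#: which are extrinsic engineering choices.
THRESHOLD_PROVENANCE: dict[str, str] = {
    "normal_low": "clinical convention (adult normal rate band, 60/min)",
    "normal_high": "clinical convention (adult normal rate band, 100/min)",
    "even_tolerance": "extrinsic (ideal evenness is exact equality)",
    "rhythm_cv_threshold": "extrinsic (no quantified 'similar intervals')",
    "violation_fraction": "extrinsic (no quantified exception allowance)",
    "bigeminy_ratio": "extrinsic (short/long contrast not quantified)",
    "bigeminy_min_pairs": "extrinsic",
    "min_rhythm_cycles": "clinical convention (rhythm needs >= 3 cycles)",
    "af_min_run": "pattern rule (each typed sub-beating needs > 1 grain)",
    "onset_segment_s": "extrinsic (sudden-onset analysis granularity)",
}


@dataclass(frozen=True)
class ThresholdConfig:
    """All tunable thresholds, with adult defaults.

    normal_low / normal_high
        Inclusive bounds of the normal rate band, in cycles per 60 s.
    even_tolerance
        Relative tolerance for adjacent-duration equality in the ideal
        evenness test (0 = exact).
    rhythm_cv_threshold
        Coefficient-of-variation cut between regular and irregular rhythm.
    violation_fraction
        Fraction of adjacent pairs allowed to break a pattern's ideal
        relation in the tolerant pattern tests.
    bigeminy_ratio
        A pair counts as short/long only if short < ratio x long.
    bigeminy_min_pairs
        Minimum consecutive alternating pairs to call bigeminy.
    min_rhythm_cycles
        Minimum cycles for a rhythm judgement (three or more).
    af_min_run
        Minimum cycles per typed run for it to count as a sub-beating
        episode (> 1 grain).
    onset_segment_s
        Tumbling sub-segment length for sudden-onset scanning.
    """

    normal_low: int = 60
    normal_high: int = 100
    even_tolerance: float = 0.0
    rhythm_cv_threshold: float = 0.10
    violation_fraction: float = 0.1
    bigeminy_ratio: float = 0.8
    bigeminy_min_pairs: int = 3
    min_rhythm_cycles: int = 3
    af_min_run: int = 2
    onset_segment_s: float = 10.0

    def __post_init__(self) -> None:
        if self.normal_low > self.normal_high:
            raise ValidationError("normal_low must be <= normal_high")
        for name in ("even_tolerance", "rhythm_cv_threshold", "violation_fraction"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ThresholdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data.get("thresholds", data))

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DEFAULT_CONFIG = ThresholdConfig()


def _require_pairs(durations: Sequence[float]) -> list[tuple[float, float]]:
    if len(durations) < 2:
        raise ValidationError(
            f"need at least 2 cycles to assess a pattern, got {len(durations)}"
        )
    return list(zip(durations, durations[1:]))


def classify_rate(
    grain_count: int,
    window_duration: float = 60.0,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    target: str = "window",
) -> ProcessAttribute:
    """Trichotomous rate label for a measuring window's grain count.

    The 60/100 band is defined for 60-second windows; for other window
    durations the bounds rescale linearly (counts per 60 s).  Exactly one
    of SLOW/NORMAL/FAST is returned for every non-negative count:
    ``count < low`` is slow, ``low <= count <= high`` normal,
    ``count > high`` fast.
    """
    if grain_count < 0:
        raise ValidationError("grain_count must be >= 0")
    if not window_duration > 0:
        raise ValidationError("window_duration must be positive")
    scale = window_duration / 60.0
    low = cfg.normal_low * scale
    high = cfg.normal_high * scale
    if grain_count < low:
        label = AttributeLabel.SLOW_RATE
    elif grain_count <= high:
        label = AttributeLabel.NORMAL_RATE
    else:
        label = AttributeLabel.FAST_RATE
    return ProcessAttribute(
        label=label,
        target=target,
        parameters={
            "grain_count": grain_count,
            "window_duration_s": window_duration,
            "normal_low": low,
            "normal_high": high,
        },
    )


def is_ideal_even(durations: Sequence[float], tol: float = 0.0) -> bool:
    """True iff every adjacent duration pair is equal within relative *tol*.

    The tolerance is relative to the larger duration of the pair; tol 0
    demands exact equality (the ideal even process).
    """
    pairs = _require_pairs(durations)
    return all(abs(b - a) <= tol * max(a, b) for a, b in pairs)


def is_ideal_accelerating(durations: Sequence[float]) -> bool:
    """True iff every cycle is strictly shorter than its predecessor.

    Ties falsify the strict ideal (and falsify deceleration too).
    """
    return all(b < a for a, b in _require_pairs(durations))


def is_ideal_decelerating(durations: Sequence[float]) -> bool:
    """True iff every cycle is strictly longer than its predecessor."""
    return all(b > a for a, b in _require_pairs(durations))


_PATTERNS = ("accelerating", "decelerating", "even")


def tolerant_pattern(
    durations: Sequence[float],
    pattern: str,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> bool:
    """Pattern test allowing a bounded fraction of exceptions.

    True iff the fraction of adjacent pairs violating the pattern's ideal
    relation is at most ``cfg.violation_fraction``.  For ``"even"`` the
    ideal relation is equality within ``cfg.even_tolerance``.
    """
    if pattern not in _PATTERNS:
        raise ValidationError(f"unknown pattern {pattern!r}; choose from {_PATTERNS}")
    pairs = _require_pairs(durations)
    if pattern == "accelerating":
        violations = sum(1 for a, b in pairs if not b < a)
    elif pattern == "decelerating":
        violations = sum(1 for a, b in pairs if not b > a)
    else:
        violations = sum(
            1 for a, b in pairs if abs(b - a) > cfg.even_tolerance * max(a, b)
        )
    return violations / len(pairs) <= cfg.violation_fraction


def pattern_distances(durations: Sequence[float]) -> PatternDistanceProfile:
    """Distances to the three ideal patterns as total violation magnitude.

    Over adjacent pairs ``(d_{k-1}, d_k)``:

    * ``accel = sum max(0, d_k - d_{k-1})`` — total magnitude of duration
      increases (each increase moves the sequence away from acceleration);
    * ``decel = sum max(0, d_{k-1} - d_k)`` — total magnitude of decreases;
    * ``even  = sum |d_k - d_{k-1}|`` — total absolute change.

    ``even == accel + decel`` by construction.  Magnitude sums (rather
    than violation counts) are used because they give a strict closeness
    ordering on sequences where pair counting ties; the split of the
    continuum between accelerating, even and decelerating is fiat either
    way.
    """
    pairs = _require_pairs(durations)
    diffs = np.array([b - a for a, b in pairs], dtype=float)
    accel = float(np.sum(np.clip(diffs, 0.0, None)))
    decel = float(np.sum(np.clip(-diffs, 0.0, None)))
    return PatternDistanceProfile(accel=accel, decel=decel, even=accel + decel)


def classify_rhythm(
    durations: Sequence[float],
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    target: str = "segment",
) -> ProcessAttribute:
    """Regular vs irregular rhythm via the coefficient of variation.

    A rhythm judgement requires at least ``cfg.min_rhythm_cycles`` cycles
    (three or more subsequent cycles).  CV = sample std / mean of the
    durations; CV <= threshold is regular.
    """
    if len(durations) < cfg.min_rhythm_cycles:
        raise ValidationError(
            f"rhythm requires at least {cfg.min_rhythm_cycles} subsequent "
            f"cycles, got {len(durations)}"
        )
    arr = np.asarray(durations, dtype=float)
    cv = float(arr.std(ddof=1) / arr.mean())
    label = (
        AttributeLabel.REGULAR_RHYTHM
        if cv <= cfg.rhythm_cv_threshold
        else AttributeLabel.IRREGULAR_RHYTHM
    )
    return ProcessAttribute(
        label=label,
        target=target,
        parameters={"cv": cv, "rhythm_cv_threshold": cfg.rhythm_cv_threshold},
    )


def detect_bigeminy(
    durations: Sequence[float], cfg: ThresholdConfig = DEFAULT_CONFIG
) -> bool:
    """Detect bigeminal short/long pairing of cycle durations.

    Bigeminy pairs a normal beat with a premature beat, so durations
    alternate short/long.  True iff, starting at either parity and in
    either orientation, at least ``cfg.bigeminy_min_pairs`` consecutive
    non-overlapping pairs each satisfy ``short < bigeminy_ratio * long``.

    Sequences too short to hold that many pairs return False (not an
    error).
    """
    n = len(durations)
    if n < 2 * cfg.bigeminy_min_pairs:
        return False
    for phase in (0, 1):
        for short_first in (True, False):
            streak = 0
            for i in range(phase, n - 1, 2):
                a, b = durations[i], durations[i + 1]
                short, long = (a, b) if short_first else (b, a)
                if short < cfg.bigeminy_ratio * long:
                    streak += 1
                    if streak >= cfg.bigeminy_min_pairs:
                        return True
                else:
                    streak = 0
    return False


def classify_af_pattern(
    runs: Sequence[RunSegment],
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    target: str = "sequence",
) -> Optional[ProcessAttribute]:
    """Chronic vs paroxysmal atrial fibrillation from typed runs.

    * all cycles AF-typed -> CHRONIC_AF (the beating has only AF cycles
      as parts);
    * at least 2 AF runs of length >= ``af_min_run`` AND at least 1
      sinus (SA-node) run of length >= ``af_min_run`` -> PAROXYSMAL_AF
      (episodes separated by normal beating);
    * no AF cycles -> None;
    * otherwise None — AF cycles are present but form no qualifying
      episode structure (isolated ectopy; the orchestrator notes this).
    """
    if not runs:
        raise ValidationError("empty run list")
    af_runs = [r for r in runs if r.cycle_type is CycleType.ATRIAL_FIBRILLATION]
    if not af_runs:
        return None
    total = sum(r.length for r in runs)
    af_total = sum(r.length for r in af_runs)
    if af_total == total:
        return ProcessAttribute(
            label=AttributeLabel.CHRONIC_AF,
            target=target,
            parameters={"n_cycles": total},
        )
    af_episodes = [r for r in af_runs if r.length >= cfg.af_min_run]
    sa_episodes = [
        r
        for r in runs
        if r.cycle_type is CycleType.SA_NODE and r.length >= cfg.af_min_run
    ]
    if len(af_episodes) >= 2 and len(sa_episodes) >= 1:
        return ProcessAttribute(
            label=AttributeLabel.PAROXYSMAL_AF,
            target=target,
            parameters={
                "n_af_episodes": len(af_episodes),
                "n_sa_episodes": len(sa_episodes),
                "af_min_run": cfg.af_min_run,
            },
        )
    return None


def detect_sudden_onset(
    seq: CycleSequence, cfg: ThresholdConfig = DEFAULT_CONFIG
) -> list[tuple[float, AttributeLabel, str]]:
    """Find sudden-onset-of-acceleration boundaries in a sequence.

    The sequence is cut into tumbling sub-segments of
    ``cfg.onset_segment_s`` seconds.  An onset event is the shared
    boundary instant between a segment labelled NORMAL_RATE that is *not*
    itself tolerantly accelerating and an immediately following segment
    that is tolerantly accelerating: the end instant of steady normal
    beating coincides with the start instant of the acceleration.

    Returns (boundary time, preceding rate label, following pattern name)
    tuples; an empty list when no onset is present.
    """
    segments = tile_windows(seq, window_duration=cfg.onset_segment_s, mode="tumbling")
    events: list[tuple[float, AttributeLabel, str]] = []
    durs = seq.durations

    def seg_durations(w: MeasuringWindow) -> list[float]:
        return [durs[k] for k in w.contained_cycle_indices]

    for prev, nxt in zip(segments, segments[1:]):
        prev_d, next_d = seg_durations(prev), seg_durations(nxt)
        if len(prev_d) < 2 or len(next_d) < 2:
            continue
        prev_rate = classify_rate(prev.grain_count, prev.duration, cfg)
        if prev_rate.label is not AttributeLabel.NORMAL_RATE:
            continue
        if tolerant_pattern(prev_d, "accelerating", cfg):
            continue  # already accelerating: no new onset at this boundary
        if tolerant_pattern(next_d, "accelerating", cfg):
            events.append((nxt.start, prev_rate.label, "accelerating"))
    return events


@dataclass
class AttributeProfile:
    """Full deterministic attribute profile of a cycle sequence."""

    attributes: list[ProcessAttribute]
    windows: list[MeasuringWindow]
    notes: list[str] = field(default_factory=list)


def attribute_profile(
    seq: CycleSequence,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    window_duration: float = 60.0,
) -> AttributeProfile:
    """Run every classifier over *seq*: per-window rate and rhythm,
    whole-sequence patterns, bigeminy, AF structure and sudden onsets.

    Raises :class:`ValidationError` if *seq* is not a valid beating
    process (fewer than 2 cycles or non-contiguous).
    """
    report = validate_beating_process(seq)
    if not report:
        raise ValidationError("; ".join(report.issues))

    attrs: list[ProcessAttribute] = []
    notes: list[str] = []
    wins = tile_windows(seq, window_duration=window_duration, mode="tumbling")
    durs = seq.durations

    for i, w in enumerate(wins):
        target = f"window[{i}]@{w.start:g}s"
        attrs.append(classify_rate(w.grain_count, w.duration, cfg, target=target))
        wd = [durs[k] for k in w.contained_cycle_indices]
        if len(wd) >= cfg.min_rhythm_cycles:
            attrs.append(classify_rhythm(wd, cfg, target=target))
        else:
            notes.append(f"{target}: too few cycles for a rhythm judgement")

    if len(durs) >= 2:
        dist = pattern_distances(durs)
        params = {"accel": dist.accel, "decel": dist.decel, "even": dist.even}
        if is_ideal_even(durs, cfg.even_tolerance):
            attrs.append(
                ProcessAttribute(AttributeLabel.IDEAL_EVEN, "sequence", params)
            )
        if is_ideal_accelerating(durs):
            attrs.append(
                ProcessAttribute(AttributeLabel.IDEAL_ACCELERATING, "sequence", params)
            )
        elif tolerant_pattern(durs, "accelerating", cfg):
            attrs.append(
                ProcessAttribute(
                    AttributeLabel.TOLERANT_ACCELERATING, "sequence", params
                )
            )
        if is_ideal_decelerating(durs):
            attrs.append(
                ProcessAttribute(AttributeLabel.IDEAL_DECELERATING, "sequence", params)
            )
        elif tolerant_pattern(durs, "decelerating", cfg):
            attrs.append(
                ProcessAttribute(
                    AttributeLabel.TOLERANT_DECELERATING, "sequence", params
                )
            )
        if detect_bigeminy(durs, cfg):
            attrs.append(
                ProcessAttribute(
                    AttributeLabel.BIGEMINAL,
                    "sequence",
                    {
                        "bigeminy_ratio": cfg.bigeminy_ratio,
                        "bigeminy_min_pairs": cfg.bigeminy_min_pairs,
                    },
                )
            )

    runs = segment_runs(seq)
    af_attr = classify_af_pattern(runs, cfg)
    if af_attr is not None:
        attrs.append(af_attr)
    elif any(r.cycle_type is CycleType.ATRIAL_FIBRILLATION for r in runs):
        notes.append("isolated ectopy: AF cycles present without episode structure")

    for t, prev_label, pattern in detect_sudden_onset(seq, cfg):
        attrs.append(
            ProcessAttribute(
                AttributeLabel.SUDDEN_ONSET,
                f"boundary@{t:g}s",
                {"preceding": prev_label.value, "following": pattern},
            )
        )

    return AttributeProfile(attributes=attrs, windows=wins, notes=notes)
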