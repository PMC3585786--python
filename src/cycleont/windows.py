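"""Fiat measuring windows over a cycle sequence.

Heart rate is defined over a stipulated (fiat) measurement interval —
conventionally 60 seconds.  A window is the half-open interval
``[start, start + duration)``; a cycle is *contained* in a window iff it
lies wholly inside it (full cycles only), and the window's *grain count*
is the number of contained cycles.  A trailing span shorter than the
window duration yields no window: a 45-second tail is not a sixty-second
beating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import CycleSequence


@dataclass(frozen=True)
class MeasuringWindow:
    """A fiat temporal interval with its fully contained cycles.

    The interval is half-open, ``[start, start + duration)``, so abutting
    tumbling windows never double count a cycle at a shared boundary.
    """

    start: float
    duration: float = 60.0
    contained_cycle_indices: tuple[int, ...] = field(default_factory=tuple)

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def grain_count(self) -> int:
        return len(self.contained_cycle_indices)

    def contains(self, onset: float, cycle_duration: float) -> bool:
        """Full containment: the whole cycle lies within the window.

        Boundary comparisons tolerate 1e-9 s so that cycles tiling a
        window exactly are not lost to float accumulation.
        """
        return (
            onset >= self.start - 1e-9
            and onset + cycle_duration <= self.end + 1e-9
        )


def _populate(window_start: float, window_duration: float, seq: CycleSequence) -> MeasuringWindow:
    end = window_start + window_duration
    contained = tuple(
        k
        for k, ev in enumerate(seq.events)
        if ev.onset >= window_start - 1e-9 and ev.end <= end + 1e-9
    )
    return MeasuringWindow(
        start=window_start,
        duration=window_duration,
        contained_cycle_indices=contained,
    )


def tile_windows(
    seq: CycleSequence,
    window_duration: float = 60.0,
    mode: str = "tumbling",
    step: float | None = None,
) -> list[MeasuringWindow]:
    """Segment *seq* into fixed-duration measuring windows.

    Parameters
    ----------
    seq:
        The cycle sequence to segment.
    window_duration:
        Window length in seconds (> 0); default 60.
    mode:
        ``"tumbling"`` — windows start at ``seq.start`` and abut;
        ``"sliding"`` — windows advance by *step* seconds (default 1.0).
    step:
        Slide step in seconds; only meaningful for sliding mode.

    Returns
    -------
    list of :class:`MeasuringWindow` with containment sets populated.  A
    trailing span shorter than *window_duration* yields no window.
    """
    if not window_duration > 0:
        raise ValueError(f"window_duration must be positive, got {window_duration}")
    if mode not in ("tumbling", "sliding"):
        raise ValueError(f"unknown window mode {mode!r}")
    if mode == "tumbling":
        stride = window_duration
    else:
        stride = 1.0 if step is None else float(step)
        if not stride > 0:
            raise ValueError(f"sliding step must be positive, got {step}")

    windows: list[MeasuringWindow] = []
    start = seq.start
    # Small tolerance so float accumulation does not drop a final exact window.
    while start + window_duration <= seq.end + 1e-9:
        windows.append(_populate(start, window_duration, seq))
        start += stride
    return windows


def count_grains(window: MeasuringWindow) -> int:
    """Number of cycles wholly inside the window's half-open interval."""
    return window.grain_count
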