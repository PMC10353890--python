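"""Behavioural event records shared by the simulator and the detectors.

Frame intervals are half-open ``[start, end)`` on the shared frame axis, so
``end - start`` divided by the frame rate is the event duration in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChaseEvent", "ChainEvent", "interval_overlap", "events_to_intervals"]


@dataclass(frozen=True)
class ChaseEvent:
    """One fly pursuing another: ``chaser`` trails ``target``."""

    chaser: int
    target: int
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("event end must be >= start")

    def duration_s(self, frame_rate: float) -> float:
        return (self.end - self.start) / frame_rate


@dataclass(frozen=True)
class ChainEvent:
    """A single-file follow-line of flies, each trailing the one ahead.

    ``members`` are listed in follow order, leader first.
    """

    members: tuple[int, ...]
    start: int
    end: int
    mean_speed_mm_s: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        if self.end < self.start:
            raise ValueError("event end must be >= start")

    def duration_s(self, frame_rate: float) -> float:
        return (self.end - self.start) / frame_rate


def interval_overlap(a_start, a_end, b_start, b_end) -> float:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


def events_to_intervals(events, frame_rate: float) -> list[tuple[float, float]]:
    """Convert frame-indexed events to (start_s, end_s) second intervals."""
    out = []
    for ev in events:
        out.append((ev.start / frame_rate, ev.end / frame_rate))
    return out
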