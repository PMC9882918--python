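"""Pulse regimens: ordered on/off antibiotic phase schedules.

Convention: a cycle is on-then-off.  Cycle boundaries (the per-cycle
population peaks in an eradicating regimen) fall at t = l*(t_on + t_off).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

__all__ = ["Segment", "PulseRegimen"]

_PHASES = ("on", "off")


@dataclass(frozen=True)
class Segment:
    phase: str
    duration_h: float

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise ValueError(f"phase must be 'on' or 'off', got {self.phase!r}")
        if not self.duration_h > 0:
            raise ValueError(f"duration must be positive, got {self.duration_h}")


@dataclass(frozen=True)
class PulseRegimen:
    """An ordered schedule of antibiotic on/off segments."""

    segments: Tuple[Segment, ...]

    def __init__(self, segments: Iterable):
        segs = tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in segments
        )
        object.__setattr__(self, "segments", segs)

    @classmethod
    def uniform(cls, t_on: float, t_off: float, n_cycles: int) -> "PulseRegimen":
        """n_cycles repetitions of (on for t_on) then (off for t_off)."""
        if n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
        segs: List[Segment] = []
        for _ in range(n_cycles):
            segs.append(Segment("on", t_on))
            segs.append(Segment("off", t_off))
        return cls(segs)

    @classmethod
    def constant(cls, phase: str, duration_h: float) -> "PulseRegimen":
        """A single phase held for the whole duration (e.g. constant dosing)."""
        return cls([Segment(phase, duration_h)])

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def total_duration_h(self) -> float:
        return sum(s.duration_h for s in self.segments)

    def as_uniform(self) -> Optional[Tuple[float, float, int]]:
        """(t_on, t_off, n_cycles) if the schedule is a uniform pulse train, else None."""
        segs = self.segments
        if len(segs) < 2 or len(segs) % 2:
            return None
        t_on, t_off = segs[0].duration_h, segs[1].duration_h
        for i, s in enumerate(segs):
            want_phase = "on" if i % 2 == 0 else "off"
            want_dur = t_on if i % 2 == 0 else t_off
            if s.phase != want_phase or s.duration_h != want_dur:
                return None
        return (t_on, t_off, len(segs) // 2)

    def phase_boundaries(self):
        """Cumulative segment end times, starting after t=0."""
        t, out = 0.0, []
        for s in self.segments:
            t += s.duration_h
            out.append(t)
        return out

    def cycle_starts(self, period: Optional[float] = None):
        """Times t_2l = l*(t_on + t_off) for a uniform regimen (peaks)."""
        u = self.as_uniform()
        if u is None:
            raise ValueError("cycle starts are defined for uniform regimens only")
        t_on, t_off, n = u
        period = t_on + t_off
        return [l * period for l in range(n + 1)]

    def to_records(self):
        return [{"phase": s.phase, "duration_h": s.duration_h} for s in self.segments]

    @classmethod
    def from_records(cls, records) -> "PulseRegimen":
        return cls([Segment(r["phase"], float(r["duration_h"])) for r in records])
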