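"""Time–activity curves, frame schedules and physical-decay handling.

Whole-body PET dosimetry protocols acquire a handful of multi-minute
bed passes separated by rest gaps (e.g. 0–8, 12–20, … 112–120 min after
injection).  Each organ's activity is reported once per pass, so a
time–activity curve (TAC) is a short, irregularly spaced series of
activities in MBq.  Internal dosimetry integrates the *decay-uncorrected*
TAC — the activity physically present in the organ — whereas image
reconstructions usually report decay-corrected values referenced to
injection time; both representations and the conversion between them
live here.

Canonical units: frame times in minutes since injection, activities in
MBq, isotope decay constants in h⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Isotope",
    "F18",
    "FrameSchedule",
    "TimeActivityCurve",
    "Subject",
    "frame_midpoints",
    "decay_uncorrect",
    "decay_correct",
    "MINUTES_PER_HOUR",
]

MINUTES_PER_HOUR = 60.0


@dataclass(frozen=True)
class Isotope:
    """A radionuclide defined by its physical half-life.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"F-18"``.
    half_life_min : float
        Physical half-life in minutes; must be positive.

    The decay constant is derived, never stored, so the two can never
    drift apart.
    """

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if not self.half_life_min > 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_min}")

    @property
    def half_life_h(self) -> float:
        return self.half_life_min / MINUTES_PER_HOUR

    @property
    def decay_constant_per_h(self) -> float:
        """λ = ln2 / T½ in h⁻¹."""
        return math.log(2.0) / self.half_life_h

    @property
    def mean_life_h(self) -> float:
        """T½/ln2 in hours — the residence time of a trapped, non-excreting
        deposit of the full injected activity (≈2.64 h for F-18)."""
        return self.half_life_h / math.log(2.0)

    def decay_factor(self, t_min: float) -> float:
        """exp(−λt) for a time ``t_min`` minutes after injection."""
        return math.exp(-self.decay_constant_per_h * t_min / MINUTES_PER_HOUR)


#: Fluorine-18 with the conventional 109.77 min half-life
#: (T½/ln2 = 2.6394 h, the remainder-of-body closure constant).
F18 = Isotope("F-18", 109.77)


@dataclass(frozen=True)
class FrameSchedule:
    """An ordered set of acquisition frames (start, end) in minutes.

    Frames must be non-overlapping and strictly increasing; rest gaps
    between bed passes are allowed and simply not sampled.
    """

    intervals: Tuple[Tuple[float, float], ...]

    def __init__(self, intervals: Sequence[Sequence[float]]):
        ivals = tuple((float(a), float(b)) for a, b in intervals)
        for a, b in ivals:
            if not a < b:
                raise ValueError(f"frame start must precede end, got ({a}, {b})")
            if a < 0:
                raise ValueError(f"frame start before injection: {a}")
        for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError(f"frames overlap or are out of order near t={s1} min")
        object.__setattr__(self, "intervals", ivals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def midpoints_min(self) -> np.ndarray:
        return frame_midpoints(self)

    @property
    def midpoints_h(self) -> np.ndarray:
        return frame_midpoints(self) / MINUTES_PER_HOUR

    @classmethod
    def uniform(cls, start_min: float, end_min: float, n_frames: int) -> "FrameSchedule":
        """Contiguous equal frames covering [start, end] — dense reference
        schedules for convergence studies."""
        edges = np.linspace(start_min, end_min, n_frames + 1)
        return cls(list(zip(edges[:-1], edges[1:])))


#: The two acquisition schedules used in the clinical protocols this
#: package emulates (minutes post-injection, 4 min rest between passes).
T807_SCHEDULE = FrameSchedule(
    [(0, 8), (12, 20), (24, 32), (40, 48), (60, 68), (84, 92), (112, 120)]
)
MEFWAY_SCHEDULE = FrameSchedule([(0, 16), (20, 36), (40, 56), (60, 84), (90, 114)])


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Midpoint time of each frame, in minutes.

    Each multi-minute frame is reduced to a single sample at its
    temporal midpoint; the TAC is then integrated as a point series.
    """
    if len(schedule) == 0:
        raise ValueError("schedule has no frames")
    return np.array([(a + b) / 2.0 for a, b in schedule.intervals])


@dataclass(frozen=True)
class TimeActivityCurve:
    """One organ's sampled activity on a frame schedule.

    ``decay_corrected`` records whether values have been rescaled to
    remove physical decay (reference time = injection).  Dosimetry
    consumes decay-uncorrected curves.
    """

    organ: str
    schedule: FrameSchedule
    activity_mbq: Tuple[float, ...]
    decay_corrected: bool = False

    def __init__(self, organ, schedule, activity_mbq, decay_corrected=False):
        act = tuple(float(a) for a in activity_mbq)
        if len(act) != len(schedule):
            raise ValueError(
                f"{organ}: {len(act)} activities for {len(schedule)} frames"
            )
        for i, a in enumerate(act):
            if a < 0:
                raise ValueError(f"{organ}: negative activity {a} MBq at frame {i}")
        object.__setattr__(self, "organ", str(organ))
        object.__setattr__(self, "schedule", schedule)
        object.__setattr__(self, "activity_mbq", act)
        object.__setattr__(self, "decay_corrected", bool(decay_corrected))

    @property
    def times_h(self) -> np.ndarray:
        return self.schedule.midpoints_h

    @property
    def values(self) -> np.ndarray:
        return np.array(self.activity_mbq)


def decay_uncorrect(tac: TimeActivityCurve, isotope: Isotope) -> TimeActivityCurve:
    """Convert a decay-corrected TAC to the physically present activity.

    Multiplies each sample at midpoint t by exp(−λt).  Errors if the
    curve is already uncorrected — a silent second application would
    halve the dose estimate per half-life of scan time.
    """
    if not tac.decay_corrected:
        raise ValueError(f"{tac.organ}: TAC is already decay-uncorrected")
    t_min = frame_midpoints(tac.schedule)
    act = [a * isotope.decay_factor(t) for a, t in zip(tac.activity_mbq, t_min)]
    return replace(tac, activity_mbq=tuple(act), decay_corrected=False)


def decay_correct(tac: TimeActivityCurve, isotope: Isotope) -> TimeActivityCurve:
    """Inverse of :func:`decay_uncorrect` (multiply by exp(+λt))."""
    if tac.decay_corrected:
        raise ValueError(f"{tac.organ}: TAC is already decay-corrected")
    t_min = frame_midpoints(tac.schedule)
    act = [a / isotope.decay_factor(t) for a, t in zip(tac.activity_mbq, t_min)]
    return replace(tac, activity_mbq=tuple(act), decay_corrected=True)


@dataclass
class Subject:
    """One scanned subject: identity, injected activity and organ TACs."""

    id: str
    sex: str
    injected_mbq: float
    isotope: Isotope = field(default=F18)
    tacs: Dict[str, TimeActivityCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.injected_mbq > 0:
            raise ValueError(f"injected activity must be positive, got {self.injected_mbq}")

    @property
    def organs(self) -> List[str]:
        return list(self.tacs)

    def uncorrected(self) -> "Subject":
        """Return a copy with every TAC decay-uncorrected (no-op per TAC
        already in physical units)."""
        tacs = {
            o: decay_uncorrect(t, self.isotope) if t.decay_corrected else t
            for o, t in self.tacs.items()
        }
        return Subject(self.id, self.sex, self.injected_mbq, self.isotope, tacs)
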