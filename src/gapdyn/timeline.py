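"""Developmental timeline and timed illumination scenarios.

All times are minutes on a clock anchored at the onset of gastrulation
(t = 0); negative values are time before gastrulation.  The syncytial
blastoderm timeline used throughout: nuclear cycle 14 occupies the last
45 min, cycle 13 the 15 min before that, and cycles 10-12 roughly the
preceding 30 min, with the whole blastoderm stage spanning 2.5 hr from
fertilisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class DevTimeline:
    """Stage boundaries of the late syncytial blastoderm, in minutes."""

    gastrulation_t: float = 0.0
    nc14: tuple = (-45.0, 0.0)
    nc13: tuple = (-60.0, -45.0)
    nc10_12: tuple = (-90.0, -60.0)
    blastoderm_total: float = 150.0

    def __post_init__(self):
        spans = (self.nc14, self.nc13, self.nc10_12)
        durations = (45.0, 15.0, 30.0)
        for (a, b), dur in zip(spans, durations):
            if not np.isclose(b - a, dur):
                raise InvalidInputError(f"stage ({a}, {b}) must last {dur} min")
        if not (np.isclose(self.nc13[1], self.nc14[0])
                and np.isclose(self.nc10_12[1], self.nc13[0])):
            raise InvalidInputError("stage intervals must be contiguous")


@dataclass(frozen=True)
class IlluminationScenario:
    """Time windows during which Bcd-dependent transcription is off.

    Windows are half-open [start, end) pairs on the gastrulation clock,
    sorted and non-overlapping, each ending at or before gastrulation.
    An empty window list is the dark control.
    """

    id: str = "dark"
    windows: tuple = ()

    def __post_init__(self):
        wins = tuple((float(a), float(b)) for a, b in self.windows)
        object.__setattr__(self, "windows", wins)
        prev_end = -np.inf
        for a, b in wins:
            if a >= b:
                raise InvalidInputError(f"window ({a}, {b}) must have start < end")
            if b > 0:
                raise InvalidInputError(f"window ({a}, {b}) must end by t = 0")
            if a < prev_end:
                raise InvalidInputError("windows must be sorted and non-overlapping")
            prev_end = b

    def illuminated(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.windows)

    @property
    def first_window_start(self) -> float:
        return self.windows[0][0] if self.windows else np.inf


def scenario_to_mask(scenario: IlluminationScenario, times) -> np.ndarray:
    """Boolean Bcd-activity mask: True where no illumination window covers t.

    ``times`` must be sorted ascending; windows use the half-open
    convention [start, end).
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise InvalidInputError("times must be sorted")
    lit = np.zeros(times.shape, dtype=bool)
    for a, b in scenario.windows:
        lit |= (times >= a) & (times < b)
    return ~lit


def default_battery() -> list[IlluminationScenario]:
    """The eight-scenario illumination battery.

    Scenario 1 is the dark control; 2-5 start progressively earlier and
    run to gastrulation; 6 and 7 are early illumination with dark
    recovery over the last 30 or 60 min; 8 ends before cycle 10.
    """
    spec = {
        "1": (),
        "2": ((-20.0, 0.0),),
        "3": ((-30.0, 0.0),),
        "4": ((-45.0, 0.0),),
        "5": ((-60.0, 0.0),),
        "6": ((-90.0, -30.0),),
        "7": ((-90.0, -60.0),),
        "8": ((-120.0, -90.0),),
    }
    return [IlluminationScenario(id=k, windows=v) for k, v in spec.items()]


def model_battery() -> list[IlluminationScenario]:
    """Scenarios 1-6, the subset run through the circuit model."""
    return default_battery()[:6]
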