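"""Mesopic microperimetry simulation: 4-2 staircase, exam loop, locus classes.

The simulated instrument follows the MP-1 protocol: a white Goldmann III
stimulus (0.43 deg), attenuation range 0-20 dB, starting level 10 dB, and a
4-2 staircase.  A locus with no response to the brightest 0-dB stimulus is an
absolute scotoma, coded -1.

Staircase convention (the instrument's exact termination rule is not public;
this is the conventional two-reversal/last-seen reading of a 4-2 strategy):
a *reversal* is a seen-to-not-seen transition; steps are 4 dB before the first
reversal and 2 dB after; the staircase terminates on the second reversal, or
when the ceiling is seen, or when the floor (0 dB) is not seen; the measured
sensitivity is the last seen attenuation, clipped to the range.

Because the stimulus covers an extended retinal area rather than a point, each
locus observer aggregates the sensitivity field over the stimulus footprint
(centre plus a hexagonal ring at the stimulus radius).  The default
aggregation is ``max``: stimulation of surviving retina anywhere under the
footprint suffices to elicit a response, which is what makes loci straddling a
lesion border come out non-absolute.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .geometry import StimulusSpec, TestGrid
from .phantom import Phantom

__all__ = [
    "ABSOLUTE",
    "LocusClass",
    "SensitivityMap",
    "ExamConfig",
    "staircase_4_2",
    "make_footprint_observer",
    "simulate_exam",
    "classify_locus",
]

#: Sentinel sensitivity for an absolute scotoma (no response at 0 dB).
ABSOLUTE: float = -1.0


class LocusClass(enum.Enum):
    """Three-way partition of measured sensitivity."""

    ABSOLUTE = "absolute"
    RELATIVE = "relative"
    NONSCOTOMATOUS = "nonscotomatous"


def classify_locus(value: float) -> LocusClass:
    """Classify a measured sensitivity: -1 absolute; [0, 8] relative; (8, 20] non-scotomatous.

    8 dB itself counts as a relative scotoma (the non-scotomatous class is
    strictly greater than 8 dB).
    """
    if value == ABSOLUTE:
        return LocusClass.ABSOLUTE
    if not 0.0 <= value <= 20.0:
        raise ValueError(f"sensitivity {value} outside [-1] + [0, 20] dB")
    if value <= 8.0:
        return LocusClass.RELATIVE
    return LocusClass.NONSCOTOMATOUS


def staircase_4_2(
    observer: Callable[[float], bool],
    start_db: float = 10.0,
    db_range: tuple[float, float] = (0.0, 20.0),
    max_presentations: int = 50,
) -> float:
    """Run a 4-2 staircase against a yes/no observer; return dB or ``ABSOLUTE``.

    ``observer(attenuation_db)`` must return True iff the stimulus is seen.
    Seen responses step the attenuation up (dimmer), unseen down (brighter);
    the step is 4 dB until the first seen-to-not-seen reversal, 2 dB after,
    and the staircase ends on the second such reversal (measured sensitivity =
    last seen level), on a seen ceiling stimulus (= ceiling), or on an unseen
    floor stimulus (= absolute scotoma, -1).
    """
    lo, hi = float(db_range[0]), float(db_range[1])
    if not lo <= start_db <= hi:
        raise ValueError("start_db outside db_range")

    level = float(start_db)
    step = 4.0
    reversals = 0
    last_seen: float | None = None
    prev_response: bool | None = None

    for _ in range(max_presentations):
        seen = observer(level)
        if not isinstance(seen, (bool, np.bool_)):
            raise TypeError(f"observer must return a bool, got {type(seen).__name__}")
        seen = bool(seen)
        if seen:
            last_seen = level
            if level >= hi:
                return hi
        else:
            if level <= lo:
                return ABSOLUTE if last_seen is None else max(last_seen, lo)
            if prev_response is True:
                reversals += 1
                step = 2.0
                if reversals >= 2:
                    return min(max(last_seen, lo), hi)
        prev_response = seen
        level = min(hi, max(lo, level + step if seen else level - step))
    raise RuntimeError("staircase failed to terminate (non-stationary observer?)")


def _footprint_offsets(diameter_deg: float, n_ring: int = 6) -> np.ndarray:
    """Sampling offsets over the stimulus footprint: centre + hexagonal ring at the radius."""
    r = diameter_deg / 2.0
    ang = 2.0 * math.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return np.vstack([[0.0, 0.0], ring])


def make_footprint_observer(
    phantom: Phantom,
    x_deg: float,
    y_deg: float,
    stimulus: StimulusSpec = StimulusSpec(),
    aggregation: Literal["max", "mean"] = "max",
    psychometric_slope_db: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Callable[[float], bool]:
    """Yes/no observer for one locus, driven by the phantom's sensitivity field.

    The effective sensitivity is the max (default) or mean of the field over
    the stimulus footprint.  With a zero psychometric slope the observer is
    deterministic (sees iff attenuation <= effective sensitivity); a positive
    slope makes the response probabilistic with a logistic psychometric
    function of that slope (dB).
    """
    offsets = _footprint_offsets(stimulus.diameter_deg)
    field = phantom.sensitivity(x_deg + offsets[:, 0], y_deg + offsets[:, 1])
    if aggregation == "max":
        eff = float(np.max(field))
    elif aggregation == "mean":
        eff = float(np.mean(field))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    if psychometric_slope_db > 0 and rng is None:
        raise ValueError("a stochastic observer needs an rng")

    def observer(attenuation_db: float) -> bool:
        if psychometric_slope_db <= 0:
            return attenuation_db <= eff
        p = 1.0 / (1.0 + math.exp((attenuation_db - eff) / psychometric_slope_db))
        return bool(rng.random() < p)

    return observer


@dataclass(frozen=True)
class SensitivityMap:
    """Measured sensitivities on a test grid: dB in [0, 20] or -1 (absolute)."""

    grid: TestGrid
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.grid):
            raise ValueError("one value per locus required")
        for v in self.values:
            if v != ABSOLUTE and not 0.0 <= v <= 20.0:
                raise ValueError(f"sensitivity {v} outside [-1] + [0, 20] dB")

    def value_of(self, locus_id: int) -> float:
        for locus, v in zip(self.grid, self.values):
            if locus.locus_id == locus_id:
                return v
        raise KeyError(locus_id)

    def classes(self) -> tuple[LocusClass, ...]:
        return tuple(classify_locus(v) for v in self.values)

    def to_frame(self):
        df = self.grid.to_frame()
        df["value_db"] = list(self.values)
        df["locus_class"] = [c.value for c in self.classes()]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ExamConfig:
    """Parameters of a simulated microperimetry examination."""

    stimulus: StimulusSpec = StimulusSpec()
    start_db: float = 10.0
    aggregation: Literal["max", "mean"] = "max"
    psychometric_slope_db: float = 0.0


def simulate_exam(
    phantom: Phantom,
    grid: TestGrid,
    config: ExamConfig = ExamConfig(),
    seed: int | None = None,
) -> SensitivityMap:
    """Simulate a full microperimetry test of ``phantom`` on ``grid``.

    With the default deterministic observer the result is seed-independent
    (the follow-up-mode analogue: repeat runs are identical); ``seed`` only
    matters when a psychometric slope is configured.
    """
    rng = None
    if config.psychometric_slope_db > 0:
        rng = np.random.default_rng(phantom.seed if seed is None else seed)
    values = []
    for locus in grid:
        observer = make_footprint_observer(
            phantom,
            locus.x_deg,
            locus.y_deg,
            stimulus=config.stimulus,
            aggregation=config.aggregation,
            psychometric_slope_db=config.psychometric_slope_db,
            rng=rng,
        )
        values.append(
            staircase_4_2(
                observer,
                start_db=config.start_db,
                db_range=config.stimulus.db_range,
            )
        )
    return SensitivityMap(grid=grid, values=tuple(values))
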