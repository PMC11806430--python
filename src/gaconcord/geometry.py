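"""Coordinate conventions, T-grid construction, and photometric unit conversions.

The testing geometry follows the mesopic microperimetry protocol used in
geographic-atrophy trials: a T-shaped grid of evenly spaced loci anchored at
the anatomic fovea, with arms extending temporally, superiorly, and
inferiorly.  All retinal positions are fovea-centred degrees of visual angle;
positive ``x`` is temporal and positive ``y`` is superior, irrespective of
laterality (a laterality flag on the imaging side controls the mapping to
image columns).

Angular-to-linear conversion uses the Goldmann III equivalence of
0.43 degrees = 125 micrometres on the retina, so that every printed length in
the protocol (125 um stimulus, 250 um lesion-persistence rule) is internally
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UM_PER_DEGREE",
    "RetinalPosition",
    "GridLocus",
    "TestGrid",
    "StimulusSpec",
    "build_t_grid",
    "deg_to_um",
    "um_to_deg",
    "db_to_luminance",
    "luminance_to_db",
    "asb_to_cdm2",
]

#: Retinal micrometres per degree of visual angle, from the Goldmann III
#: stimulus equivalence (0.43 deg = 125 um).
UM_PER_DEGREE: float = 125.0 / 0.43

_ARMS = ("foveal", "temporal", "superior", "inferior")


@dataclass(frozen=True)
class RetinalPosition:
    """Fovea-centred retinal position in degrees (positive x temporal, y superior)."""

    x_deg: float
    y_deg: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_deg) and math.isfinite(self.y_deg)):
            raise ValueError("retinal position must be finite")


@dataclass(frozen=True)
class GridLocus:
    """A single test locus: position plus arm membership."""

    locus_id: int
    arm: str
    x_deg: float
    y_deg: float

    @property
    def position(self) -> RetinalPosition:
        return RetinalPosition(self.x_deg, self.y_deg)


@dataclass(frozen=True)
class TestGrid:
    """Ordered collection of test loci with uniform centre-to-centre spacing."""

    loci: tuple[GridLocus, ...]
    spacing_deg: float

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def arm(self, name: str) -> tuple[GridLocus, ...]:
        if name not in _ARMS:
            raise ValueError(f"unknown arm {name!r}; expected one of {_ARMS}")
        return tuple(l for l in self.loci if l.arm == name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in self.loci],
                "axis": [l.arm for l in self.loci],
                "x_deg": [l.x_deg for l in self.loci],
                "y_deg": [l.y_deg for l in self.loci],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class StimulusSpec:
    """Perimetric stimulus: Goldmann III white stimulus by default.

    ``max_luminance_cdm2`` is the 0-dB (brightest) luminance; sensitivities are
    expressed as decibels of attenuation relative to it.
    """

    diameter_deg: float = 0.43
    duration_ms: float = 200.0
    max_luminance_cdm2: float = 127.0
    db_range: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        if self.diameter_deg <= 0:
            raise ValueError("stimulus diameter must be positive")
        if self.max_luminance_cdm2 <= 0:
            raise ValueError("0-dB luminance must be positive")
        lo, hi = self.db_range
        if not lo < hi:
            raise ValueError("db_range must be increasing")


def _arm_count(extent_deg: float, spacing_deg: float, arm: str, tol: float = 1e-9) -> int:
    ratio = extent_deg / spacing_deg
    n = round(ratio)
    if n < 1 or abs(ratio - n) > tol:
        raise ValueError(
            f"{arm} extent {extent_deg} deg is not a positive multiple of "
            f"spacing {spacing_deg} deg"
        )
    return int(n)


def build_t_grid(
    temporal_deg: float = 15.0,
    superior_deg: float = 12.0,
    inferior_deg: float = 12.0,
    spacing_deg: float = 1.0,
) -> TestGrid:
    """Build the T-shaped test grid: a foveal locus plus three arms.

    With the default extents (15 deg temporal, 12 deg superior, 12 deg
    inferior, 1 deg spacing) this yields the protocol's 40 evenly spaced loci.
    Loci are ordered fovea first, then temporal, superior, inferior, each arm
    from the fovea outwards.
    """
    if spacing_deg <= 0:
        raise ValueError("spacing must be positive")
    n_t = _arm_count(temporal_deg, spacing_deg, "temporal")
    n_s = _arm_count(superior_deg, spacing_deg, "superior")
    n_i = _arm_count(inferior_deg, spacing_deg, "inferior")

    loci: list[GridLocus] = [GridLocus(0, "foveal", 0.0, 0.0)]
    k = 1
    for i in range(1, n_t + 1):
        loci.append(GridLocus(k, "temporal", i * spacing_deg, 0.0))
        k += 1
    for i in range(1, n_s + 1):
        loci.append(GridLocus(k, "superior", 0.0, i * spacing_deg))
        k += 1
    for i in range(1, n_i + 1):
        loci.append(GridLocus(k, "inferior", 0.0, -i * spacing_deg))
        k += 1
    return TestGrid(tuple(loci), spacing_deg)


def deg_to_um(angle_deg, um_per_degree: float = UM_PER_DEGREE):
    """Convert visual angle (degrees) to retinal distance (micrometres)."""
    return np.multiply(angle_deg, um_per_degree)


def um_to_deg(distance_um, um_per_degree: float = UM_PER_DEGREE):
    """Convert retinal distance (micrometres) to visual angle (degrees)."""
    return np.divide(distance_um, um_per_degree)


def db_to_luminance(attenuation_db, max_luminance_cdm2: float = 127.0):
    """Stimulus luminance (cd/m^2) after decimal-log attenuation in dB.

    0 dB is the brightest stimulus; each 10 dB attenuates by a factor of 10
    (20 dB of 127 cd/m^2 -> 1.27 cd/m^2).
    """
    attenuation_db = np.asarray(attenuation_db, dtype=float)
    if np.any(attenuation_db < 0):
        raise ValueError("attenuation must be non-negative dB")
    out = max_luminance_cdm2 * 10.0 ** (-attenuation_db / 10.0)
    return float(out) if out.ndim == 0 else out

def luminance_to_db(luminance_cdm2, max_luminance_cdm2: float = 127.0):
    """Inverse of :func:`db_to_luminance`."""
    luminance_cdm2 = np.asarray(luminance_cdm2, dtype=float)
    if np.any(luminance_cdm2 <= 0):
        raise ValueError("luminance must be positive")
    out = 10.0 * np.log10(max_luminance_cdm2 / luminance_cdm2)
    return float(out) if out.ndim == 0 else out


def asb_to_cdm2(luminance_asb):
    """Convert apostilbs to cd/m^2 (1 asb = 1/pi cd/m^2)."""
    luminance_asb = np.asarray(luminance_asb, dtype=float)
    if np.any(luminance_asb < 0):
        raise ValueError("luminance must be non-negative")
    out = luminance_asb / math.pi
    return float(out) if out.ndim == 0 else out
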