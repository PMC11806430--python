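"""Overlay of function onto structure and 1-D Dice concordance.

Microperimetry loci from one arm-line of the T-grid are projected onto the
matching OCT line scan (shared fovea-centred frame), absolute-scotoma zones
are built by nearest-neighbour interpolation between loci, FAF-defined
atrophy polygons are intersected with the scan line, and agreement between
scotoma and atrophy zones is quantified by the Dice similarity coefficient

    DSC = 2 TP / (2 TP + FP + FN)

over pixel counts on a shared raster: TP = pixels in both zones, FP = pixels
scotomatous without atrophy, FN = pixels atrophic without scotoma.  DSC is 1
for complete overlap, 0 for none, and undefined when both zones are empty (a
line with neither scotoma nor atrophy carries no concordance information and
is excluded from aggregation rather than scored 1).

Low-concordance lines (DSC below 0.5 by default) are classified by their
dominant error direction, mirroring the discordance taxonomy seen clinically:
scotoma without atrophy (function worse than structure) versus atrophy
without scotoma (structure worse than function).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .geometry import UM_PER_DEGREE, deg_to_um
from .intervals import IntervalSet
from .microperimetry import ABSOLUTE, SensitivityMap

__all__ = [
    "DiscordanceClass",
    "ConcordanceRecord",
    "loci_on_axis",
    "scotoma_intervals",
    "faf_intervals",
    "dice",
    "classify_discordance",
    "filter_single_scotoma_lines",
]

Axis = Literal["horizontal", "vertical"]


class DiscordanceClass(enum.Enum):
    CONCORDANT = "concordant"
    SCOTOMA_WITHOUT_ATROPHY = "scotoma_without_atrophy"
    ATROPHY_WITHOUT_SCOTOMA = "atrophy_without_scotoma"
    MIXED = "mixed"


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per line-scan concordance result between scotoma and atrophy zones."""

    tp_px: int
    fp_px: int
    fn_px: int
    dsc: float | None
    modality: str = ""
    axis: str = ""
    eye_id: str = ""
    visit_id: str = ""
    n_absolute_loci: int = 0

    def __post_init__(self) -> None:
        denom = 2 * self.tp_px + self.fp_px + self.fn_px
        if denom > 0:
            expected = 2 * self.tp_px / denom
            if self.dsc is None or abs(self.dsc - expected) > 1e-12:
                raise ValueError("dsc inconsistent with TP/FP/FN counts")
        elif self.dsc is not None:
            raise ValueError("dsc must be undefined (None) when all counts are zero")

    @property
    def defined(self) -> bool:
        return self.dsc is not None


def loci_on_axis(
    sensitivity_map: SensitivityMap, axis: Axis
) -> list[tuple[float, float]]:
    """Ordered (position_um, value) pairs of the loci lying on one scan axis.

    The horizontal scan carries the foveal locus plus the temporal arm
    (positive um = temporal); the vertical scan carries the foveal locus plus
    the superior (positive) and inferior (negative) arms.
    """
    grid = sensitivity_map.grid
    pairs = []
    for locus, value in zip(grid, sensitivity_map.values):
        if axis == "horizontal":
            if locus.arm in ("foveal", "temporal"):
                pairs.append((float(deg_to_um(locus.x_deg)), value))
        elif axis == "vertical":
            if locus.arm in ("foveal", "superior", "inferior"):
                pairs.append((float(deg_to_um(locus.y_deg)), value))
        else:
            raise ValueError(f"unknown axis {axis!r}")
    pairs.sort(key=lambda p: p[0])
    return pairs


def nearest_locus_index(positions_um: Sequence[float], x_um: float) -> int:
    """Index of the locus nearest to ``x_um`` (ties broken toward the lower position)."""
    positions = np.asarray(positions_um, dtype=float)
    d = np.abs(positions - x_um)
    return int(np.argmin(d))  # argmin returns the first (lower) index on ties


def _cell_edges(positions: np.ndarray, terminal_halfwidth_um: float | None) -> np.ndarray:
    """Nearest-neighbour cell edges: midpoints, plus half-spacing beyond the ends."""
    if len(positions) == 1:
        if terminal_halfwidth_um is None:
            raise ValueError("a single locus needs an explicit terminal half-width")
        h = terminal_halfwidth_um
        return np.array([positions[0] - h, positions[0] + h])
    mids = (positions[:-1] + positions[1:]) / 2.0
    first = positions[0] - (positions[1] - positions[0]) / 2.0
    last = positions[-1] + (positions[-1] - positions[-2]) / 2.0
    if terminal_halfwidth_um is not None:
        first = positions[0] - terminal_halfwidth_um
        last = positions[-1] + terminal_halfwidth_um
    return np.concatenate([[first], mids, [last]])


def scotoma_intervals(
    line_loci: Sequence[tuple[float, float]],
    terminal_halfwidth_um: float | None = None,
) -> IntervalSet:
    """Absolute-scotoma zones from loci on a line, by nearest-neighbour interpolation.

    Every axis point takes the status of its nearest locus, so each locus owns
    the half-open cell between the midpoints to its neighbours; terminal loci
    extend one half-spacing beyond their centre.  Cells of absolute loci
    (value -1) are merged into the returned interval set.
    """
    if not line_loci:
        raise ValueError("at least one locus is required")
    positions = np.array([p for p, _ in line_loci], dtype=float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("locus positions must be strictly increasing")
    values = np.array([v for _, v in line_loci], dtype=float)
    edges = _cell_edges(positions, terminal_halfwidth_um)
    cells = [
        (edges[i], edges[i + 1]) for i in range(len(positions)) if values[i] == ABSOLUTE
    ]
    return IntervalSet.from_pairs(cells) if cells else IntervalSet()


def tested_extent_um(
    line_loci: Sequence[tuple[float, float]],
    terminal_halfwidth_um: float | None = None,
) -> tuple[float, float]:
    """Lateral extent covered by the nearest-neighbour cells of the tested loci."""
    positions = np.array([p for p, _ in line_loci], dtype=float)
    edges = _cell_edges(positions, terminal_halfwidth_um)
    return float(edges[0]), float(edges[-1])


def faf_intervals(
    faf_polygons: Iterable[Polygon],
    axis: Axis,
    reach_deg: float = 60.0,
    min_length_um: float = 1.0,
) -> IntervalSet:
    """Crossings of FAF-defined atrophy polygons with a scan line through the fovea.

    Each polygon (degrees, fovea-centred frame) is intersected with the axis
    line, and the resulting chords are converted to um intervals and merged.
    Degenerate (tangent) crossings shorter than ``min_length_um`` are dropped.
    """
    if axis == "horizontal":
        line = LineString([(-reach_deg, 0.0), (reach_deg, 0.0)])
        coord = 0
    elif axis == "vertical":
        line = LineString([(0.0, -reach_deg), (0.0, reach_deg)])
        coord = 1
    else:
        raise ValueError(f"unknown axis {axis!r}")

    pairs = []
    for poly in faf_polygons:
        inter = poly.intersection(line)
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if g.geom_type != "LineString":
                continue  # point (tangent) crossings carry no length
            coords = np.asarray(g.coords)[:, coord]
            lo, hi = float(coords.min()), float(coords.max())
            if deg_to_um(hi - lo) >= min_length_um:
                pairs.append((deg_to_um(lo), deg_to_um(hi)))
    return IntervalSet.from_pairs(pairs) if pairs else IntervalSet()


def dice(
    scotoma: IntervalSet,
    atrophy: IntervalSet,
    raster_um_per_px: float,
    domain: tuple[float, float],
) -> tuple[int, int, int, float | None]:
    """Pixel-count Dice between two interval sets on a shared raster.

    Both sets are rasterised over ``domain`` at ``raster_um_per_px`` (a pixel
    belongs to a set iff its centre is covered); returns
    ``(tp, fp, fn, dsc)`` with ``dsc = 2 tp / (2 tp + fp + fn)``, or None when
    both sets are empty.  Intervals outside the domain raise.
    """
    a = scotoma.rasterize(domain, raster_um_per_px)
    b = atrophy.rasterize(domain, raster_um_per_px)
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    denom = 2 * tp + fp + fn
    dsc = 2 * tp / denom if denom > 0 else None
    return tp, fp, fn, dsc


def classify_discordance(
    record: ConcordanceRecord, low_threshold: float = 0.5
) -> DiscordanceClass:
    """Discordance taxonomy for one line: concordant above the DSC gate, else by error direction.

    FP-dominant lines (scotomatous pixels without atrophy) mean function worse
    than structure; FN-dominant lines the reverse.  Undefined DSC (both zones
    empty) maps to MIXED, carrying no directional information.
    """
    if record.dsc is None:
        return DiscordanceClass.MIXED
    if record.dsc >= low_threshold:
        return DiscordanceClass.CONCORDANT
    if record.fp_px > record.fn_px:
        return DiscordanceClass.SCOTOMA_WITHOUT_ATROPHY
    if record.fn_px > record.fp_px:
        return DiscordanceClass.ATROPHY_WITHOUT_SCOTOMA
    return DiscordanceClass.MIXED


def filter_single_scotoma_lines(
    records: Iterable[ConcordanceRecord],
) -> list[ConcordanceRecord]:
    """Sensitivity-analysis filter: drop lines with exactly one absolute-scotoma locus.

    A single absolute point yields a short scotoma zone whose DSC is
    necessarily low; lines with zero or two-plus absolute loci are retained.
    """
    return [r for r in records if r.n_absolute_loci != 1]
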