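"""Ordered disjoint half-open 1-D intervals along a scan line.

Interval sets represent zones along the lateral axis of an OCT line scan, in
signed micrometres from the fovea: absolute-scotoma zones from microperimetry,
choroidal-hypertransmission zones from reflectance profiling, and FAF-defined
atrophy crossings.  All intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["IntervalSet"]


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, pairwise-disjoint half-open intervals ``[start_um, end_um)``."""

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.intervals:
            if not (np.isfinite(start) and np.isfinite(end)):
                raise ValueError("interval bounds must be finite")
            if not start < end:
                raise ValueError(f"empty or inverted interval [{start}, {end})")
            if start < prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = end

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[float]], merge_gap: float = 0.0) -> "IntervalSet":
        """Build from possibly unsorted/overlapping pairs, merging gaps < ``merge_gap``.

        Touching intervals (gap == 0) are always merged so the invariant of
        strict disjointness holds.
        """
        pairs = sorted((float(a), float(b)) for a, b in pairs)
        merged: list[list[float]] = []
        for start, end in pairs:
            if not start < end:
                raise ValueError(f"empty or inverted interval [{start}, {end})")
            gap = start - merged[-1][1] if merged else np.inf
            if gap <= 0 or gap < merge_gap:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        return cls(tuple((a, b) for a, b in merged))

    @classmethod
    def from_mask(cls, mask: np.ndarray, edges_um: np.ndarray) -> "IntervalSet":
        """Build from a boolean pixel mask and the ``len(mask)+1`` pixel-edge positions."""
        mask = np.asarray(mask, dtype=bool)
        edges_um = np.asarray(edges_um, dtype=float)
        if edges_um.shape != (mask.size + 1,):
            raise ValueError("edges_um must have one more element than mask")
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        return cls(tuple((edges_um[i], edges_um[j]) for i, j in zip(starts, ends)))

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    @property
    def lengths(self) -> np.ndarray:
        return np.array([end - start for start, end in self.intervals])

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum()) if self.intervals else 0.0

    @property
    def bounds(self) -> tuple[float, float] | None:
        if not self.intervals:
            return None
        return self.intervals[0][0], self.intervals[-1][1]

    def _edges(self) -> np.ndarray:
        return np.array([e for iv in self.intervals for e in iv])

    def contains(self, x) -> np.ndarray:
        """Vectorised membership test (half-open convention)."""
        x = np.asarray(x, dtype=float)
        if not self.intervals:
            return np.zeros(x.shape, dtype=bool)
        idx = np.searchsorted(self._edges(), x, side="right")
        return (idx % 2) == 1

    # -- transforms --------------------------------------------------------

    def clip(self, lo_um: float, hi_um: float) -> "IntervalSet":
        """Intersect with ``[lo_um, hi_um)``."""
        if not lo_um < hi_um:
            raise ValueError("clip window must be increasing")
        out = []
        for start, end in self.intervals:
            s, e = max(start, lo_um), min(end, hi_um)
            if s < e:
                out.append((s, e))
        return IntervalSet(tuple(out))

    def filter_min_length(self, min_length_um: float) -> "IntervalSet":
        """Keep intervals with length >= ``min_length_um``."""
        return IntervalSet(
            tuple(iv for iv in self.intervals if iv[1] - iv[0] >= min_length_um)
        )

    def rasterize(self, domain: tuple[float, float], resolution_um: float) -> np.ndarray:
        """Boolean pixel mask over ``domain``: a pixel is set iff its centre is covered."""
        lo, hi = domain
        if resolution_um <= 0:
            raise ValueError("raster resolution must be positive")
        if not lo < hi:
            raise ValueError("domain must be increasing")
        b = self.bounds
        if b is not None and (b[0] < lo - 1e-9 or b[1] > hi + 1e-9):
            raise ValueError(
                f"intervals [{b[0]}, {b[1]}) extend outside domain [{lo}, {hi})"
            )
        n = int(round((hi - lo) / resolution_um))
        centers = lo + (np.arange(n) + 0.5) * resolution_um
        return self.contains(centers)

    def overlap_length(self, other: "IntervalSet") -> float:
        """Exact total length of the pairwise intersection (interval arithmetic)."""
        total = 0.0
        for a0, a1 in self.intervals:
            for b0, b1 in other.intervals:
                total += max(0.0, min(a1, b1) - max(a0, b0))
        return total
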