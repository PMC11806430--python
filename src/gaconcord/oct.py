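"""Choroidal-slab reflectance profiling and hypertransmission segmentation.

Workflow, per OCT line scan:

1. obtain the per-column Bruch's-membrane (BM) row — ground truth passthrough
   on phantoms, or a simple intensity-drop heuristic as a fallback;
2. extract the choroidal slab, 64-200 um beneath BM (the 64 um anterior
   offset keeps large hyporeflective choroidal vessels out of the slab);
3. average the slab per A-scan into a lateral reflectance profile
   (0-255 grayscale and 0-1 normalised);
4. threshold the profile into hypertransmission zones, merge near-adjacent
   runs, and discard zones shorter than 250 um — short hypertransmission
   defects are not accepted as complete RPE and outer retinal atrophy (cRORA).

The printed workflow ends with a human grader segmenting lesion limits from
the profile; here the thresholding is automated (fixed cutoff or Otsu) so the
pipeline is testable end to end, with threshold, minimum length, and gap
handling all exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_otsu

from .intervals import IntervalSet
from .phantom import LineScan

__all__ = [
    "SlabSpec",
    "ReflectanceProfile",
    "segment_bm",
    "reflectance_profile",
    "segment_hypertransmission",
]


@dataclass(frozen=True)
class SlabSpec:
    """Choroidal slab beneath Bruch's membrane: [offset_um, depth_um) of depth."""

    offset_um: float = 64.0
    depth_um: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.offset_um < self.depth_um:
            raise ValueError("slab requires 0 < offset_um < depth_um")


@dataclass(frozen=True)
class ReflectanceProfile:
    """Per-A-scan mean choroidal-slab intensity along a line scan.

    ``positions_um`` are signed lateral positions from the fovea;
    ``mean_raw`` is the 0-255 grayscale mean, ``mean_norm`` its 0-1
    normalisation (divide by 255; no per-scan contrast stretching, so values
    stay comparable across scans).  ``truncated`` flags columns whose slab ran
    past the image bottom (mean over the available rows only).
    """

    positions_um: np.ndarray
    mean_raw: np.ndarray
    truncated: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions_um)
        if len(self.mean_raw) != n or len(self.truncated) != n:
            raise ValueError("profile arrays must have equal length")
        if n and np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def mean_norm(self) -> np.ndarray:
        return self.mean_raw / 255.0

    @property
    def lateral_um_per_px(self) -> float:
        return float(np.median(np.diff(self.positions_um)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position_um": self.positions_um,
                "mean_raw": self.mean_raw,
                "mean_norm": self.mean_norm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def segment_bm(
    scan: LineScan,
    mode: Literal["truth", "fallback"] = "truth",
    smooth_sigma_px: float = 2.0,
    search_um: float = 60.0,
    min_drop: float = 5.0,
) -> np.ndarray:
    """Per-column Bruch's-membrane rows (sub-pixel floats).

    ``truth`` returns the rendering ground truth carried by the scan (the
    contract a dedicated segmentation model would fulfil on real data).
    ``fallback`` is a documented heuristic: per column, smooth the A-scan,
    locate the brightest band, and take the row with the steepest downward
    intensity step within ``search_um`` below it (the RPE/choroid boundary).
    Columns with no convincing drop (e.g. hypertransmission, where the choroid
    stays bright) are flagged and linearly interpolated from their neighbours.
    """
    if mode == "truth":
        return scan.bm_rows.copy()
    if mode != "fallback":
        raise ValueError(f"unknown mode {mode!r}")

    img = scan.image.astype(float)
    n_rows, n_cols = img.shape
    window = max(3, int(round(search_um / scan.axial_scale_um_per_px)))
    half = 3  # rows averaged on each side of a candidate boundary

    smoothed = gaussian_filter1d(img, smooth_sigma_px, axis=0)
    est = np.full(n_cols, np.nan)
    for c in range(n_cols):
        col = smoothed[:, c]
        r0 = int(np.argmax(col))
        lo = r0
        hi = min(n_rows - half, r0 + window)
        if hi <= lo:
            continue
        rows = np.arange(lo, hi)
        above = np.array([col[max(0, r - half) : r].mean() if r > 0 else col[r] for r in rows])
        below = np.array([col[r : r + half].mean() for r in rows])
        drops = above - below
        best = int(np.argmax(drops))
        if drops[best] >= min_drop:
            est[c] = rows[best]

    missing = np.isnan(est)
    if missing.all():
        raise ValueError("fallback BM segmentation found no candidate rows")
    if missing.any():
        cols = np.arange(n_cols)
        est[missing] = np.interp(cols[missing], cols[~missing], est[~missing])
    return est


def reflectance_profile(
    scan: LineScan,
    bm_rows: np.ndarray | None = None,
    slab: SlabSpec = SlabSpec(),
) -> ReflectanceProfile:
    """Mean choroidal-slab intensity per A-scan.

    For each column the slab spans rows ``[round(bm + offset/ax),
    round(bm + depth/ax))`` (nearest-integer bounds of the sub-pixel float
    depths, half-open).  Columns whose slab extends past the image bottom are
    averaged over the available rows and flagged.
    """
    if bm_rows is None:
        bm_rows = scan.bm_rows
    bm_rows = np.asarray(bm_rows, dtype=float)
    img = scan.image
    n_rows, n_cols = img.shape
    if bm_rows.shape != (n_cols,):
        raise ValueError("bm_rows must have one entry per column")

    ax = scan.axial_scale_um_per_px
    top = np.rint(bm_rows + slab.offset_um / ax).astype(int)
    bot = np.rint(bm_rows + slab.depth_um / ax).astype(int)
    if np.any(bot - top < 1):
        raise ValueError("slab thinner than one pixel at the axial scale")
    if np.any(top < 0) or np.any(top >= n_rows):
        raise ValueError("slab top outside the image")

    truncated = bot > n_rows
    if truncated.any():
        warnings.warn(
            f"choroidal slab truncated at image bottom in {int(truncated.sum())} columns",
            stacklevel=2,
        )
    bot = np.minimum(bot, n_rows)

    csum = np.vstack([np.zeros(n_cols), np.cumsum(img, axis=0)])
    cols = np.arange(n_cols)
    sums = csum[bot, cols] - csum[top, cols]
    means = sums / (bot - top)

    return ReflectanceProfile(
        positions_um=scan.column_positions_um(),
        mean_raw=means,
        truncated=truncated,
    )


def segment_hypertransmission(
    profile: ReflectanceProfile,
    threshold_norm: float | None = None,
    min_length_um: float = 250.0,
    merge_gap_um: float = 50.0,
    min_otsu_separation: float = 20.0 / 255.0,
) -> IntervalSet:
    """Hypertransmission zones: supra-threshold profile runs >= ``min_length_um``.

    Columns with ``mean_norm >= threshold_norm`` form runs; runs separated by
    gaps shorter than ``merge_gap_um`` are merged (bridging vessel shadows and
    speckle dropouts); runs shorter than ``min_length_um`` (default 250 um,
    the cRORA persistence rule) are discarded.  Intervals are half-open in um,
    spanning the outer pixel edges of each run.

    When ``threshold_norm`` is None the cutoff is chosen by Otsu's method on
    the profile — parameter-free on bimodal profiles — guarded by a minimum
    separation between the two Otsu classes: if the class means differ by less
    than ``min_otsu_separation`` the profile is treated as unimodal (no
    hypertransmission) rather than letting Otsu bisect noise.
    """
    norm = profile.mean_norm
    if threshold_norm is None:
        if norm.size == 0 or np.allclose(norm, norm[0]):
            return IntervalSet()
        thr = float(threshold_otsu(norm))
        lo_mean = norm[norm < thr].mean() if np.any(norm < thr) else thr
        hi_mean = norm[norm >= thr].mean() if np.any(norm >= thr) else thr
        if hi_mean - lo_mean < min_otsu_separation:
            return IntervalSet()
    else:
        if not 0.0 < threshold_norm < 1.0:
            raise ValueError("threshold_norm must lie in (0, 1)")
        thr = threshold_norm

    mask = norm >= thr
    if not mask.any():
        return IntervalSet()

    res = profile.lateral_um_per_px
    edges = np.concatenate(
        [profile.positions_um - res / 2.0, [profile.positions_um[-1] + res / 2.0]]
    )
    runs = IntervalSet.from_mask(mask, edges)
    merged = IntervalSet.from_pairs(runs.intervals, merge_gap=merge_gap_um)
    return merged.filter_min_length(min_length_um)
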