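"""Synthetic-eye phantoms with known ground truth.

A phantom bundles everything the analysis pipeline consumes, with the truth
known by construction:

* ``oct_atrophy`` — polygons (degrees) where choroidal hypertransmission is
  ground truth, i.e. where RPE loss lets the OCT beam through to the choroid;
* ``faf_atrophy`` — polygons where FAF-defined geographic atrophy is truth
  (the OCT polygons, optionally dilated or eroded, emulating modality
  disagreement);
* ``functional_atrophy`` — polygons driving the retinal-sensitivity field
  (normally the OCT polygons, but deliberately decouplable to manufacture the
  discordance scenarios seen clinically: scotoma without hypertransmission and
  vice versa);
* a sensitivity field (dB; -1 codes "no response at 0 dB") with a sigmoidal
  transition at lesion borders;
* Bruch's-membrane geometry and an OCT rendering model with multiplicative
  speckle.

Scenario presets reproduce qualitatively distinct structure-function
relationships: concordant atrophy, a test line running between two lesions,
isolated outer retinal atrophy (reticular-pseudodrusen-like, no RPE loss),
a line clipping the edge of a lesion, partial photoreceptor degeneration over
intact hypertransmission, and FAF contours offset from OCT truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import shapely
from scipy.special import expit
from shapely.geometry import Point, Polygon

from .geometry import UM_PER_DEGREE, deg_to_um

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "Phantom",
    "LineScan",
    "RenderConfig",
    "make_phantom",
    "render_line_scan",
    "scenario_preset",
    "SCENARIO_NAMES",
]

Axis = Literal["horizontal", "vertical"]


@dataclass(frozen=True)
class LesionSpec:
    """An atrophic lesion: a circle (centre/radius) or an explicit polygon, in degrees."""

    center_deg: tuple[float, float] | None = None
    radius_deg: float | None = None
    polygon_deg: tuple[tuple[float, float], ...] | None = None

    def to_polygon(self) -> Polygon:
        if self.polygon_deg is not None:
            poly = Polygon(self.polygon_deg)
        elif self.center_deg is not None and self.radius_deg is not None:
            if self.radius_deg <= 0:
                raise ValueError("lesion radius must be positive")
            poly = Point(*self.center_deg).buffer(self.radius_deg, quad_segs=64)
        else:
            raise ValueError("lesion needs either polygon_deg or center_deg+radius_deg")
        if not poly.is_valid or poly.is_empty:
            raise ValueError("lesion polygon is invalid (self-intersecting or empty)")
        return poly

    def grown(self, delta_deg: float) -> "LesionSpec":
        """Radially grown copy (circles grow the radius; polygons are buffered)."""
        if self.radius_deg is not None:
            return dataclasses.replace(self, radius_deg=self.radius_deg + delta_deg)
        poly = self.to_polygon().buffer(delta_deg, quad_segs=64)
        return LesionSpec(polygon_deg=tuple(poly.exterior.coords))

    def shifted(self, dx_deg: float, dy_deg: float) -> "LesionSpec":
        if self.center_deg is not None:
            cx, cy = self.center_deg
            return dataclasses.replace(self, center_deg=(cx + dx_deg, cy + dy_deg))
        return LesionSpec(
            polygon_deg=tuple((x + dx_deg, y + dy_deg) for x, y in self.polygon_deg)
        )


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth parameters of a synthetic eye.

    ``base_sensitivity_db`` is the retinal sensitivity outside atrophy (14 dB,
    a typical perilesional mesopic value in eyes with geographic atrophy);
    ``scotoma_floor_db`` the value deep inside functional atrophy (-1 = no
    response at the brightest stimulus).  ``transition_width_deg`` controls the
    sigmoidal border of the sensitivity field (0 = step).  ``faf_offset_deg``
    dilates (>0) or erodes (<0) the FAF contours relative to OCT truth.
    ``functional_lesions`` overrides the lesions driving the sensitivity field;
    by default the OCT lesions do.
    """

    lesions: tuple[LesionSpec, ...] = ()
    base_sensitivity_db: float = 14.0
    scotoma_floor_db: float = -1.0
    transition_width_deg: float = 0.0
    faf_offset_deg: float = 0.0
    functional_lesions: tuple[LesionSpec, ...] | None = None
    bm_profile: Literal["flat", "parabola"] = "parabola"
    bm_center_depth_um: float = 1150.0
    bm_sag_um: float = 150.0
    laterality: Literal["OD", "OS"] = "OD"

    def __post_init__(self) -> None:
        if not -1.0 <= self.scotoma_floor_db <= 20.0:
            raise ValueError("scotoma_floor_db must lie in [-1, 20]")
        if not -1.0 <= self.base_sensitivity_db <= 20.0:
            raise ValueError("base_sensitivity_db must lie in [-1, 20]")
        if self.transition_width_deg < 0:
            raise ValueError("transition width must be non-negative")


def _union(polys: Sequence[Polygon]):
    return shapely.union_all(list(polys)) if polys else None


@dataclass(frozen=True)
class Phantom:
    """A synthetic eye with known structural and functional ground truth."""

    config: PhantomConfig
    seed: int
    oct_atrophy: tuple[Polygon, ...]
    faf_atrophy: tuple[Polygon, ...]
    functional_atrophy: tuple[Polygon, ...]

    def sensitivity(self, x_deg, y_deg) -> np.ndarray:
        """Retinal sensitivity field (dB in [-1, 20]) at fovea-centred positions.

        Equal to ``base_sensitivity_db`` outside functional atrophy and
        ``scotoma_floor_db`` deep inside, with a logistic transition of the
        configured width across the lesion border (signed boundary distance).
        """
        scalar = np.isscalar(x_deg) and np.isscalar(y_deg)
        x = np.atleast_1d(np.asarray(x_deg, dtype=float))
        y = np.atleast_1d(np.asarray(y_deg, dtype=float))
        x, y = np.broadcast_arrays(x, y)
        cfg = self.config
        base, floor = cfg.base_sensitivity_db, cfg.scotoma_floor_db
        geom = _union(self.functional_atrophy)
        if geom is None or geom.is_empty:
            out = np.full(x.shape, base)
        else:
            pts = shapely.points(np.column_stack([x.ravel(), y.ravel()]))
            inside = shapely.contains(geom, pts)
            d = shapely.distance(shapely.boundary(geom), pts)
            signed = np.where(inside, -d, d)  # positive outside the lesion
            w = cfg.transition_width_deg
            if w == 0:
                vals = np.where(signed > 0, base, floor)
            else:
                vals = floor + (base - floor) * expit(signed / w)
            out = vals.reshape(x.shape)
        out = np.clip(out, -1.0, 20.0)
        return float(out[0]) if scalar else out

    def bm_depth_um(self, x_deg) -> np.ndarray:
        """Bruch's-membrane depth below the scan top (um) vs lateral position.

        A shallow parabola, deepest at the fovea (foveal pit geometry), or flat.
        """
        x = np.asarray(x_deg, dtype=float)
        cfg = self.config
        if cfg.bm_profile == "flat":
            return np.full(x.shape, cfg.bm_center_depth_um)
        # parabola: depth decreases quadratically away from the fovea,
        # dropping by bm_sag_um at 15 deg eccentricity
        return cfg.bm_center_depth_um - cfg.bm_sag_um * (x / 15.0) ** 2


def make_phantom(config: PhantomConfig, seed: int) -> Phantom:
    """Materialise a phantom from its configuration (deterministic given both)."""
    oct_polys = tuple(l.to_polygon() for l in config.lesions)
    func_specs = (
        config.functional_lesions if config.functional_lesions is not None else config.lesions
    )
    func_polys = tuple(l.to_polygon() for l in func_specs)
    if config.faf_offset_deg == 0:
        faf_polys = oct_polys
    else:
        faf_polys = tuple(
            p.buffer(config.faf_offset_deg, quad_segs=64) for p in oct_polys
        )
        faf_polys = tuple(p for p in faf_polys if not p.is_empty)
    return Phantom(
        config=config,
        seed=int(seed),
        oct_atrophy=oct_polys,
        faf_atrophy=faf_polys,
        functional_atrophy=func_polys,
    )


# ---------------------------------------------------------------------------
# OCT rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderConfig:
    """Layered-intensity OCT rendering model.

    Geometry mirrors a 30-degree spectral-domain line scan (768 columns x 496
    rows).  Intensities are 8-bit grayscale means: the choroid renders at
    ``choroid_outside`` beneath intact RPE and ``choroid_inside``
    (hypertransmission) where the scan crosses OCT atrophy; the RPE band is
    attenuated over atrophy.  Speckle is multiplicative unit-mean gamma noise
    with shape ``speckle_shape`` (or Gaussian, or none).
    """

    width_px: int = 768
    height_px: int = 496
    field_deg: float = 30.0
    axial_um_per_px: float = 3.87
    fovea_col: int | None = None
    choroid_inside: float = 160.0
    choroid_outside: float = 80.0
    retina_intensity: float = 110.0
    rpe_intensity: float = 230.0
    rpe_attenuated: float = 90.0
    vitreous_intensity: float = 25.0
    retina_thickness_um: float = 200.0
    rpe_thickness_um: float = 20.0
    noise: Literal["gamma", "gaussian", "none"] = "gamma"
    speckle_shape: float = 4.0
    gaussian_sigma: float = 10.0

    @property
    def lateral_um_per_px(self) -> float:
        return self.field_deg * UM_PER_DEGREE / self.width_px

    @property
    def fovea_col_(self) -> int:
        return self.width_px // 2 if self.fovea_col is None else self.fovea_col


@dataclass(frozen=True)
class LineScan:
    """A rendered (or loaded) OCT line scan with its geometry sidecar.

    ``image`` rows are depth, columns lateral; values lie in [0, 255].
    ``bm_rows`` is the per-column Bruch's-membrane row (sub-pixel float).
    For a horizontal scan, increasing column means increasing temporal
    eccentricity; for a vertical scan, increasing superior eccentricity.
    """

    image: np.ndarray
    lateral_scale_um_per_px: float
    axial_scale_um_per_px: float
    axis: Axis
    fovea_col: int
    bm_rows: np.ndarray

    def __post_init__(self) -> None:
        img = self.image
        if img.ndim != 2:
            raise ValueError("line-scan image must be 2-D")
        if self.bm_rows.shape != (img.shape[1],):
            raise ValueError("bm_rows must have one entry per column")
        if np.any(self.bm_rows < 0) or np.any(self.bm_rows >= img.shape[0]):
            raise ValueError("bm_rows must lie within the image depth")
        if not 0 <= self.fovea_col < img.shape[1]:
            raise ValueError("fovea_col outside image width")
        if img.size and (img.min() < 0 or img.max() > 255):
            raise ValueError("image values must lie in [0, 255]")

    @property
    def n_cols(self) -> int:
        return self.image.shape[1]

    def column_positions_um(self) -> np.ndarray:
        """Signed lateral position of each column (um from the fovea)."""
        cols = np.arange(self.n_cols)
        return (cols - self.fovea_col) * self.lateral_scale_um_per_px

    def column_positions_deg(self) -> np.ndarray:
        return self.column_positions_um() / UM_PER_DEGREE


def _axis_points(x_deg: np.ndarray, axis: Axis) -> np.ndarray:
    """Fovea-centred (x, y) coordinates of points along a scan axis."""
    if axis == "horizontal":
        return np.column_stack([x_deg, np.zeros_like(x_deg)])
    if axis == "vertical":
        return np.column_stack([np.zeros_like(x_deg), x_deg])
    raise ValueError(f"unknown axis {axis!r}")


def render_line_scan(
    phantom: Phantom,
    axis: Axis = "horizontal",
    config: RenderConfig = RenderConfig(),
    seed: int | None = None,
) -> LineScan:
    """Render an OCT line scan through the fovea along ``axis``.

    The speckle realisation is drawn from ``seed`` (default: derived from the
    phantom seed and axis), so the same phantom yields reproducible but
    axis-distinct noise.
    """
    cfg = config
    n_cols, n_rows = cfg.width_px, cfg.height_px
    fovea_col = cfg.fovea_col_
    positions_deg = (np.arange(n_cols) - fovea_col) * cfg.field_deg / n_cols

    bm_um = phantom.bm_depth_um(positions_deg)
    bm_rows = bm_um / cfg.axial_um_per_px
    if np.any(bm_rows >= n_rows) or np.any(bm_rows < 0):
        raise ValueError("Bruch's membrane falls outside the image depth")

    pts = _axis_points(positions_deg, axis)
    geom = _union(phantom.oct_atrophy)
    if geom is None or geom.is_empty:
        atrophic = np.zeros(n_cols, dtype=bool)
    else:
        atrophic = shapely.contains(geom, shapely.points(pts))

    rows = np.arange(n_rows, dtype=float)[:, None]  # (rows, 1)
    bm = bm_rows[None, :]  # (1, cols)
    retina_top = bm - cfg.retina_thickness_um / cfg.axial_um_per_px
    rpe_top = bm - cfg.rpe_thickness_um / cfg.axial_um_per_px

    rpe_level = np.where(atrophic, cfg.rpe_attenuated, cfg.rpe_intensity)[None, :]
    choroid_level = np.where(atrophic, cfg.choroid_inside, cfg.choroid_outside)[None, :]

    img = np.full((n_rows, n_cols), cfg.vitreous_intensity)
    img = np.where((rows >= retina_top) & (rows < rpe_top), cfg.retina_intensity, img)
    img = np.where((rows >= rpe_top) & (rows < bm), rpe_level, img)
    img = np.where(rows >= bm, choroid_level, img)

    if cfg.noise != "none":
        if seed is None:
            seed = _render_seed(phantom.seed, axis)
        rng = np.random.default_rng(seed)
        if cfg.noise == "gamma":
            k = cfg.speckle_shape
            img = img * rng.gamma(k, 1.0 / k, size=img.shape)
        elif cfg.noise == "gaussian":
            img = img + rng.normal(0.0, cfg.gaussian_sigma, size=img.shape)
        else:
            raise ValueError(f"unknown noise model {cfg.noise!r}")
        img = np.clip(img, 0.0, 255.0)

    return LineScan(
        image=img,
        lateral_scale_um_per_px=cfg.lateral_um_per_px,
        axial_scale_um_per_px=cfg.axial_um_per_px,
        axis=axis,
        fovea_col=fovea_col,
        bm_rows=bm_rows,
    )


def _render_seed(phantom_seed: int, axis: Axis) -> int:
    ss = np.random.SeedSequence([int(phantom_seed), 0 if axis == "horizontal" else 1])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

SCENARIO_NAMES = (
    "concordant",
    "between_lesions",
    "outer_retinal_atrophy",
    "edge_of_lesion",
    "partial_pr_degeneration",
    "faf_offset",
)


def scenario_preset(name: str) -> PhantomConfig:
    """Phantom configuration reproducing a named structure-function scenario.

    Each preset has a known discordance direction on the tested lines:

    * ``concordant`` — one lesion crossing both test lines; scotoma,
      hypertransmission, and FAF atrophy coincide.
    * ``between_lesions`` — two lesions flank the horizontal line without
      touching it, yet the intervening tissue is non-functional: absolute
      scotoma without hypertransmission.
    * ``outer_retinal_atrophy`` — photoreceptor loss without RPE loss
      (reticular-pseudodrusen-like): absolute scotoma, no hypertransmission,
      no FAF atrophy.
    * ``edge_of_lesion`` — the line clips a lesion edge; part of each stimulus
      footprint lands on surviving retina, so hypertransmission is present
      without an absolute scotoma.
    * ``partial_pr_degeneration`` — hypertransmission with only partial
      photoreceptor degeneration (relative scotoma): structure worse than
      function.
    * ``faf_offset`` — concordant geometry but FAF contours dilated relative
      to OCT truth, degrading FAF concordance only.
    """
    if name == "concordant":
        return PhantomConfig(
            lesions=(LesionSpec(center_deg=(1.5, 1.5), radius_deg=2.5),),
        )
    if name == "between_lesions":
        return PhantomConfig(
            lesions=(
                LesionSpec(center_deg=(4.0, 1.45), radius_deg=1.2),
                LesionSpec(center_deg=(4.0, -1.45), radius_deg=1.2),
            ),
            functional_lesions=(LesionSpec(center_deg=(4.0, 0.0), radius_deg=1.6),),
        )
    if name == "outer_retinal_atrophy":
        return PhantomConfig(
            lesions=(),
            functional_lesions=(LesionSpec(center_deg=(8.0, 0.0), radius_deg=2.0),),
        )
    if name == "edge_of_lesion":
        return PhantomConfig(
            lesions=(LesionSpec(center_deg=(5.0, 2.35), radius_deg=2.5),),
        )
    if name == "partial_pr_degeneration":
        return PhantomConfig(
            lesions=(LesionSpec(center_deg=(3.0, 0.0), radius_deg=2.0),),
            scotoma_floor_db=4.0,
        )
    if name == "faf_offset":
        return PhantomConfig(
            lesions=(LesionSpec(center_deg=(1.5, 1.5), radius_deg=2.5),),
            faf_offset_deg=0.6,
        )
    raise ValueError(
        f"unknown scenario {name!r}; valid presets: {', '.join(SCENARIO_NAMES)}"
    )
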