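"""End-to-end orchestration: phantom cohort -> imaging -> perimetry -> concordance -> statistics.

``run_pipeline`` simulates a longitudinal cohort of synthetic eyes from a
scenario preset (or explicit phantom configuration), renders horizontal and
vertical OCT line scans, simulates the microperimetry examination, profiles
the choroidal slab, builds scotoma / hypertransmission / FAF interval sets,
computes per-line Dice records for both structural modalities, and fits the
repeated-measures models.  Everything is deterministic given the run seed.

Concordance is evaluated over the *tested extent* of each line — the
nearest-neighbour cells of the perimetry loci (half a spacing beyond the
terminal loci) — because function is only measured there; structural
intervals are clipped to that window before rasterisation.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    ConcordanceRecord,
    classify_discordance,
    dice,
    faf_intervals,
    loci_on_axis,
    scotoma_intervals,
    tested_extent_um,
)
from .geometry import TestGrid, build_t_grid, deg_to_um
from .microperimetry import ABSOLUTE, ExamConfig, classify_locus, simulate_exam
from .oct import SlabSpec, reflectance_profile, segment_bm, segment_hypertransmission
from .phantom import (
    Phantom,
    PhantomConfig,
    RenderConfig,
    make_phantom,
    render_line_scan,
    scenario_preset,
)
from .stats import (
    ModelFit,
    compare_modalities,
    fit_grouped_repeated,
    locus_reflectivity,
)

__all__ = [
    "GridConfig",
    "OctConfig",
    "ConcordanceConfig",
    "JitterConfig",
    "RunConfig",
    "RunSummary",
    "analyze_phantom",
    "run_pipeline",
]


@dataclass(frozen=True)
class GridConfig:
    temporal_deg: float = 15.0
    superior_deg: float = 12.0
    inferior_deg: float = 12.0
    spacing_deg: float = 1.0

    def build(self) -> TestGrid:
        return build_t_grid(
            self.temporal_deg, self.superior_deg, self.inferior_deg, self.spacing_deg
        )


@dataclass(frozen=True)
class OctConfig:
    slab: SlabSpec = SlabSpec()
    bm_mode: str = "truth"
    threshold_norm: float | None = None  # None -> Otsu
    min_length_um: float = 250.0
    merge_gap_um: float = 50.0


@dataclass(frozen=True)
class ConcordanceConfig:
    raster_um_per_px: float | None = None  # None -> scan lateral pixel size
    low_dsc_threshold: float = 0.5
    exclude_lines_without_scotoma: bool = False


@dataclass(frozen=True)
class JitterConfig:
    """Optional per-eye geometry variation and per-visit lesion growth (degrees)."""

    center_sd_deg: float = 0.0
    radius_sd_deg: float = 0.0
    growth_per_visit_deg: float = 0.0

    @property
    def active(self) -> bool:
        return any(
            v > 0
            for v in (self.center_sd_deg, self.radius_sd_deg, self.growth_per_visit_deg)
        )


@dataclass(frozen=True)
class RunConfig:
    seed: int
    scenario: str | PhantomConfig = "concordant"
    n_eyes: int = 2
    n_visits: int = 2
    grid: GridConfig = GridConfig()
    render: RenderConfig = RenderConfig()
    exam: ExamConfig = ExamConfig()
    oct: OctConfig = OctConfig()
    concordance: ConcordanceConfig = ConcordanceConfig()
    jitter: JitterConfig = JitterConfig()
    stats_covariance: str = "auto"
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.n_eyes < 1 or self.n_visits < 1:
            raise ValueError("n_eyes and n_visits must be >= 1")

    def phantom_config(self) -> PhantomConfig:
        if isinstance(self.scenario, PhantomConfig):
            return self.scenario
        return scenario_preset(self.scenario)


@dataclass
class RunSummary:
    """Complete result of one pipeline run."""

    records: pd.DataFrame
    loci: pd.DataFrame
    modality_fit: ModelFit | None
    reflectivity_fit: ModelFit | None
    provenance: dict
    stage_log: list[dict] = field(default_factory=list)

    def mean_dsc(self, modality: str) -> float:
        sel = self.records[
            (self.records["modality"] == modality) & self.records["dsc"].notna()
        ]
        return float(sel["dsc"].mean())


def _jittered_config(
    base: PhantomConfig, jitter: JitterConfig, rng: np.random.Generator, visit: int
) -> PhantomConfig:
    lesions = base.lesions
    functional = base.functional_lesions
    if jitter.active:
        def perturb(specs, dx, dy, dr):
            out = []
            for spec, ddx, ddy, ddr in zip(specs, dx, dy, dr):
                s = spec.shifted(ddx, ddy)
                if ddr != 0:
                    s = s.grown(ddr)
                out.append(s)
            return tuple(out)

        n = len(lesions) + (len(functional) if functional else 0)
        dx = rng.normal(0.0, jitter.center_sd_deg, n) if jitter.center_sd_deg else np.zeros(n)
        dy = rng.normal(0.0, jitter.center_sd_deg, n) if jitter.center_sd_deg else np.zeros(n)
        dr = rng.normal(0.0, jitter.radius_sd_deg, n) if jitter.radius_sd_deg else np.zeros(n)
        dr = dr + jitter.growth_per_visit_deg * visit
        k = len(lesions)
        lesions = perturb(lesions, dx[:k], dy[:k], dr[:k])
        if functional:
            functional = perturb(functional, dx[k:], dy[k:], dr[k:])
    elif visit and jitter.growth_per_visit_deg:
        g = jitter.growth_per_visit_deg * visit
        lesions = tuple(l.grown(g) for l in lesions)
        if functional:
            functional = tuple(l.grown(g) for l in functional)
    return dataclasses.replace(base, lesions=lesions, functional_lesions=functional)


def analyze_phantom(
    phantom: Phantom,
    grid: TestGrid,
    render: RenderConfig = RenderConfig(),
    exam: ExamConfig = ExamConfig(),
    oct: OctConfig = OctConfig(),
    concordance: ConcordanceConfig = ConcordanceConfig(),
    eye_id: str = "eye00",
    visit_id: int = 0,
) -> tuple[list[dict], list[dict]]:
    """Full structure-function analysis of one phantom at one visit.

    Returns per-line concordance records (one per axis and modality) and
    per-locus observations (reflectivity + scotoma class) as row dicts.
    """
    smap = simulate_exam(phantom, grid, exam)
    half_spacing_um = float(deg_to_um(grid.spacing_deg)) / 2.0

    records: list[dict] = []
    loci_rows: list[dict] = []
    for axis in ("horizontal", "vertical"):
        scan = render_line_scan(phantom, axis, render)
        bm = segment_bm(scan, mode=oct.bm_mode)
        profile = reflectance_profile(scan, bm, oct.slab)
        hyper = segment_hypertransmission(
            profile,
            threshold_norm=oct.threshold_norm,
            min_length_um=oct.min_length_um,
            merge_gap_um=oct.merge_gap_um,
        )

        line_loci = loci_on_axis(smap, axis)
        scot = scotoma_intervals(line_loci, terminal_halfwidth_um=half_spacing_um)
        n_abs = sum(1 for _, v in line_loci if v == ABSOLUTE)
        faf = faf_intervals(phantom.faf_atrophy, axis)

        domain = tested_extent_um(line_loci, terminal_halfwidth_um=half_spacing_um)
        raster = concordance.raster_um_per_px or scan.lateral_scale_um_per_px

        if concordance.exclude_lines_without_scotoma and n_abs == 0:
            continue

        for modality, atrophy in (("OCT", hyper), ("FAF", faf)):
            tp, fp, fn, dsc = dice(
                scot, atrophy.clip(*domain), raster_um_per_px=raster, domain=domain
            )
            rec = ConcordanceRecord(
                tp_px=tp,
                fp_px=fp,
                fn_px=fn,
                dsc=dsc,
                modality=modality,
                axis=axis,
                eye_id=eye_id,
                visit_id=str(visit_id),
                n_absolute_loci=n_abs,
            )
            records.append(
                {
                    "eye_id": eye_id,
                    "visit": visit_id,
                    "axis": axis,
                    "modality": modality,
                    "tp_px": tp,
                    "fp_px": fp,
                    "fn_px": fn,
                    "dsc": dsc if dsc is not None else np.nan,
                    "n_absolute_loci": n_abs,
                    "discordance_class": classify_discordance(
                        rec, concordance.low_dsc_threshold
                    ).value,
                }
            )

        for idx, (pos_um, value) in enumerate(line_loci):
            refl = locus_reflectivity(
                profile, pos_um, footprint_um=deg_to_um(exam.stimulus.diameter_deg)
            )
            loci_rows.append(
                {
                    "eye_id": eye_id,
                    "visit": visit_id,
                    "axis": axis,
                    "locus_id": f"{axis[0]}{idx:02d}",
                    "position_um": pos_um,
                    "value_db": value,
                    "locus_class": classify_locus(value).value,
                    "reflectivity": refl,
                }
            )
    return records, loci_rows


def run_pipeline(config: RunConfig) -> RunSummary:
    """Run the full simulated study and fit the summary models.

    Deterministic given ``config`` (including its seed); per-eye and per-visit
    randomness is drawn from spawned seed sequences so cohort size changes do
    not reshuffle existing eyes.
    """
    t0 = _time.perf_counter()
    stage_log: list[dict] = []
    grid = config.grid.build()
    base_cfg = config.phantom_config()
    root_ss = np.random.SeedSequence(config.seed)
    eye_seqs = root_ss.spawn(config.n_eyes)

    all_records: list[dict] = []
    all_loci: list[dict] = []
    for e, eye_ss in enumerate(eye_seqs):
        eye_id = f"eye{e:02d}"
        visit_seqs = eye_ss.spawn(config.n_visits + 1)
        eye_rng = np.random.default_rng(visit_seqs[-1])
        for v in range(config.n_visits):
            cfg_ev = _jittered_config(base_cfg, config.jitter, eye_rng, v)
            pseed = int(visit_seqs[v].generate_state(1)[0] % (2**31))
            phantom = make_phantom(cfg_ev, seed=pseed)
            recs, loci = analyze_phantom(
                phantom,
                grid,
                render=config.render,
                exam=config.exam,
                oct=config.oct,
                concordance=config.concordance,
                eye_id=eye_id,
                visit_id=v,
            )
            all_records.extend(recs)
            all_loci.extend(loci)
    stage_log.append(
        {"stage": "simulate+concord", "seconds": round(_time.perf_counter() - t0, 3),
         "n_line_records": len(all_records), "n_locus_observations": len(all_loci)}
    )

    records = pd.DataFrame(all_records)
    loci = pd.DataFrame(all_loci)

    t1 = _time.perf_counter()
    modality_fit = None
    reflectivity_fit = None
    if not records.empty:
        wide = records.pivot_table(
            index=["eye_id", "visit", "axis"],
            columns="modality",
            values="dsc",
        ).reset_index().rename(columns={"OCT": "dsc_oct", "FAF": "dsc_faf"})
        paired = wide.dropna(subset=["dsc_oct", "dsc_faf"])
        if len(paired) >= 2 and (paired["dsc_oct"] - paired["dsc_faf"]).std() > 0:
            modality_fit = compare_modalities(paired, covariance="AR1")
    if not loci.empty and loci["locus_class"].nunique() >= 2:
        reflectivity_fit = fit_grouped_repeated(
            loci,
            covariance=config.stats_covariance,
            series_cols=("eye_id", "axis", "locus_id"),
        )
    stage_log.append(
        {"stage": "stats", "seconds": round(_time.perf_counter() - t1, 3)}
    )

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "scenario": config.scenario
        if isinstance(config.scenario, str)
        else "custom",
        "n_eyes": config.n_eyes,
        "n_visits": config.n_visits,
    }
    summary = RunSummary(
        records=records,
        loci=loci,
        modality_fit=modality_fit,
        reflectivity_fit=reflectivity_fit,
        provenance=provenance,
        stage_log=stage_log,
    )
    if config.output_dir is not None:
        _write_outputs(summary, config)
    return summary


def _write_outputs(summary: RunSummary, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.records.to_csv(out / "records.csv", index=False)
    summary.loci.to_csv(out / "loci.csv", index=False)
    config.grid.build().to_csv(out / "grid.csv")
    fits = {
        "modality_comparison": summary.modality_fit.to_dict()
        if summary.modality_fit
        else None,
        "reflectivity_by_class": summary.reflectivity_fit.to_dict()
        if summary.reflectivity_fit
        else None,
    }
    with open(out / "fits.json", "w") as fh:
        json.dump(fits, fh, indent=2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(summary.provenance, fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        fh.write(_report_text(summary))


def _report_text(summary: RunSummary) -> str:
    lines = ["gaconcord run report", "====================", ""]
    for k, v in summary.provenance.items():
        lines.append(f"{k}: {v}")
    lines.append("")
    rec = summary.records
    if not rec.empty:
        for modality in ("OCT", "FAF"):
            sel = rec[(rec["modality"] == modality) & rec["dsc"].notna()]
            if len(sel):
                lines.append(
                    f"mean DSC ({modality} vs microperimetry): {sel['dsc'].mean():.3f} "
                    f"over {len(sel)} lines"
                )
        counts = rec["discordance_class"].value_counts().to_dict()
        lines.append(f"discordance classes: {counts}")
        # sensitivity analysis: drop lines with exactly one absolute scotoma,
        # whose DSC is necessarily low
        kept = rec[(rec["n_absolute_loci"] != 1) & rec["dsc"].notna()]
        for modality in ("OCT", "FAF"):
            sel = kept[kept["modality"] == modality]
            if len(sel):
                lines.append(
                    f"mean DSC ({modality}), excluding single-scotoma lines: "
                    f"{sel['dsc'].mean():.3f} over {len(sel)} lines"
                )
    if summary.modality_fit is not None:
        d = summary.modality_fit.pairwise_differences[0]
        lines.append(
            f"paired DSC difference (OCT - FAF): {d.estimate:.4f} "
            f"[{d.ci_low:.4f}, {d.ci_high:.4f}], p = {d.p_value:.2e}"
        )
    if summary.reflectivity_fit is not None:
        lines.append(
            "reflectivity class means: "
            + ", ".join(
                f"{g}: {e.estimate:.2f}"
                for g, e in summary.reflectivity_fit.group_means.items()
            )
            + f" (covariance {summary.reflectivity_fit.covariance_structure})"
        )
    for entry in summary.stage_log:
        lines.append(f"stage {entry['stage']}: {entry['seconds']} s")
    return "\n".join(lines) + "\n"
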