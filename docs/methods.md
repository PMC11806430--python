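# Methods

This note documents the models, defaults, and numerical choices behind
`gaconcord`, and what the synthetic phantoms do and do not establish about
real data.

## Coordinate frame and units

All retinal positions are fovea-centred degrees of visual angle, positive
x temporal and positive y superior, independent of laterality (nasal loci are
never tested by the T-grid, so arm directions are semantic rather than
screen-space; a laterality flag on the phantom is reserved for mapping to
image columns). Angular-to-linear conversion is a single constant,
125 µm / 0.43° ≈ 290.7 µm/°, taken from the Goldmann III stimulus
equivalence so that every protocol length (125 µm stimulus diameter, 250 µm
lesion-persistence rule) is internally consistent. A schematic-eye formula
would differ by a few percent; the constant is configurable where it enters.

## Microperimetry simulation

The test grid is the protocol's T: a foveal locus plus arms of 15° (temporal)
and 12° (superior, inferior) at 1° spacing — 40 loci, the only partition of
40 consistent with the stated extents when the foveal locus is included
(whether the instrument tests the intersection locus itself is not public;
we include it).

**Staircase.** The 4-2 staircase starts at 10 dB. The exact instrument
termination rule is not public either, so the conventional two-reversal /
last-seen convention is adopted and documented: a *reversal* is a
seen→not-seen transition; steps are 4 dB before the first reversal and 2 dB
after; the run ends on the second reversal (result = last seen level), on a
seen ceiling stimulus (result = 20 dB), or on an unseen 0 dB stimulus
(absolute scotoma, coded −1). Exhaustive simulation over deterministic
observers shows every integer threshold in [2, 18] is recovered within 2 dB.

**Footprint observers.** A Goldmann III stimulus covers an extended retinal
area, so each locus observer aggregates the phantom's sensitivity field over
a 7-point footprint sample (centre + hexagonal ring at the stimulus radius).
The default aggregation is **max**: stimulation of surviving retina anywhere
under the footprint elicits a response. This is what makes loci straddling a
lesion border come out non-absolute, the mechanism behind
atrophy-without-scotoma discordance at lesion edges; *mean* aggregation is
available for sensitivity analyses. Responses are deterministic by default
(seen iff attenuation ≤ effective sensitivity); a logistic psychometric slope
can be configured, seeded for reproducibility.

**Classification.** Measured sensitivities partition into absolute (−1),
relative ([0, 8] dB), and non-scotomatous ((8, 20] dB) loci. Whether 8 dB
itself is relative or non-scotomatous is ambiguous in common usage
("0 to 8" versus "greater than 8"); we take [0, 8] inclusive as relative
since "greater than 8" is strict.

## Phantoms and OCT rendering

A phantom carries three polygon layers in degrees — OCT-true atrophy
(hypertransmission truth), FAF-true atrophy (the OCT polygons buffered by a
configurable offset; 0 keeps them identical), and *functional* atrophy
driving the sensitivity field, which defaults to the OCT polygons but can be
decoupled. The decoupling is the point: every clinically observed
discordance direction can be manufactured on demand (scenario presets:
`concordant`, `between_lesions`, `outer_retinal_atrophy`, `edge_of_lesion`,
`partial_pr_degeneration`, `faf_offset`).

The sensitivity field is `base` (default 14 dB, a typical perilesional
mesopic value in GA eyes) outside functional atrophy and `floor` (default
−1) deep inside, with a logistic transition of configurable width over the
signed boundary distance. No quantitative sensitivity-depth profile across
GA borders is established in the literature; the transition width is a free
parameter, not an estimate.

Rendering uses a layered-intensity model on a 768 × 496 grid spanning a 30°
field (lateral scale ≈ 11.36 µm/px with the package's µm/° constant; axial
3.87 µm/px): vitreous 25, retina 110, an RPE band of 230 attenuated to 90
over atrophy, and choroid at 80 outside versus 160 (hypertransmission)
inside atrophy crossings. Bruch's membrane is a shallow parabola, deepest at
the fovea (a flat option exists for tests), recorded per column as sub-pixel
ground truth. Speckle is multiplicative unit-mean gamma noise with shape
k = 4 — the standard minimal OCT speckle surrogate — configurable to
Gaussian or none. The renderer makes no attempt at photorealism (no drusen
texture, no vessel shadows, no layer-specific speckle statistics); passing
tests demonstrate correctness of the measurement chain on controlled
contrast, not segmentation performance on clinical images.

## Choroidal-slab profiling and hypertransmission

The slab is 64–200 µm beneath Bruch's membrane; the 64 µm anterior offset
keeps large hyporeflective choroidal vessels out of the average. Slab bounds
are computed in float depth from the sub-pixel BM trace and rounded to
nearest-integer rows, half-open, so tests are bit-stable. Per-column means
are reported raw (0–255) and normalised by 255 — no per-scan contrast
stretching, keeping group statistics comparable across scans. Columns whose
slab runs past the image bottom are averaged over the available rows and
flagged.

On real data the final lesion limits were drawn by a human grader guided by
the profile; a testable pipeline needs automation, so segmentation here is
threshold + gap-merge + minimum length, all exposed: columns at or above the
threshold form runs, gaps shorter than 50 µm are bridged (speckle dropouts,
vessel shadows), and runs shorter than 250 µm are discarded (short
hypertransmission defects are not accepted as cRORA). The default threshold
is Otsu's method on the profile — parameter-free on bimodal profiles —
guarded by a minimum separation of 20/255 between the Otsu classes, because
on a lesion-free (unimodal) profile Otsu would bisect the speckle
distribution and emit spurious runs. The grader's effective threshold and
gap handling on the clinical data are unknown; these defaults are
engineering choices.

The BM `fallback` segmenter (per column: smooth, find the brightest band,
take the steepest downward step within 60 µm below it; flag-and-interpolate
columns without a convincing drop, e.g. under hypertransmission) is a
documented heuristic standing in for a learned segmentation model's
contract. On noiseless phantoms it is within 1 px of truth; it is not
validated for noisy or pathological scans — use `truth` mode or an external
trace there.

## Overlay and Dice

Scotoma zones come from nearest-neighbour interpolation between loci: each
locus owns the half-open cell between midpoints to its neighbours, terminal
loci extend one half-spacing outward (making every locus footprint
symmetric; boundary handling is otherwise arbitrary), and nearest-neighbour
ties break toward the lower position. FAF zones are exact polygon/axis
chords; tangent touches below 1 µm are dropped.

Dice is computed on pixel counts (raster default = the scan's lateral pixel
size; an exact interval-arithmetic oracle is kept in the tests), with
TP/FP/FN as scotoma∩atrophy, scotoma-only, atrophy-only. Two conventions
matter:

* **Evaluation domain.** Concordance is evaluated over the *tested extent*
  of each line — the union of the loci's nearest-neighbour cells — because
  the T-grid covers only the temporal/superior/inferior arms while the scan
  spans the full 30° line; atrophy outside the perimetered extent can never
  be matched by measured function and would otherwise register as spurious
  FN. Structural intervals are clipped to this window before rasterisation.
* **Undefined DSC.** A line with neither scotoma nor atrophy has an
  undefined DSC and is excluded from aggregation rather than scored 1: it
  carries no concordance information. Lines with atrophy but no scotoma
  score 0 and are included by default; a switch
  (`exclude_lines_without_scotoma`) removes scotoma-free lines entirely,
  since whether such lines should enter the primary aggregate is a judgment
  call, and both behaviours are reported separately when it matters.

Low-concordance lines (DSC < 0.5) are classified by dominant error
direction: FP-dominant → scotoma without atrophy (function worse than
structure), FN-dominant → the reverse, ties → mixed. A sensitivity-analysis
filter drops lines with exactly one absolute-scotoma locus, whose DSC is
necessarily low.

## Repeated-measures models

Both analyses use the same fitter: a linear mixed model with an eye-level
random intercept and a structured residual covariance over repeated
measures, estimated by REML. The marginal covariance of eye *i* is
σ_b²·J + R_i with R_i block-diagonal over series (eye × locus for the
reflectivity model, eye × axis for the DSC comparison) and the within-series
structure one of AR(1), heterogeneous AR(1), or heterogeneous compound
symmetry, chosen by lowest REML AIC unless fixed. The restricted likelihood
is maximised over log/atanh-transformed parameters with L-BFGS-B; fixed
effects and their covariance follow by GLS at the fitted covariance.
Cell-means coding makes the fixed effects the per-group estimates directly.
The global Wald F-test of group equality (residual denominator df) gates
pairwise two-sided t-tests at 0.05, with no further multiplicity
correction. Whether random intercepts should be per eye or per eye × axis is
not settled; the series definition is an argument, and both layouts are
available.

The per-locus reflectivity is the profile mean over one stimulus diameter
(125 µm) centred on the locus — the averaging footprint is an assumption,
recorded as such, with the width configurable. Simulation at 24 eyes ×
5 visits (4 loci per class per eye, AR(1) ρ = 0.3 — one-time realism
choices) shows the global test's type-I error at the nominal 0.05 and
generating class means recovered within 2 SE at the expected rate; reported
standard errors match the empirical sampling SD. Known limitation: SEs are
plug-in Wald SEs — no Kenward-Roger-style small-sample inflation — so
*joint* coverage of several correlated contrasts runs a few points below
nominal at two dozen eyes, exactly as the t-versus-z effect predicts.

## Pipeline determinism and problem sizes

Every stochastic element (speckle, optional psychometric observers, cohort
jitter) draws from seed sequences spawned from the single run seed, so runs
are byte-identical given the same configuration, and adding eyes does not
reshuffle existing ones. Per-eye lesion jitter and per-visit growth are
available but default to zero, so a scenario's ground truth is exactly its
preset unless variation is requested. Default cohort sizes in examples and
tests (2–3 eyes × 2 visits end to end; 100–400 replicates for the
statistical calibration suites; 200 seeded renders for the speckle boundary
property) were chosen as the smallest sizes at which the checked properties
are stable.

## What the phantom tests do not show

Phantoms share one coordinate frame across modalities (the FAF-to-OCT
registration problem is assumed solved), have circular-ish single-boundary
lesions, stationary speckle, and deterministic observers. Results on them
validate the measurement and inference chain — geometry, staircase,
profiling, interval algebra, model recovery — not clinical segmentation
accuracy, fixation instability, test–retest variability, or registration
error on real images.
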