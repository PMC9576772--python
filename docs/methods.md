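# Methods

`axoncyto` models cerebral white matter as a fibre composite: relatively
straight, elliptical, tortuous tubular axons (bounded by their myelin
sheath, the "outer" surface) embedded in extra-cellular matrix. It
implements three measurement stages and one synthesis stage around that
model, plus a synthetic-data generator that stands in for FIB-SEM
acquisitions so the whole chain is testable against known ground truth.

## 2D myelin quantification (`myelin2d`)

Osmium-stained myelin appears as bright annuli on a darker, unevenly
illuminated background. The myelin content of an image is estimated as the
white-pixel relative frequency after a fixed stage order: 3×3 median
filter (mirror padding) → small greyscale opening (radius 1 px: isolated
bright pixels are not myelin) → background estimation by a large greyscale
opening → background subtraction (clamped at 0) → locally adaptive
binarisation → small binary opening.

Parameters, with defaults and rationale:

- `background_radius` = 50 px ≈ 1 μm at the 0.020 μm/px working
  resolution: the element must be larger than the largest axon radius so
  the opening erases all axon-scale foreground and keeps only the smooth
  illumination field. Radii above 3 px use an octagonal structuring
  element whose sequence decomposition is *exact* (the decomposed disk is
  approximate and can violate opening anti-extensivity, which the tests
  assert); the shape difference is irrelevant at this scale.
- `window` (adaptive threshold) = 1/8 of the smaller image dimension,
  rounded to odd. The per-pixel threshold is
  `max(2·(1 − sensitivity)·local_mean, min_threshold)` with strict
  inequality (ties → black). At the default `sensitivity` = 0.5 the
  threshold is exactly the local mean, so a constant image binarises all
  black; larger values admit more foreground.
- `min_threshold` = 0.05 of the dynamic range: a noise floor. The
  background opening sits roughly one noise standard deviation below the
  background surface, so the subtracted image carries a small positive
  residual everywhere; without a floor, empty regions would binarise
  white against their own near-zero local mean.

Homogeneity across subsamples is declared when every subsample's mean
white fraction lies within the largest subsample standard deviation of the
grand mean.

## 3D morphometry (`morpho3d`)

The imaging plane of a milled stack is generally not perpendicular to an
axon; a tube tilted by α shows an apparent area inflated by 1/cos α.
All measurements are therefore taken on planes perpendicular to the
centerline:

- **Centerline**: chain of per-slice voxel centroids in physical μm
  (anisotropic spacing is handled by never resampling; 150 nm slices vs
  20 nm pixels), smoothed with a 5-station moving average whose end
  windows shrink symmetrically (asymmetric end windows pull the endpoints
  inward along a curving path and bias the arc length). For periodic
  volumes, per-slice centroids are circular means unwrapped slice-to-slice.
- **Stations**: every 150 nm of arc length, first/last half-spacing
  trimmed; tangents by central differences at half-spacing.
- **Cross-sections**: the axon surface is the zero level of a slice-wise
  signed Euclidean distance field interpolated linearly in z
  (shape-based interpolation). Interpolating the *binary* mask instead
  biases oblique sections toward the intersection of consecutive
  outlines, an error of several percent at 45° tilt with 150 nm slices;
  the distance-field zero level morphs one outline into the next, which
  is what a slice-interpolating surface reconstruction does, and keeps
  the tilted-cylinder area error under 1% at all tilts up to 45°.
- **Descriptors**: shoelace area; best-fit diameter d = 2√(area/π)
  (equivalent-area circle); moment-matched ellipse from the closed-form
  second moments of the polygon interior, reported as ellipticity
  E = a/b − 1 (0 = circle, 1 = major axis twice the minor); tortuosity
  τ = 1 − end-to-end distance / arc length (0 = straight).
- **Aggregates**: axonal density = axon count / box volume (axons/mm³,
  every axon with any voxels counts once); volume fraction = labelled
  voxels / all voxels; per-axon volume = Σ station area × spacing.
  Stations whose polygon has fewer than 5 vertices or area below
  π(0.1 μm)² (the 0.2 μm resolvable-diameter floor) are excluded; axons
  that cannot be measured are recorded and reported, never silently
  dropped.

## Lognormal statistics (`statsfit`)

Closed-form maximum likelihood on ln x (μ = mean, σ² = divisor-n
variance); mode = exp(μ − σ²), median = exp(μ), arithmetic moments by the
standard identities. `mode_median_to_params` inverts published
(mode, median) pairs to (μ, σ), which is how the bundled tract presets are
built. The moment-agreement check compares fit-implied arithmetic
mean/SD with the sample's own (default tolerance 10%); it is a coarse
adequacy check, deliberately insensitive to mild non-lognormality (a
uniform sample passes — a test documents this). Q-Q data uses plotting
positions (i − 0.5)/n with the reference line from the ln-sample mean/SD.
Exact zeros (perfectly straight synthetic axons) are excluded from
log-based fits with a reported count.

## RVE generation (`rve`)

Inputs per tract (bundled presets `cc`, `cr`, `fo`, built only from
published summary values): lognormal area and diameter (μ, σ) via
mode/median inversion, ellipticity range, mean tortuosity ± SD, axonal
density ± SD, volume fraction ± SD, interlayer area CV (0.10) and
interlayer semi-axis step cap (0.05 μm); minimum inter-surface clearance
0.02 μm (one in-plane voxel, at the low end of the observed ECM gaps).

Algorithm (every draw from the config seed):

1. **Count selection.** The published density and volume fraction are not
   mutually consistent with the area distribution (density × mean area ×
   length over-predicts VF by ~40% for the corpus callosum), so the axon
   count N is chosen inside the density ± SD band such that the
   cumulative drawn area lands closest to the VF target; drawn areas are
   rescaled only if still outside VF ± SD, and only to the nearest band
   edge, preserving the drawn distribution as far as possible.
2. **Sway calibration.** Lateral undulation is decomposed into a
   bundle-coherent path shared by all axons plus a 10% per-axon
   component (long-correlation AR(1), slope-capped at ≈40° tilt).
   Observed inter-axon gaps are tens of nanometres while the tortuosity
   targets imply sub-micrometre lateral structure; only coherent bundle
   undulation satisfies both, and shared sway preserves inter-tube
   distances exactly. The amplitude is calibrated by bisection so that
   the mean tortuosity — measured exactly as the morphometry stage
   measures it (slice-midpoint sampling + 5-station smoothing) — hits
   the tract target; tolerance 10⁻⁴ on the amplitude.
3. **Placement.** Random sequential addition of the perpendicular-plane
   seed ellipses, largest first, with periodic x–y wrap and clearance
   `min_gap + 2 × growth cap`; exact polygon distances (32-gon ellipses)
   behind a bounding-circle prefilter.
4. **Lofting.** Station sections every 150 nm in z. The z-plane section
   is the drawn perpendicular ellipse (with its per-station lognormal
   area jitter, CV 0.10, step-capped at 0.05 μm/station) stretched by
   sec α along the local tilt azimuth of the *measurement-convention*
   smoothed path — so perpendicular cuts recover the drawn area and
   ellipticity. This makes the in-plane orientation drift slowly along
   z.
5. **Overlap resolution.** Sampled distance checks at every station
   against periodic neighbours. Phase 1 rebuilds violating tubes on the
   pure shared sway; phase 2 shrinks both sections at any residually
   violating station until the clearance holds (the tilt stretch moves
   sections toward each other faster than their separations grow at
   high-tilt stations), then re-imposes the per-station step cap by
   lowering neighbours. Shrinking never creates new contacts, so the
   invariant is guaranteed.
6. **Outer loop.** Collision shrinkage systematically pulls the achieved
   volume fraction below the drawn total, so the generator iterates:
   while the achieved VF (after shrinkage) is more than half an SD from
   the target and iterations remain (≤5), all areas are rescaled toward
   the target and placement repeats; the realisation closest to the
   target is kept. Only if the best realisation is outside target ± SD
   does generation fail, naming the binding constraint.

STL export lofts each tube as a 32-vertex ring strip with end caps
(watertight, consistently outward, χ = 2 per shell; the inscribed 32-gon
under-estimates section area by 0.64%, within the 1% volume tolerance the
tests assert). Tubes crossing the periodic x–y boundary are clipped to
the box with the wrapped remainder emitted as separate closed shells;
cut faces are capped by ear-clipping the boundary loops (no external
triangulation engine required). A clipped sliver that cannot be closed
is repaired hole-by-hole; only a still-open sliver would abort the export.

## Synthetic data (`synth`)

The 2D phantom emulates a stained white-matter face: background at 30% of
the 16-bit dynamic range, myelin annuli at 75%, glial blobs at 45%
(between background and myelin; sparse by default so their accepted
contamination of the white count stays ≈1%), mild Gaussian grain
(σ = 1.5%), an additive quadratic illumination field scaled to the
configured amplitude, and salt-and-pepper noise on a configured fraction
of pixels. Annuli (outer diameter 0.6–1.6 μm, thickness 0.12–0.35 μm,
matching the published diameter scale) are placed largest-first by
rejection sampling with pixelwise disjointness and a 1-px separation;
unplaceable rings are skipped and refill batches of small rings close the
remaining gap. The truth mask and fraction are captured *before* any
corruption. Contrast levels are conventions chosen to exercise the
pipeline, not calibrated to any real acquisition.

The 3D phantom delegates tube generation to the RVE kernel (one geometric
model for phantoms and syntheses) and voxelises with the center-inside
rule (surface ties → inside, with a float-rounding allowance) on the
anisotropic 0.020 × 0.020 × 0.150 μm grid.

What the generators deliberately do not emulate: milling artefacts,
curtaining, charging, myelin delamination, non-tubular glial processes,
axon branching, or entangled fibre configurations. Passing round trips
therefore demonstrate correctness of the measurement chain on the fibre
model, not robustness to every real-tissue artefact.

## Problem sizes and numerical choices

Unit tests run on 256² phantoms and 5–6 μm boxes (a handful of axons);
the acceptance suite and script run full 764×1024 phantoms and
15×15×15 μm³ RVEs (≈30–60 axons, ≈57 M voxels), with station subsampling
(every 4th–6th station) for the ellipse summaries, which are stable per
station. Measured tortuosity, density and volume fraction do not depend
on the station stride. Known limitations: at high volume fraction and
high tortuosity jointly (the fornix corner), collision shrinkage trims a
few percent of section area at high-tilt stations, and the density/VF
compromise truncates the heavy upper tail of the drawn area distribution
— the robust mode/median round-trip is unaffected, the arithmetic mean is
biased low by up to ~15%.
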