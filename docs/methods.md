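# Methods

## The measurement model

A microvascular-network permeability experiment produces, per device, a
registered two-channel confocal z-stack: a vessel-marker channel (GFP-tagged
endothelium) and a tracer channel (fluorescently labelled cargo). The
package treats both channels as non-negative float intensity grids in axis
order (z, y, x) with an explicit physical voxel size in µm; intensities are
never rescaled on read, and a missing voxel size is an error rather than a
silent 1 µm default (precedence: explicit argument > TIFF/OME metadata >
JSON sidecar).

Two complementary readouts are computed.

### Compartment partitioning

The vessel channel is thresholded (global Otsu by default; per-slice Otsu
and fixed thresholds available) into a binary vasculature mask, followed by
morphological closing (default radius 2 µm, applied on an edge-padded array
so vessels touching the stack border are not eroded) and removal of
connected components below 100 µm³. Mean tracer intensity is computed per
z-slice over mask voxels (intraluminal) and non-mask voxels
(extravascular), and the per-slice means are averaged unweighted across the
stack. This two-step average differs from a pooled voxel mean whenever the
mask area varies with depth; the pooled variant is exposed as an option
(`use_pooled`). Slices where a compartment is empty contribute no term to
the stack average (they are excluded, not counted as zero, which would bias
toward zero).

Between-condition effects are expressed as day-normalized differences: for
each ligand-functionalized (TF) device, Δ = value − mean(control values),
computed strictly within one measurement day. Mixing days in one Δ call is
an error; the grouping is what removes day-to-day drift in illumination and
detector gain.

### Distance-resolved profiles

Line scans are sampled by bilinear interpolation on 2D z-projections, with
pixel centres at (index + 0.5)·pixel size. Lumen borders are found by level
crossing on the vessel profile: baseline = mean of the outer 10 % tails,
level = baseline + f·(peak − baseline) with f = 0.5 by default (FWHM —
symmetric under blur; the fraction is a parameter), and the borders are the
linearly interpolated crossings tightest around the global peak. A profile
without a crossing pair bracketing the peak ("no enclosed lumen") is an
error, and such scans are skipped during batch analysis.

Two projections are used deliberately:

* **tracer values come from the average-intensity projection**, matching
  how such profiles are conventionally measured;
* **border detection and diameters use the maximum-intensity projection of
  the vessel channel.** The average projection of a filled tube has a
  chord-length (semicircular) cross-section whose half-maximum width is
  √3/2 ≈ 0.87 of the true diameter; the maximum projection restores a
  top-hat whose half-maximum crossings sit at the true borders. Diameter
  recovery on cylinder phantoms is within one voxel for radii 5–30 µm at
  PSF σ ≤ 2 µm.

The tracer profile beyond the border (distance d = 0 at the level-crossing
border on the analysis side, measured along the scan line) is normalized as

    value(d) = 100 · (tracer(d) − background) / (luminal_reference − background)

i.e. background is subtracted from both numerator and reference before
forming the percentage. The luminal reference is the mean tracer value
inside the detected borders; by default the pipeline restricts it to the
central 50 % of the lumen interval (`core_fraction = 0.5`) because on
average projections the z-columns near the lumen edge mix luminal with
perivascular signal (the lumen chord shrinks toward the edge), which
dilutes the reference by several percent at typical geometries; the lumen
core is nearly undiluted. `core_fraction = 1` reproduces the plain
inside-borders mean. Background defaults to 0 and can be supplied
explicitly or estimated from the outer scan tails (`estimate_background`);
the tail estimate is only sensible when the scan reaches regions of pure
background, which a 100 µm analysis window next to a vessel often does not.

Profiles are truncated at 100 µm (parameter), binned to a common grid
(default 5 µm bins, bin centres at (k + ½)·width), averaged unweighted
across scans with per-bin standard deviations, and summarized by ordinary
least squares of % value on distance. Conditions are compared by the mean
% over the profiled range ("mean permeability" in the assay's sense — not
a P_app coefficient) and by the ratio of slope magnitudes (defined only
when both slopes are negative).

Scan placement replaces manual blinded line drawing with a reproducible
procedure: the projected mask is skeletonized, n skeleton points at least
`min_separation` µm apart are drawn deterministically from a seeded RNG,
and scans are placed perpendicular to the local skeleton tangent (principal
axis of skeleton pixels within 10 µm). "Evenly distributed" is thus
operationalized as a minimum-separation constraint.

## The synthetic phantom generator

Phantoms emulate the statistical structure the analysis assumes: tubes
(polyline centerline + radius) in an empty gel; vessel channel =
`vessel_intensity` inside tubes; tracer channel = `tracer_luminal` inside
and `max(floor, tracer_luminal·(a + b·d))` outside, with d the true
Euclidean distance to the nearest tube surface, a ∈ (0, 1] the fractional
intensity at the wall, b ≤ 0 the decay slope per µm and `floor` an absolute
background. The decay is linear-with-floor (not exponential) because the
analysis fits lines; an exponential variant can be emulated by piecewise
tube parameters but is not built in. Voxels straddling a tube surface get
fractional occupancy (linear ramp over one voxel) — the partial-volume
effect of sampling a sharp boundary on a finite grid — so intensity edges
sit at the true surface rather than the nearest voxel centre. Optics and
detection are a Gaussian PSF blur (σ in µm, anisotropy handled via the
voxel size) followed by Poisson shot noise on the blurred signal
(`Poisson(value·poisson_scale)/poisson_scale`) plus additive Gaussian read
noise, clipped at zero. Noise comes after blur, as shot noise acts on
detected photons. Every artifact is a pure function of (parameters, seed).

Defaults: one straight tube of radius 15 µm spanning a 16×256×256-voxel
stack at 2 µm isotropic voxels (z-depth 32 µm ≈ the tube diameter,
mirroring stacks that cover just the depth of the vasculature — deeper
stacks only dilute the average projection), vessel and luminal tracer
intensity 1000 a.u., tracer floor 20 a.u., PSF σ = 1 µm, read noise
σ = 10 a.u., Poisson scale 1.

The default 2×2 experiment design (TF/control × 30 min/24 h, three devices
per condition split over two batch days) encodes the biological pattern
under study via per-cell (a, b): TF (0.92, −0.0006) and control
(0.90, −0.0006) at 30 min — near-identical early distribution — and TF
(0.876, −0.001) vs control (0.875, −0.0036) at 24 h — same wall intensity
but a 3.6× steeper control decay. These values were chosen so the
closed-form cell means 100a + 50·100b equal 89.0/87.0 and 82.6/69.5 % and
the 24 h slope ratio equals 3.6.

What the phantoms do *not* emulate: curved/branching network topology (the
generator supports polyline tubes, but the default is straight, and the
distance-along-scan vs Euclidean-distance discrepancy for curved vessels is
not exercised), the bright media channel bordering the gel, nanoparticle
aggregation, non-uniform illumination, and any real microscope's gain
curve. Passing tests therefore demonstrate correctness of the computation
under the stated forward model, not robustness to every artifact of real
stacks.

## Numerical choices and degenerate inputs

* All OLS fits go through `scipy.stats.linregress`; a constant profile has
  slope 0 and r² reported as 0 (the correlation is undefined).
* Level crossings are linearly interpolated between samples; with multiple
  crossing pairs, the pair tightest around the global peak wins.
* Otsu on a constant stack raises "no threshold separable"; an empty mask
  after cleanup is a warning, not an error.
* Slices with an empty compartment carry NaN means and are excluded from
  stack averages; a measurement value of NaN propagates visibly rather
  than silently becoming 0.
* The calibration curve regresses intensity on amount and inverts
  (classical calibration); inverse regression is an option. Negative
  calibrated amounts are clipped to 0 with a warning; yields above 100 %
  are reported as computed with a warning, since noise can legitimately
  exceed the nominal input.
* Seeds: experiment-level seeds are spawned with `numpy SeedSequence` from
  one master seed and reduced below 2³¹; identical configs give
  byte-identical output tables.

## Problem sizes

The test suite and the acceptance script run on scaled-down phantoms chosen
as the package's own verification sizes: Monte-Carlo checks use
16×64×64- to 16×128×256-voxel stacks (100 seeds), and the end-to-end
experiment template is 8×64×64 voxels per device for the 100-seed ordering
check. The default pipeline scene (16×256×256 at 2 µm) corresponds to a
512×512 µm field — smaller than a full-chip region of interest
(~1223×1583 µm); rendering a full-size field is just a matter of passing a
larger `shape`, with cost linear in voxel count.

## Known limitations

* The level-crossing fraction of the original border-detection tool is not
  standardized across instruments; 0.5 is a defensible, blur-symmetric
  default but absolute diameters shift with the fraction.
* Mean permeability depends on the distance origin; a border mislocated by
  δ µm shifts the profile by roughly |slope|·δ percentage points.
* Whether the "outside" compartment should exclude the media channel of a
  real chip is assay-dependent; an exclusion ROI can be emulated by masking
  the tracer stack before partitioning, but no dedicated argument is
  provided.
* The Δ statistic deliberately stops short of inference; two-way ANOVA or
  post hoc tests on the tidy output tables are left to standard statistics
  packages.
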