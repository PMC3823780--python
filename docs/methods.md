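# Methods

This note documents the models, conventions and numerical choices behind
`spiralfilm`, and what the synthetic studies do and do not demonstrate.

## Spiral geometry

The film surface is the Archimedean spiral `r = aθ` extruded along the
cylinder axis. Defaults reproduce the published phantom: `a = 0.5129`
cm/rad, `θ_min = π/3` (the film cannot bend more tightly), film
13.0 cm × 25.4 cm. The arc length from the origin is closed-form,

    s(θ) = (a/2) [ θ√(1+θ²) + asinh θ ],

and `θ_max` is never a free parameter: it is the Brent root of
`s(θ_max) − s(θ_min) = 25.4 cm`, ≈ 9.8989 rad (~1.6 turns, outer radius
≈ 5.08 cm). Film coordinates are `u` (along the arc from the `θ_min`
edge) and `v` (axial from one film edge); the film is axially centred
on the isocenter plane, so `z = v − width/2`. The winding sense is a
configurable handedness flag (default counterclockwise), since nothing
in the phantom's definition fixes it. The inverse map resolves the
winding by choosing the `θ ∈ [θ_min, θ_max]` matching the point's polar
angle modulo 2π with the smallest radial residual (ties to the smaller
θ); points radially farther than 0.05 cm from every turn are
"off-surface". Arc-length inversion uses safeguarded Newton iteration
(exact derivative `a√(1+θ²)`, bisection fallback), accurate to well
below 1e−9 cm.

One genuine tension in the constants: the spiral was designed to pass
through the chamber point (2, −2, 0) cm at `θ = 7π/4`, but
`a = 0.5129` puts the spiral at (1.9939, −1.9939), 0.086 mm short;
solving the constraint exactly would give `a ≈ 0.5145`. We keep the
stated 0.5129 and simply report the offset (the acceptance script
prints it).

## Dose grids and interpolation

`DoseGrid` stores dose in cGy on voxel centers with origin, spacing and
an orthonormal orientation; all lengths are cm internally and DICOM mm
are converted at the boundary. Interpolation is trilinear among the 8
surrounding voxel centers, evaluated by rotating the query point into
the grid frame; the valid domain is the center-to-center bounding box
and there is **no extrapolation** — outside points are invalid (NaN)
and excluded downstream. Trilinear was chosen because it is standard
for dose grids and exactly testable: it reproduces affine fields and is
bounded by the 8 neighbouring values.

RT Dose files are written with 16-bit stored integers and
`DoseGridScaling = max_dose / (2¹⁶ − 1)`, so quantization is < 0.002%
of the maximum dose; units are GY in the file, cGy in memory.

## Resampling

Calculated dose maps are produced directly on the film raster (pixel
centers at `(i + ½)·pitch`, default pitch the 72-dpi scan pitch
25.4/72 mm), avoiding any second regridding before comparison. The
raster size follows by truncation, giving 720 × 368 pixels for the
default film at the default pitch. Because the spiral surface is
developable, the film raster is isometric in `(u, v)` and no area
weighting is needed. Orthogonal planes (transverse/coronal/sagittal)
are extracted through the isocenter at the same pitch.

## Film model and calibration

The film's dose-responding quantity is the net optical density of the
red channel, `netOD = log10(I₀/I)`, referenced to the 0-cGy piece and
clipped below at zero; zero intensities map to 0.5 LSB with a warning.
Dose recovery uses the standard radiochromic form

    D(netOD) = b·netOD + c·netODⁿ,  b, c ≥ 0,  n ∈ [1.5, 4],

fitted by least squares in dose. The constraints make the curve
monotone with `D(0) = 0`, hence numerically invertible (dense-table
seed + Newton polish, used by the virtual film generator). The
calibration series is the ten-level set 0 … 318.3 cGy. Registration of
the measured map allows axis flips and in-plane translation only — the
spiral grooves physically fix rotation. The 24-h darkening wait is
metadata with no computational role.

## Gamma analysis

The measured distribution is the reference; the calculated one is
searched. For an analysed pixel `m`,

    γ(m) = min over calculated samples c of
           √( |r_c − r_m|²/dta² + (D_c − D_m)²/(dd·D_ref)² ),

with `dta = 3 mm`, `dd = 3%` by default. Local normalization takes
`D_ref = D_m` pixel by pixel; global (VanDyk) normalization takes the
measured plane maximum or a prescribed dose. The analysis mask keeps
pixels at or above a threshold (default 50%) of the measured plane
maximum that are valid in both maps; measured-valid pixels with invalid
calculation are excluded and counted separately.

Numerically, the calculated map is densified by bilinear interpolation
with an integer refinement factor per axis chosen so the sub-pixel step
is ≤ dta/10; original pixel centers remain nodes, so the optimised and
brute-force searches scan the identical candidate set. The optimised
search evaluates candidates within a radius (default 3·dta) by strided
slicing of the padded fine grid, with offsets visited in order of
increasing spatial penalty and an early exit once the spatial term
alone dominates. It provably returns the global minimum: a candidate
farther than `γ_found·dta` loses on its distance term alone, and the
radius is expanded whenever that bound is not yet met. The brute-force
variant scans every densified sample with no pruning and serves as the
independent oracle.

A pixel passes when `γ ≤ 1 + 1e−9`; the epsilon forgives pure
floating-point round-off at the boundary (a pure shift of exactly one
DTA otherwise flips between pass and fail depending on how the
sub-pixel step divides). Pass-rate summaries use the sample SD (n−1);
for a single plane the SD is reported as 0 and flagged as undefined.

Radial profiles sample both maps bilinearly along rays from the film
center at a fixed angular step (default 12°, 30 profiles) at half-pixel
spacing, each distribution normalised to its own plane maximum; rays
stop at the pixel-center extent where bilinear sampling is defined.
Isodose contours are marching-squares polylines at 10%, 20%, … 90% of
the plane maximum.

## Exact Wilcoxon signed-rank test

Plane and grid-size comparisons involve ~9 paired values, where the
normal approximation is poor. Zero differences are dropped, tied
absolute differences get mid-ranks, and the null distribution of the
positive rank sum is computed exactly by dynamic programming over the
(doubled, hence integer) ranks — arithmetically identical to
enumerating all 2ⁿ sign assignments, feasible to n = 25. The two-sided
p doubles the smaller tail, capped at 1. Nine concordant pairs give the
smallest attainable p, 2/512 ≈ 0.0039.

## Synthetic studies: what they show and what they do not

The dose engines are analytic, not Monte Carlo. A single field is
`D = D₀·P(x)·P(z)·exp(−μ·depth)` with erf penumbra edges (σ = 0.4 cm)
at ±field/2 (6 × 6 cm² default), attenuation μ = 0.04 cm⁻¹, entry at
the 6-cm cylinder surface. The VMAT-like engine superposes that kernel
over 72 uniformly spaced gantry angles aimed at the target and
normalises the target-center dose to 200 cGy (one fraction of a typical
74 Gy / 37-fraction prostate prescription). The phantom radius (6 cm)
exceeds the derived outer spiral radius (~5.1 cm) so the film is fully
covered; the phantom's true outer dimensions are not published, so this
is a documented assumption. Virtual films push the planar dose through
the inverse calibration response to a 16-bit red-channel value
(unexposed level 40000); the generating curve is
`(b, c, n) = (300, 500, 2.5)`, spanning the ten-level series with netOD
up to ~0.6, typical of red-channel EBT2 readings. Perturbations (shift,
dose scale, multiplicative noise, axial stripes) are explicit and
seeded; all generators are bit-reproducible given (spec, seed).

These studies validate the *pipeline*: exactness of the geometry and
interpolation, correctness of the gamma search against its oracle,
identity of the unperturbed chain, and the directional responses to
controlled errors. They do not reproduce clinical pass rates: real
films add scanner lateral response, batch variation and development
kinetics, and a real TPS adds Monte Carlo noise and beam-model effects,
none of which are modelled here. Two consequences worth noting
explicitly. First, a pure rigid shift of a smooth field by up to one
DTA is fully matchable by the spatial search, so pass rates stay at
100% through 3 mm and only drop beyond (the acceptance script shows
98.1% at 5 mm); real measurements fail earlier because shift combines
with noise and calibration error. Second, under 3 mm/3% both the 2 mm
and 1 mm calculation grids verify the smooth synthetic fields at 100%,
so the grid-size effect appears not in the pass rate (the trend
inequality holds, but as equality) but in the maximum deviation from
the analytic truth on the spiral plane, which the 1 mm grid reduces by
roughly 3–4× (≈ 1.5 cGy → ≈ 0.4 cGy on the default plans).

## Problem sizes

The studies are sized for a desk-scale run: virtual films for the
chain studies use an 18-dpi raster (pitch 25.4/18 mm ≈ 1.41 mm,
180 × 92 pixels on the film), the grid-size experiment resamples at
1 mm pitch over five plans, and oracle-equivalence checks use ten
64 × 64 map pairs. The full-resolution 72-dpi raster (720 × 368) is
exercised in the I/O tests and available throughout via the default
pitch.
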