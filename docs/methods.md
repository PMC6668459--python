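# Methods

`platefpm` models the computational pipeline of an array-level Fourier
ptychographic microscope (FPM): 96 miniature microscopes image the wells of
a standard microtiter plate in parallel under one shared LED array, and
each well's low-resolution intensity frames are fused in the spatial
frequency domain into a high-resolution complex (amplitude + phase) image.
This note records the models, the defaults and the numerical choices, and
what the synthetic experiments do and do not establish.

## Illumination geometry and scheduling

Wells form an 8 x 12 lattice at 9 mm pitch; the LED plane sits at
`h = 33 mm` with 3 mm LED pitch, so each well sees a 7 x 7 segment
(18 mm x 18 mm) of the shared array. Because the segment is twice the well
pitch wide, 75% of its area is shared with neighbouring wells and the whole
plate needs only 1120 LEDs instead of 96 x 49 = 4704.

Coordinates are right-handed with the sample plane at `z = 0`, the LED
plane at `z = +h`, `x` along the 12-well axis. Well centres are snapped to
integer multiples of the well pitch (the central well is the origin) so
they stay on the LED lattice for any plate size; for even row/column counts
this puts the origin half a pitch off the geometric plate centre, which
affects nothing downstream.

The parallel schedule lights a rectangular sub-lattice with
source-to-source separation `m` LED pitches and sweeps all `m^2` offset
classes. `m` must satisfy `m * pitch > 2 h tan(asin(NA_illum))` so no well
ever sees two sources inside its acceptance cone; this is validated up
front and re-verified exhaustively during plan construction. The default
`m = 8` yields 64 frames per batch of which 49 land inside any given
well's segment (the other 15 are padding for that well but useful to its
neighbours). For `m * pitch` equal to the segment width the two
segment-edge LEDs share an offset class and appear in the same frame, so
full-segment coverage is provably impossible; the planner then enforces
coverage of the segment interior only. Acquisition is brightfield-only:
frames whose illumination NA exceeds the objective NA (0.23) are dropped,
leaving 21 of the 49 segment LEDs.

## Meniscus ray tracing

A well holds ~3 mm of medium (n = 1.33) whose free surface is modelled as
flat or as a spherical cap pinned at the well wall
(`cap_radius_of_curvature_mm < 0` = concave-up; `|R|` must be at least the
well radius). For each LED/field-point pair the surface intersection of the
refracted path is found by 2-D root finding (Powell hybrid on the landing
error, tolerance 1e-6 mm, iteration cap 100; solved in offset coordinates
because MINPACK's relative finite-difference step degenerates at
zero-valued coordinates, with a coarse grid restart for strongly curved
caps where the surface-point-to-landing map folds). The effective
wavevector delivered to the reconstruction is
`n_liquid * (dir_x, dir_y) / lambda_vacuum` of the in-liquid ray. With all
indices set to 1 the tracer reduces exactly to the free-space geometry, a
property the tests exploit as an oracle. Only directions are traced — no
radiometry, polarization or evaporation. An optional plate-bottom slab adds
a parallel lateral offset. Strong curvatures (|R| close to the well radius)
create genuine caustic shadow zones where some field points are unreachable
from a given LED; the tracer reports this as a calibration error rather
than clamping.

The qualitative meniscus effect — centre-to-edge incidence-angle drift
several times the flat-surface parallax — appears for tight curvatures
(ratio > 3 at `R ~ 1.1` well radii, ~2.3 at 2 well radii). The physical
instrument's measured 5-degree/6x drift corresponds to a curvature not
derivable from published geometry, so it is treated as a calibration
example, not a target.

## Pupils, Zernike modes and defocus

Pupils live on the NA-bounded disk `|f| <= NA/lambda` of a centred
spatial-frequency grid (zero outside; amplitude clipped at 1.5 to bound
iterative recovery). Zernike indexing is Noll (1 piston, 4 defocus, 5/6
astigmatism, 11 primary spherical), with maps normalised to unit RMS over
the disk. Some instrument literature counts defocus as the "fifth"
coefficient by starting at 0; this package standardises on Noll. Fitting
projects a quality-guided-unwrapped phase map (scikit-image
`unwrap_phase`) onto the first 15 modes by least squares; a synthesised
map round-trips to 1e-6. Lens-to-lens orientation across the array is
arbitrary, so paired sin/cos modes are summarised as rotation-invariant
quadrature magnitudes per (n, |m|).

Defocus uses the angular-spectrum kernel
`phi(f) = 2 pi dz (sqrt(1/lambda^2 - |f|^2) - 1/lambda)` anchored to zero
piston at `f = 0` (|dz| <= 500 um supported). An axial shift of a thin
sample multiplies the pupil by `exp(i phi)` identically for every
illumination angle, which is what makes blind refocusing a pupil-domain
search.

## Forward model and sensor noise

Per frame the high-resolution object spectrum is shifted by the frame's
effective wavevector, cropped to the pupil sub-band, filtered by the
complex pupil, inverse-transformed and squared. Downsampling is by
spectral cropping so the forward/adjoint pair is exact; a unit-amplitude
object under the axial LED yields unit intensity. Off-grid wavevectors are
split into an integer spectral-pixel shift plus a sub-pixel remainder
realised by evaluating the pupil at `P(f - delta)` (Fourier shift, clipped
to a 2-pixel-dilated support to suppress sinc tails); without this, half a
spectral pixel of quantisation costs half a fringe across a tile.

The default tile is 110 um (275 raw pixels at the 0.4 um object-side
sampling) reconstructed at 4x upsampling (0.1 um). Phantoms: a phase-only
Siemens star (default 40 spoke pairs, 1 rad depth, disk diameter 0.9 x
extent), non-overlapping 2 um spherical-phase beads (rejection-sampled),
and smooth cell-like blobs. Sensor noise is Poisson shot noise at
`photons_per_unit = 2000` photons per unit intensity with Gaussian read
noise of 5 photons and a static horizontal band pattern (amplitude 0.05,
smoothed random rows) identical across repeats and illuminations — chosen
to mimic a consumer-grade CMOS sensor qualitatively; the instrument's true
photon statistics are not published, so these are stand-ins. All
randomness flows through one seeded generator; identical seeds give
bit-identical datasets.

Whole-plate simulation draws each well's pupil from the lens-population
statistics (astigmatism sigma 0.88 rad on Noll 5 and 6, spherical sigma
0.25 rad on Noll 11) and its focus offset from the well-depth spread
(sigma 17 um). These published spreads are *inputs* to the simulator — the
desk-scale build cannot re-measure a physical lens population.

## EPRY reconstruction

For each frame the pupil-supported sub-spectrum at the frame's wavevector
gives the modelled low-resolution field; its magnitude is replaced by the
measured `sqrt(I)` and the mismatch drives paired updates of object
spectrum and pupil. The object step is the classic
`O += alpha conj(P) dPsi / max|P|^2`. The pupil step defaults to the
regularized pixel-wise (Gauss-Newton) form
`P += beta |O| conj(O) dPsi / (max|O| (|O|^2 + (delta max|O|)^2))` with
`delta = 1e-4`: object spectra are DC-dominated, and with only 21
brightfield LEDs the max-normalised textbook step moves the pupil only
along the DC trajectory (0.8 rad of injected astigmatism is still
invisible after 300 epochs, and raising beta diverges), while the
pixel-wise step recovers it to < 0.1 rad RMS in ~150 epochs. The textbook
step remains available (`ReconConfig(pupil_update="epry")`).

Frames are processed in ascending |k| order (low NA first); an epoch is
one pass. The epoch residual is
`sum_j sum_px (sqrt(I_j) - |psi_j|)^2 / sum_j sum_px I_j` — zero iff the
forward model reproduces every frame's magnitude, and invariant to the
object's global phase. When it fails to improve by at least 1% for 2
consecutive epochs both steps are halved (the adaptive rule; factor and
patience configurable). The object is initialised as the bilinearly
upsampled square root of the most axial frame with zero phase, its
spectrum clipped to the measured synthetic-aperture disk (max |k| + pupil
cutoff) because no measurement ever corrects energy outside it. Recovered
objects carry a global phase and a sub-pixel shift gauge; tests remove
both by cross-correlation registration before any error metric.

Blind refocusing is two-stage: a linear scan of defocus candidates (default
+/-100 um at 5 um steps), each scored by a 3-epoch object-only
reconstruction with an ideal pupil times the candidate defocus kernel,
then full EPRY seeded at the argmin. A non-unimodal scan (secondary minima
with > 2% prominence) warns and returns the global argmin. On simulated
data the estimate lands within one coarse step of truth across +/-100 um.

## Frame averaging and pattern removal

Temporal denoising is the per-pixel mean over repeats (std falls as
1/sqrt(n); the acquisition default is 10 repeats). The static band pattern
is estimated as the per-pixel median across illumination-averaged,
mean-removed frames — the pattern is the only component static across
illumination angles — and requires at least 3 distinct illuminations to be
identifiable. Corrected frames plus the estimated pattern reproduce the
originals exactly. The z-stack selector scores planes by Tenengrad
(normalised Sobel gradient energy) with ties resolved to the lowest z.

## Tiling and mosaicking

The 1.1 mm x 0.85 mm FOV is split into `ceil(extent/tile)` segments per
axis — 10 x 8 for 110 um tiles — each grown by half the 5% overlap margin
on interior sides (a minimal covering grid with a hard >= 5% overlap of
275 px tiles would need 11 columns, contradicting the instrument's 10 x 8
layout; the grown-segment reading reproduces it with ~5% interior
overlap). Per-tile global phases are removed row-major against the
already-anchored canvas on the overlaps, then complex values are blended
with separable distance-to-edge (feather) weights normalised to one —
complex-domain blending avoids 2-pi seam artefacts.

Agreement between a tile-wise mosaic and a single whole-field
reconstruction is quantified as RMS of the piston-removed phase difference
over the whole-field phase dynamic range (1-99 percentile), the same
normalisation used for seam steps; the suite requires < 5% on a
band-limited phantom, and measures ~4%. Normalised by the mean-removed
phase RMS instead the figure is 10-20%: reconstructing a cropped tile
treats it as periodic, and the wrap mismatch at the crop boundary is
content no tile-wise method can recover (natively periodic phantoms
reconstruct to ~1.6% at every size tested). This boundary error, not
blending, dominates tile-versus-whole disagreement.

## Resolution metrics

The Siemens-star read-out samples 1-pixel annuli at 8x the spoke-pair
count, normalises to the robust (1-99%) image range, and demodulates at
the spoke frequency and its second harmonic (a phase image modulates at
the spoke frequency; a focused intensity image of a phase star shows
mostly edge contrast at twice it), taking the larger amplitude relative to
the ring mean as the contrast. Resolution is half the local full period
`2 pi r*/N` at the innermost radius from which contrast stays above
threshold out to the star's edge; the innermost measurable annulus is
where the pixel grid still carries the local period (~3 px), and reaching
it sets the detection-limit flag. The threshold is calibrated, not
arbitrary: `calibrate_star_threshold` low-passes a synthetic star at the
coherent cutoff `NA/lambda` and returns the contrast at the radius whose
half period equals `lambda/(2 NA)`, so the metric reproduces the analytic
value on the oracle by construction (calibrated value ~0.37-0.38; the
report stores it). The FWHM read-out interpolates half-maximum crossings
around a single peak with the baseline taken as the median of the profile
ends, flooring at one pixel.

Design formulas: lateral `0.61 lambda/NA` (1.41 um), axial
`lambda/NA^2` (10.1 um) at 533 nm, coherent-area width
`2 lambda h / w` (140 um at 530 nm for 250 um emitters), plate tilt
tolerance `atan(delta/(pitch * span))` (1.16 deg ~ 1 deg for 2 mm over
11 pitches).

## Problem sizes and what the tests show

The acceptance pipeline runs at production scale: one 110 um tile (275 raw
px, 1100 px reconstructed), 21 brightfield frames, 10-repeat noise
averaging, 30 EPRY epochs, refocus scans over +/-100 um. The unit and
property suites run on 51.2 um tiles (128 raw px) and smaller, with the
same optics, which keeps each reconstruction near a second; the
resolution-versus-defocus curve and the tiling round trip use these
reduced sizes as declared scaled-down stand-ins for whole-well processing.

Simulated resolutions (~0.64 um in focus, ~0.65 um refocused at
+/-30-50 um) sit well below the instrument's certified <= 1.26 um because
the simulation has no fabrication imperfection, finite LED extent,
spectral bandwidth or calibration error; the bound, the shape of the
defocus curve (flat plateau with refocusing; rapid loss beyond the native
+/-15 um without it) and the blind-estimate accuracy (+/-5 um) are the
reproducible claims. Pure defocus is exactly invertible here, so refocused
resolution does not degrade at +/-50 um the way the physical instrument's
does. Other known limitations: thin-sample (projection) approximation
throughout; no fluorescence photophysics; no sensor temperature or
power-line modelling; meniscus curvature is a free parameter rather than a
fitted physical model.
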