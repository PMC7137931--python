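# Methods

This note documents the models behind the simulator, the fixed numerical
recipes, the defaults and why they were chosen, and what the synthetic data
do and do not establish about real hardware.

## Coordinate and unit conventions

All physical quantities are micrometres unless suffixed otherwise.  Image
row 0 corresponds to minimum Y and column 0 to minimum X; a stage position
is the physical location of the field-of-view centre; stage +Z moves the
focal plane deeper into the specimen (larger specimen z).  Registration
shifts `(dy, dx)` are the displacement of the second image's content
relative to the first (`b(r, c) ≈ a(r − dy, c − dx)`); mosaic tile
positions are top-left corners in pixels and equal `stage position /
pixel_um`, so a tile at larger stage X sits further right on the canvas
while its *content* appears shifted left relative to the previous tile.
Axis positions live in `[0, 13000]` µm (the 13 mm travel of both stage
types); moves beyond a hard stop are clamped and flagged in the command
log rather than raised, matching physical behaviour.

## Virtual specimen

`make_nervenet_specimen` builds a 3-D intensity field emulating a
flat-mounted epithelium carrying a nerve net:

* **Geometry** — the filament pattern is the ridge set of a Voronoi
  diagram of `n_filaments` random cell centres (mirrored across the domain
  borders to close the diagram).  A polygonal mesh is both what the tissue
  looks like and, practically, guarantees that any tile-overlap strip of
  reasonable size contains registerable structure; an earlier random-walk
  design left featureless corridors that no registration could use.  Mesh
  strands are widened to a Gaussian cross-section of radius 1.5 µm.
* **Height surface** — the mesh sits on a smooth surface
  `h(x, y) = mid_z + tilt·(x, y) + Σ₄ (A/4)·cos·cos` with four random
  low-order cosine terms of amplitude `A` (default: a quarter of the Z
  extent).  This makes the in-focus plane drift across XY, which is what
  forces Z-stacking and inter-tile Z-correction.  The `tilt` parameter
  gives a controlled linear focus drift for correction experiments; the
  surface is analytic, so tests can compare achieved focal planes against
  exact ground truth.
* **Intensities** — background 50 AU, filament peak 1000 AU, spread across
  Z planes with a Gaussian of σ = max(radius, pitch_z/2) about the surface.
  Voxel pitch defaults: 1 µm XY, 2 µm Z.

## Virtual camera (`OpticsModel`, `render_frame`)

Frames are rendered per volume plane: the plane is bilinearly resampled
onto the camera grid (pixel size 0.386 µm at the default 20× NA 0.5
configuration, 256 px square FOV), blurred with a Gaussian whose σ grows
linearly with defocus distance (`defocus_blur_um_per_um`, default
0.4 µm of σ per µm of defocus), and the planes are summed.  The blur is a
deliberate simplification: it preserves exactly the properties the
scanning logic depends on (focus-score maximum at the true focal plane,
monotone decay with |defocus|, energy conservation) without diffraction
PSF physics, which is out of scope.  The blur is applied in the Fourier
domain on a half-FOV-padded resample (padding uses real neighbouring
specimen content), which conserves the plane mean exactly and lets a
Z-stack reuse one set of plane FFTs — only σ changes between frames of a
stack.

Vignetting is a radial quadratic falloff reaching `vignette_strength` at
the corners (the paraxial limit of a cosine-fourth law); the default 5 %
reflects illumination that is nearly but not perfectly uniform.  Noise is
Poisson photon noise at `photon_scale` = 0.4 photons per intensity unit
(≈400 photons, SNR ≈ 20, on bright filaments) plus Gaussian read noise of
2 DN, then quantization to 16-bit (machine-vision c-mount cameras; depth
configurable to 8-bit).  A FOV entirely outside the specimen raises
instead of returning a black frame, so scan-planning bugs surface.

## Actuator and stage models

* **Stepper** — deterministic: 500 µm per micrometer revolution over 200
  full steps, microstepped 16× → 2.5 µm per full step, 156.25 nm per
  microstep; an optional fixed `coupling_error_frac` emulates the
  systematic discrepancy a misaligned 3-D-printed coupling produces.
* **Piezo** — per actuation, displacement
  `units · mean(direction) · (1 + U(−v, +v))` with `v = 0.20`: the
  distribution is uniform because only the ±20 % bound is characterized,
  and truncation makes the bound hard.  The directional mean implements
  the observed up/down asymmetry as a divisor on downward travel
  (`asymmetry_ratio` default 1.15 — the effect is reported qualitatively,
  so the ratio is a configurable model choice).  The nominal step is
  0.02 µm (the actuators' typical 20 nm step); because real per-unit
  travel depends on load and drive settings, the model treats it as a
  per-configuration calibrated constant rather than a function of
  `load_g`, exactly as the hardware is recalibrated per load in practice.
* **`move_to`** — open loop: per-axis command units are the rounded ratio
  of the remaining distance to the calibrated µm-per-unit (direction
  specific).  Without an explicit calibration table the model's own
  directional mean is used — a perfectly calibrated move — so residual
  error is quantization (stepper) or the bounded variability (piezo).
* **Settle** — residual displacement after a move is a damped sinusoid
  `A·e^(−t/τ)·cos(2πft)`; acquisition waits a configured settle time and
  flags the tile if the envelope is still above threshold.  Amplitudes and
  time constants are qualitative defaults; reproducing measured
  millisecond settle values is explicitly not attempted.

## Scan planning and execution

Serpentine traversal: row 0 in +X, direction alternating per row, so
consecutive tiles never differ in both axes (minimal row-major path).
Overlap is defined per axis as the shared fraction of the FOV,
`pitch = fov·(1 − overlap)`; the working values are 25 % (X) and 30 % (Y)
for the piezo stage at 20× and 10 % for the stepper stage.  Gcode output
is absolute-positioning mm (`G21`/`G90` preamble, one `G0` per tile,
4 decimals = 0.1 µm round-trip precision).

The autofocus score is the variance of the Sobel gradient magnitude
normalized by its squared mean (Tenengrad family): offset- and
scale-invariant, zero on constant frames, maximal at the true focal plane
on noise-free renders.  The metric sits behind a registry
(`FOCUS_METRICS`) so alternatives can be swapped.  Best-focus ties break
toward the lower plane index.  Z-correction recentres the previous tile's
best-focus plane: increment `(best − (n_z−1)/2)·dz`, accumulated across
tiles because focus drift on a sloped specimen is cumulative; a
featureless tile (no usable focus signal) contributes zero with a warning
and the running offset carries over.  Whether the correction should target
the stack middle or the first in-focus plane is an open choice; middle
recentring is implemented because it maximizes the margin to both stack
ends.  Mid-scan failures still write the manifest with completed tiles and
a failure marker, so scans are resumable.

## Registration and stitching

One registration engine serves stitching, displacement measurement and
drift tracking:

* **Phase correlation** (`phase_correlate`) — Hann-windowed,
  mean-subtracted, normalized cross-power spectrum, peak searched within a
  configurable radius of an expected shift, separable quadratic sub-pixel
  refinement.  Used directly for displacement/drift (shifts ≪ image size)
  and for the sub-pixel stage of tile registration.
* **Sliding masked NCC** (`masked_ncc_shift`) — for locating the integer
  offset between adjacent tiles.  With ±20 % open-loop step error the
  offset between two tiles can deviate from plan by an amount rivalling
  the overlap width itself; a phase correlation restricted to the nominal
  overlap strip cannot represent such displacements (and zero-padded phase
  correlation dilutes the peak into noise).  The masked formulation
  computes, via FFTs of the images and their support masks, the exact
  Pearson correlation of the *actual* overlap at every candidate integer
  displacement, searched near the plan offset and restricted to candidate
  overlaps of at least 30 % of the nominal overlap area (tiny overlaps of
  smooth content correlate spuriously well).
* **Confidence and fallback** — an edge's confidence is the Pearson
  correlation of the integer-aligned overlap; below `min_confidence`
  (default 0.10) the plan offset is used and the edge flagged.  The final
  sub-pixel estimate comes from phase correlation of the aligned overlap;
  when the true offset is an integer the aligned crops are pixel-identical
  and the estimate is exact.
* **Global placement** — positions minimize the confidence-weighted squared
  disagreement with all pairwise offsets, anchor tile fixed; three
  iteratively reweighted refits down-weight edges with large residuals so
  a corrupted estimate among redundant grid edges is absorbed.
* **Composition** — linear feather blending (weight ramp of `blend_width`
  px from each tile border, weighted average in overlaps); placement is
  rounded to whole pixels — quantized camera data are not resampled.
  Zero blend width degenerates to last-writer-wins.  No intensity
  harmonization or non-rigid correction is attempted.

Under these choices a simulated 5×4 piezo scan with the default ±20 % step
error stitches to under 2 px RMS position error against the simulated
ground truth (the test fixes the seed; across other seeds the RMS varies
roughly 0.8–1.9 px).

## QC mathematics

* **USAF / diffraction** — exact closed forms; lp/mm is reported rounded
  to the nearest integer.  Note one documented inconsistency: group 7
  element 6 gives 228 lp/mm, whose line-pair spacing by the same formula
  is 1000/228 = 4.39 µm (2.19 µm line width); a sometimes-quoted 1.1 µm
  spacing for this element is inconsistent with the defining formulas, so
  the package reports the formula values.
* **Slant-edge MTF** — fixed recipe: orientation detection (transpose
  near-horizontal edges), per-row derivative-centroid edge location,
  linear fit for the edge angle (accepted 2–15° off axis), projection of
  every pixel onto the edge normal, binning into a 4×-oversampled ESF
  (empty bins interpolated), finite-difference LSF, Hamming window centred
  on the LSF, discrete Fourier magnitude, correction for the
  finite-difference derivative and bin-averaging transfer functions,
  normalization to 1 at DC, frequencies reported to 0.5 cycles/pixel.
  Against analytic oracles the estimator matches |sinc(f)| for an ideal
  edge within 2 % and the Gaussian-blur MTF `exp(−2π²σ²f²)·sinc` within
  3 % (absolute, and relative where the oracle exceeds 0.1) up to
  0.4 cycles/pixel.
* **Displacement / drift** — sub-pixel registration shift × pixel size,
  with low-confidence results flagged rather than trusted; drift tables
  register every frame against frame 0 and report the maximum per-axis
  excursion.
* **Step calibration** — per (axis, direction, step size): mean and, when
  n ≥ 2 *and* the repeats were individually resolvable, SD.  The
  µm-per-unit slope is least squares through the origin (zero command =
  zero displacement is physical) weighted by 1/s²: actuator error is
  multiplicative, so the per-unit ratios d/s are iid and their mean is the
  minimum-variance origin-forced estimator; an unweighted fit understates
  the slope's standard error under this error structure.  Parameter
  recovery on simulated actuators at n = 15 per condition falls within
  2 standard errors.
* **Illumination uniformity** — mild Gaussian smoothing (1/64 of the image
  size — a broad kernel would drag the corner estimate inward), corner
  pixels vs a central patch, plus the coefficient of variation; both are
  scale invariant.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic data
generated at call time.  Representative sizes, chosen to exercise the full
pipeline at desk scale: the bookkeeping scan is the full 10×5 grid with
20-plane stacks at 256 px tiles; the Z-correction experiment uses the same
50-tile grid at 96 px tiles with 7-plane stacks on a 0.06 µm/µm tilted
specimen; the stitching experiment uses a 5×4 grid at 128 px tiles; piezo
statistics use 1000 draws; calibration uses the measured protocol of 15
repeats × step sizes {20, 50, 250, 500, 1000} per direction.  Every random
component takes an explicit seed (`derive_seed(global, role)`, sha256,
< 2³¹) and reruns are bit-identical.

## What the simulation does and does not show

Passing tests establish that the *logic* is correct under the stated error
models: serpentine bookkeeping, focus scoring and correction, registration
and placement, and the QC formulas all behave as specified when the camera
and stage behave as modelled.  They do not validate the models themselves
against hardware: there is no diffraction-accurate PSF, no spectral or
oblique-illumination model, no thermal drift source, no acoustic/electrical
actuator physics, and the settle dynamics are qualitative.  Measured
hardware figures that depend on those physics — per-FOV acquisition times,
millisecond settle durations, a specific stepper coupling discrepancy —
are deliberately not reproduced.  The piezo step distribution is uniform
within the published bound; if the real distribution is heavier-tailed in
the interior, calibration SDs would differ while all bound-based results
would stand.
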