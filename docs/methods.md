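# Methods

## Physical model

A vessel is modelled as a hollow circular cylinder of a homogeneous,
isotropic, nearly incompressible elastic solid in vacuum (traction-free
inner and outer walls).  Its guided waves are described by displacement
potentials — one compressional potential and two shear potentials —
each a Bessel-type radial function times a circumferential harmonic
`cos/sin(nθ)` and an axial harmonic `cos(ωt + ξz)`.  Imposing zero
radial, azimuthal and axial traction on both walls yields a homogeneous
linear system; phase velocities are the values `v = ω/ξ` at which its
determinant vanishes.  For the axisymmetric family (`n = 0`) the system
decouples and the longitudinal L(0,1) mode is the root of a 4×4 block;
the flexural F(1,1) mode (`n = 1`) requires the full 6×6 determinant.
The boundary-matrix entries were derived symbolically from the potential
formulation (with second radial derivatives eliminated through the
Bessel differential equation) and the hand-coded rows are pinned against
frozen values of that independent symbolic derivation in the test suite.

Assumptions inherited from the model, and therefore from everything the
package computes with it: the tube is empty (no blood) and unembedded
(no perivascular tissue).  Both omissions stiffen the prediction — real
vessels carry fluid mass loading and radiate into surrounding tissue, so
measured velocities in vivo sit below the computed curves.  The model
also assumes small-amplitude linear elasticity and a perfectly circular,
uniform cross section.

## Numerical solution of the characteristic equation

* **Radial basis by regime.**  Below the bulk shear speed (the usual
  regime for both modes at vessel scales) the squared radial wavenumbers
  are negative and the radial functions are modified Bessel functions
  I/K; above it they are ordinary J/Y.  The basis is selected by the
  sign of each squared wavenumber, keeping the determinant real in every
  regime.  A root search never crosses the bulk shear speed, where the
  basis (and the determinant's sign convention) switches.  An optional
  complex-argument assembly with ordinary Bessel functions provides an
  independent consistency check: both constructions vanish at the same
  velocities.
* **Conditioning.**  With `c_L / c_T ≈ 4300` and radii of tens of
  micrometres, raw boundary matrices span hundreds of orders of
  magnitude; every column is scaled to unit maximum magnitude before the
  determinant (a positive per-column factor, so root locations and sign
  changes are unaffected).  Even normalized, the determinant's absolute
  scale is meaningless; all convergence criteria are therefore relative.
* **Root finding.**  At each frequency the root is bracketed by a
  sign-change scan over a geometric velocity grid (within ×1.5 of the
  continuation guess; a wider ×2.5 scan seeds the first frequency from
  the closed-form asymptote) and polished by Mueller's three-point
  quadratic iteration.  Mueller's stopping rule uses the function value
  relative to the starting scale, or a relative step below `tol`;
  degenerate (collinear) parabolas fall back to a secant step, and real
  brackets force real iterates.  A point is flagged non-converged when
  the polished residual exceeds 10⁻³ of the bracket-edge determinant
  scale; losing the bracket entirely (no sign change within ±50% of the
  continuation guess) is an error, not a silent gap.
* **Verification.**  The solver is validated against physics it does not
  contain: the F(1,1) branch approaches the Euler–Bernoulli flexural
  limit `v = (ω² E I / ρ A)^{1/4}` with the thick-ring radius of
  gyration `I/A = (a² + b²)/4` to within ~1% at low frequency for both
  artery-scale geometries and for a steel pipe, and L(0,1) approaches
  the bar velocity `sqrt(E/ρ)` (→ `sqrt(3) c_T` for an incompressible
  wall).

### Two flexural asymptotes

The package ships two low-frequency approximations for F(1,1).
`v_fpw_lowfreq` is the compact plate-analogy form
`sqrt(π f d c_T / sqrt(3))` — the antisymmetric-Lamb-wave asymptote of a
plate of thickness `d/2` — which is the form commonly quoted at these
scales and the default dispersive law of the synthetic generator.
`v_fpw_beam` is the Euler–Bernoulli thick-ring limit, which is the true
asymptote of the exact branch.  The two share the `sqrt(f·d)` scaling
but differ by a constant factor of about 1.3 for these geometries (the
plate analogy underestimates).  Asymptote-consistency checks of the
numeric solver therefore use the beam form; the plate form is retained
for comparisons with published velocity anchors and as a convenient
closed-form synthesis law.  A regression test freezes the ≈1.3 offset so
the discrepancy is documented rather than hidden.

## Passive spectroscopy

The analysis axis is the curvilinear abscissa along the vessel.  Each
trace is Fourier-transformed over the full record (rectangular window)
and, at each frequency, a phase-only spatial correlation is formed:
`C(f, r) = < cos(arg φ̂_s − arg φ̂_{s+r}) >_s`, averaged over all
position pairs separated by `r` that lie on the vessel (pairs leaving
the domain are simply dropped, so lag coverage shrinks toward the
aperture edges).  Discarding the modulus whitens the spectrum and makes
the correlation exactly invariant to any positive amplitude envelope —
for a single unidirectional plane wave `C(r) = cos(2πr/λ)` to machine
precision, which is the module's primary correctness anchor and a unit
test.

The wavelength is a one-parameter nonlinear least-squares fit of
`cos(2πr/λ)` on the central peak: the window runs between the first
negative-going zero crossings on either side of `r = 0` when visible,
and otherwise covers the whole aperture — the regime of a carotid
symmetric wave, whose ~45 cm wavelength must be extrapolated from the
curvature of the central lobe inside a 4 cm aperture.  The initial guess
is four times the zero-crossing lag (a quarter period), or eight times
the aperture when no crossing is visible.  A flat correlation (single
position, zero signal, or a spatially uniform field) raises an explicit
fit error instead of returning an unbounded wavelength, and failed
frequencies are flagged in the dispersion curve rather than dropped.
Phase velocity is assembled as `v = λf` exactly, with
`σ_v = f·σ_λ` (harmonics are bin-aligned, so the frequency error is
negligible).  Analysis frequencies are the local maxima of the mean
magnitude spectrum above a relative prominence threshold.  For broadband
traces a polychromatic focal spot averages the monochromatic spots over
a band, weighted by the mean spectral magnitude, and a central frequency
is estimated from the first post-zero-crossing maximum of the
position-averaged temporal autocorrelation (with parabolic lag
refinement).

## Time of flight

The independent cross-check correlates raw traces: for each spatial
separation, the time cross-correlation of every valid trace pair
(zero-mean, unit-energy per trace, so bright segments do not dominate)
is averaged over source positions.  A travelling wave produces a ridge
along `Δx = v·Δt`.  The ridge is tracked by continuity outward from the
origin — at each time lag the local correlation maximum nearest the
previously tracked spatial lag, refined by three-point parabolic
interpolation — because a periodic cardiac source makes the correlation
recur at multiples of its period with no travel, and a global argmax
would lock onto those aliases.  Tracking stops when no local maximum
exceeds the correlation threshold (default 0.25) or the tracked peak
jumps back toward the origin (the ridge left the aperture).  The
velocity is a weighted least-squares line through the origin (a wave
passes `Δx = 0` at `Δt = 0` by construction) with bisquare reweighting
against outliers; its uncertainty comes from the weighted residuals.
For a dispersive field the result is a band-average velocity, reported
as such; on the default retinal synthesis it falls between the phase
velocities at the band edges.

Directional filtering zeroes the two quadrants of the 2-D Fourier plane
whose space–time frequency signs correspond to the rejected direction
(plus the shared zero-frequency axes).  It is only meaningful when the
wavelength is resolved within the aperture: when most of a channel's
energy sits in the zero-spatial-frequency bins the filter destroys the
signal and biases the ridge slope low.  The pipeline therefore applies
it adaptively — only when the filtered field retains at least 90% of the
channel variance (a unidirectional resolvable wave passes almost
losslessly); otherwise the unfiltered field is used and the decision is
recorded as a run warning.  In the default carotid scenario, where both
wavelengths exceed the 4 cm aperture and no reflections are synthesized,
the filter is skipped by this rule.

## Segmentation and cross sections

The vessel is segmented on the time-averaged image: Sobel gradient
magnitude, thresholded (Otsu's threshold by default; the threshold and a
seed point are exposed because neither has a canonical value), connected
edge component selected by seed or size.  The centerline — the midline
between the paired opposing edges — is computed as the skeleton of the
filled edge contour, ordered end-to-end by the longest geodesic through
the skeleton graph, smoothed with a 5-point moving average, and
resampled to a uniform arc step of one pixel pitch by linear
interpolation.  The local lumen width comes from the distance transform.
Cross-section traces average the intensity along the normal to the local
tangent (centered differences) over ±half the median lumen width (step
half a pixel, bilinear interpolation); a per-trace linear detrend
removes slow photometric drift, which carries no wave information.
Averaging across the cross section cancels any contribution that is
equal and opposite on the two halves of the profile — the mechanism that
suppresses axisymmetric intensity fluctuations and leaves the flexural
wave dominant in the traces (verified on constructed profiles).

## Mode separation (two-wall data)

With displacements measured along the imaging beam, expansion moves the
two walls oppositely and flexion moves them together, so
`u_a = (u_top + u_bottom)/2` and `u_s = (u_top − u_bottom)/2`.  The
factor ½ makes each field a per-mode displacement amplitude; only
wavelengths matter downstream.  The generator models imaging-plane
misalignment as an amplitude factor on the antisymmetric channel, and
the estimators ignore it — a projection changes amplitude, not
wavelength.  Snapshot classification compares spatial L2 norms with a
dominance ratio of 2.

## Synthetic data: what it does and does not emulate

The generator synthesizes waves exactly in the frequency domain as sums
of travelling cosines — no PDE solve — matching the analysis's own
superposition model.  The cardiac source is a 1.5 Hz fundamental with a
configurable number of harmonics; the harmonic amplitude profile is not
constrained by any physiological measurement, so it is a free scenario
parameter (retinal default: geometric decay toward 0.3 relative
amplitude over five harmonics; carotid default: a Gaussian profile
peaked at the fifth harmonic, 7.5 Hz, placing the spectral energy in the
6–19 Hz band where carotid wave spectra concentrate).  Harmonic phases
are drawn from the scenario seed.  Record durations place an integer
number of cycles of every harmonic in the window, so spectral peaks are
bin-aligned and rectangular-window FFTs are leak-free; non-integer
durations can be configured for leakage-robustness experiments.

* **Retinal scenario** (defaults): 38 Hz frame rate, 8 s record, 5.3 mm
  field of view on a 512×512 grid (10.35 µm pitch), a gently curved
  bright vessel of Gaussian transverse profile (50 µm scale, matching a
  100 µm lumen), an antisymmetric mode following the plate-analogy
  flexural law for d = 100 µm and c_T = 0.35 m/s (9.8–21.8 mm/s across
  the five harmonics), intensity fluctuations riding multiplicatively on
  the vessel profile, and additive Gaussian noise at one tenth of the
  wave's RMS (SNR 10).
* **Carotid scenario** (defaults): 500 Hz frame rate, 2 s record, 64
  positions across a 4 cm aperture, a 3.4 m/s non-dispersive symmetric
  mode (150 µm amplitude) and a 0.5 m/s antisymmetric mode (100 µm),
  independent per-wall Gaussian noise of 5 µm — the order of ultrasonic
  phase-tracking precision.

Not emulated: laser speckle and holographic reconstruction artefacts,
ultrasound RF/IQ physics and beamforming, blood-flow dynamics, wave
attenuation, reflections, vessel taper or branching, and non-Gaussian
noise.  Passing recovery tests therefore demonstrate that the analysis
chain is internally consistent and unbiased under its own model
assumptions at realistic sampling and noise — not that it is robust to
every artefact of real recordings.

## Conventions and degenerate inputs

Image coordinates are (row, col), 0-based; the abscissa is in metres and
all file interfaces are SI (human-readable reports convert to mm/s at
retinal scale and m/s at carotid scale, with explicit unit strings).
The sign of a time-of-flight velocity follows the centerline
orientation, which is arbitrary; pipelines report magnitudes.  Reversing
the centerline flips the abscissa but leaves wavelengths unchanged
(tested).  Degenerate inputs fail loudly: blank images, vessels shorter
than 16 cross sections, records shorter than 16 samples, harmonics at or
above Nyquist, flat correlations, absent ridges, empty bands, DC-only
autocorrelations.

## Known limitations

* The empty, unembedded tube model overestimates in vivo velocities;
  fluid-loaded and embedded corrections are out of scope.
* Only the first branches L(0,1) and F(1,1) are computed; torsional
  modes and higher branches are not tracked.
* The wavelength fit model is a pure cosine; under noise the measured
  correlation is an attenuated cosine, which the one-parameter fit
  absorbs as a small (percent-level at SNR 10) wavelength bias.
* Curvature of the vessel is handled by the curvilinear parametrization,
  but strongly tortuous vessels with self-approaching segments would
  confuse the nearest-centerline-point rendering and the skeleton
  ordering.
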