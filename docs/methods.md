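# Methods

This note documents the models, the numerical choices, and the synthetic
data conditions behind `orchid-sonos`, in enough detail to judge what the
passing tests do — and do not — establish about real measurements.

## Digital offset binning

A spatial offset is a set of detector pixels at a chosen Euclidean
distance from the excitation pixel. Pixels are treated as points at their
centres (no partial-pixel weighting), matching a strictly binary mask.
Membership uses the half-open rule `Ir <= r < Or`; the rule is a
convention (the choice is invisible except for pixels landing exactly on
a radius) adopted because it makes contiguous annuli a true partition:
summing width-1 annuli over `r < R` equals the single disk sum exactly,
at integer precision. The mask centre defaults to the geometric centre
`((n-1)/2, (n-1)/2)`, fractional on even-sized detectors so that masks
are symmetric; the excitation axis is assumed to map there. Annuli of
width 1 px are the default (finest offset resolution); wider annuli
trade depth resolution for signal, and both plain annuli and cumulative
disks `(0, R_k)` are provided because published radius studies are
ambiguous about which is meant: a background that grows linearly with
radius indicates annuli, while a target that "levels off" indicates
cumulative disks. The ambiguity is surfaced as a mode switch rather than
resolved.

`bin_frame` uses a single digitize-and-accumulate pass; `binning_oracle`
is a deliberately naive per-pixel double loop kept only as an
independent cross-check in tests (frames ≤ 128×128).

## Forward model of the layered gel phantom

The simulator produces the detector frames a real instrument would
record from an agarose phantom with embedded narrow-band emitters. It is
closed-form diffusion theory, chosen over Monte-Carlo transport because
it is fast, deterministic, and reproduces the one physical fact the
method exploits — depth maps to radial broadening at the surface.

* **Excitation.** The focused spot (~µm in a real microscope) is far
  smaller than any phantom feature, so the beam is treated as a pencil:
  only the emitter column under the excitation axis is excited. The
  lateral overlap between the Gaussian beam footprint (σ = 0.05 mm
  default) and an emitter box is computed analytically (erf products),
  which keeps the response smooth in stage position. On-axis fluence
  decays as Beer–Lambert with the effective attenuation coefficient
  `mu_eff = sqrt(3 mu_a (mu_a + mu_s'))`, integrated piecewise over
  layers. Lateral diffusion of excitation light is neglected; for very
  deep layers this underestimates the excited volume, a known
  idealisation.
* **Emission escape.** A point emitter at depth z illuminates the
  surface with the dipole diffusion-reflectance kernel (source plus
  image source across the extrapolated boundary, `z_b = 2AD`,
  `D = 1/(3(mu_a+mu_s'))`). `A = 1` (index-matched) by default; the
  Groenhuis approximation `boundary_mismatch_A(n)` is available for
  mismatched boundaries. The kernel integrates over the plane to the
  escape probability (verified ≤ 1 in tests), peaks at zero offset, and
  its radial second moment grows strictly with depth — the quantitative
  form of the depth→offset mapping.
* **Voxelisation.** Emitter boxes are sliced in depth at 0.25 mm
  (≤ 1/8 of the smallest 2 mm phantom feature; configurable).
* **Autofluorescence.** Each layer carries an ascending-coefficient
  polynomial in wavelength (validated nonnegative over the scan range)
  for the broad gel/tissue background the removal stage must strip,
  weighted by layer thickness and mid-layer fluence, with an optional
  exponential radial envelope around the excitation axis
  (`af_envelope_scale_mm`, default 25 mm ≫ the detector field of view,
  or None for laterally uniform).
* **Detector and noise.** 512×512 pixels of 12 µm at unit magnification
  by default (one pixel = 12 µm at the sample plane; the pixel↔mm scale
  is a config knob, not a constant, since the true objective
  magnification of such systems varies). Expected counts are
  `dark_offset + gain·exposure·photons`; with noise on, Poisson shot
  noise on the photon term, then Gaussian read noise, then clipping at
  zero. Per-frame random streams are spawned from one seed, so a scan is
  bit-reproducible and independent of rendering order.

### What the simulator does not emulate

Real tissue heterogeneity, irregular layer boundaries, wavelength
dependence of the optical properties, tunable-filter transmission
ripple, polarisation, and time-domain effects are all out of scope.
Passing tests therefore demonstrate the correctness and internal
consistency of the processing chain and the qualitative physics of
depth–offset coupling; they do not validate quantitative depth
calibration on real samples — a calibration fit on a simple gel phantom
transfers poorly to complex media, and the depth estimator below
inherits that caveat.

## Study phantoms (built-in fixtures)

The four fixtures reproduce the published demonstration geometries:
a 5×5 mm (2 mm thick) GNS-DTTC cube sandwiched between 5 mm gel slabs;
two stacked 3 mm layers (GNS-DTTC over GNS-IR780) probed at one spot
over 800–880 nm; two embedded 2 mm dye layers (GNS-IR780 over GNS-DTTC)
inside 2 mm gel layers; and 900 nm quantum-dot lettering ("NANO", 5×7
cell glyphs, 1.4 mm cells) buried 1 mm deep, scanned 4 cm × 4 cm at 4 mm
increments and 100 ms exposure. Gel optical properties are never
reported for such phantoms, so the defaults `mu_a = 0.01/mm`,
`mu_s' = 1.0/mm`, `n = 1.33` are explicit placeholders (flagged in the
config schema), typical of low-scattering agarose in the near-IR.
Reference spectra are documented synthetic line sets: GNS-DTTC at
497 cm⁻¹ (the published marker band; ≈ 816.9 nm at 785 nm excitation)
plus a secondary band at 1125 cm⁻¹; GNS-IR780 at 905 cm⁻¹ (≈ 845.0 nm)
plus 1205 cm⁻¹; line FWHM 2 nm (≈ 15–20 cm⁻¹, typical SERS band width);
quantum dots as a single 30 nm-wide line at 900 nm. Concentrations
(10⁷ arb/mm³ for dye gels, 10⁸ for the bright QD lettering) and the
per-layer autofluorescence scale (3×10⁴) were set once to give realistic
frame statistics — hundreds of signal counts and tens of background
counts per pixel over a 100-count dark offset at 1 s exposure.

## Spectral processing

Spectra are kept on the instrument's nm axis (the tunable filter scans
wavelength); cm⁻¹ is an exact bijective view through the excitation
line. Background removal is an iterative modified polynomial fit: fit a
polynomial (default order 5, max 100 iterations), clip every point above
the fit plus the current residual deviation, repeat until the deviation
stabilises (tolerance 10⁻⁶ of the input range — the convergence rule is
this module's own choice, as the cited family of methods does not fix
one). Clipping at `fit + dev` rather than at the fit avoids the downward
ratchet of the plain clipped iteration; a final few refit passes on
background-only samples shed the baseline lift exerted by broad
Lorentzian wings. Verified fidelity: a pure polynomial background is
removed to ~10⁻¹⁴ of its range, and a 5 nm-FWHM Lorentzian riding on a
cubic background is recovered to within 3–5% of its amplitude.

Peak measurement is a windowed maximum (default window 4 nm) rather than
a line-shape fit — consistent with identifying known marker bands
without asserting a shape model.

## Analysis readouts

* **Ratiometric curve.** Per annulus, the ratio of the deep dye's peak
  to the shallow dye's peak (deep in the numerator, so depth enrichment
  reads as growth). Annuli whose shallow peak falls below a floor
  (default 10 counts) are flagged undefined, never silently dropped. In
  noise-free two-layer simulations the curve is nondecreasing across all
  annuli for 2, 3 and 5 mm layers — the method's central claim.
* **Signal versus radius.** Target and background bin sums at one
  wavelength for two stage positions, with difference and SNR. The SNR
  definition is not standardised in the literature this follows; the
  shot-noise form `(T − B)/sqrt(T + B)` is used, with a
  background-spread alternative available when several background
  positions are supplied. For the 1 mm-deep lettering at 12 µm/px the
  difference curve peaks at an interior radius (~92 px with default
  optics, consistent in order of magnitude with published ~75 px
  optima); in cumulative mode the SNR peaks and then declines as signal
  spreads over ever more pixels.
* **Depth estimation.** A least-squares fit of `amplitude × (escape-
  kernel annulus mass at depth z)` to a measured width-1 annulus
  profile, amplitude profiled out (scale invariant), coarse geometric
  z-grid (120 points, 0.05–10 mm) then bounded scalar refinement
  (xatol 10⁻⁶ mm); percentile bootstrap over annuli for the interval.
  It assumes a single dominant emitter depth and known bulk optics — a
  strong idealisation stated up front. Self-consistency recovers depth
  to < 10⁻³ mm noise-free; with Poisson noise at 10⁵ total counts the
  median absolute relative error is ~1% for depths 0.5–4 mm. Flat
  profiles are flagged non-identifiable instead of returning a number.

## Reproducibility and file formats

Scan stacks are stored as HDF5 (`/frames[pos, lambda, row, col]`,
float32, with stage/wavelength axis datasets) or multi-page float32 TIFF
with per-page JSON metadata; both read back into identical cubes, so
externally acquired stacks can enter the pipeline at the frame boundary.
All writers disable file timestamps, making outputs byte-identical under
a fixed config and seed; each pipeline run emits a provenance record
(config hash, seed, package version). Problem sizes in the test suite
and acceptance script are scaled for a desk run — reduced wavelength
grids and two-position scans where the full published grids (e.g.
11×11×11 frames of 512²) would add nothing to the property under test.

## Known limitations

Diffusion theory is inaccurate within ~1/μ_s′ of the source and surface,
so very shallow emitters are modelled only approximately; excitation-side
lateral diffusion is neglected; the depth estimator is single-depth;
spectral unmixing of overlapping emitters is out of scope; and all
quantitative depth claims are conditional on the placeholder optical
properties.
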