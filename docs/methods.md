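# Methods

This note documents the models, numerical choices and limitations of
`kvbeam` at the level a physicist would want before trusting its output.

## Source model

The tube is represented by an effective point source at the origin; the
applicator defines a circular aperture of the stated diameter in the plane
z = SSD (+z into the phantom, x = inline/anode–cathode, y = crossline, all
positions in cm). Primary and scattered radiation are both taken to
originate from this point, so penumbra arises purely from the back-projected
fluence distribution; the physical focal spot (millimeter scale) is not
modeled as an extended source.

The planar fluence is separable, `phi(x,y,E) = X(x) Y(y) U(x,E) phi0`.
`X` and `Y` are recovered from relative in-air dose scans by dividing out
the spectral response (the air-kerma integral of the local spectrum); with a
spatially uniform spectrum the correction cancels exactly and the fluence
map equals the normalized scan. `U` varies only along x — the heel-effect
direction — and is represented by spectra at discrete inline stations
(every 3 cm, the granularity of off-axis HVL measurements) with
nearest-neighbor lookup between stations; linear spectral interpolation is
deliberately not invented. `phi0` is fixed at 1: every quantity the package
reports is relative.

Between fluence samples the map interpolates linearly; beyond the outermost
sample it falls linearly to zero over one sample spacing. This penumbra tail
is a documented knob, not a measurement: scans end near the aperture edge
and no tail model is implied by the data.

Emission sampling draws plane positions with density `X(x)Y(y)` over the
aperture disk by rejection with an adaptive batch size (envelope from a
512-point grid; hard cap of 1000 rounds, unreachable in practice), energy
from the station spectrum by inverse-CDF with uniform within-bin jitter
(clipped at the kVp), and direction through the drawn plane point.

## Spectrum model

The parametric tungsten-anode model is a Kramers photon-number continuum
`(kVp − E)/E` corrected for target self-filtration: electrons penetrate to
the Thomson–Whiddington depth `x(E) = (kVp² − E²)/(C·rho_W)` with
C = 1.0×10^6 keV² cm²/g, photons of energy E are produced uniformly along
that depth and escape along `depth/sin(anode angle)` (30° default). K
characteristic lines (57.98, 59.32, 67.24, 69.07 keV; intensity ratios
100 : 57.6 : 33.6 : 8.7 for Kα1 : Kα2 : Kβ1 : Kβ2, entered at the nearest
bin) appear above the 69.525 keV K edge with total yield
`0.06 · (kVp/E_K − 1)^1.67` relative to the continuum — all literature-range
constants, fixed, with the K-line scale being the model's single tunable.
Bins are 0.5 keV wide (HVL stable to < 0.01 mm under halving); filtration is
applied bin-wise as `exp(−Σ mu(E) t)`, which makes filtration exactly
compositional.

HVL is defined on *air kerma* (the quantity an ionization chamber responds
to), solved by Brent root-finding with |transmission − 0.5| < 1e-6 at the
returned thickness. Inherent-filtration tuning bisects an Al-equivalent
thickness in [0, 20] mm added to the fixed 0.8 mm Be window; HVL is strictly
monotone in that thickness, so convergence (to 0.01 mm Al in HVL) is
guaranteed within the bracket, and an unreachable target is reported with
the bracket endpoints. The measurement-to-model inversion clamps a measured
HVL below the bare-tube floor up to the floor — such a reading can only be
noise.

Accuracy: against the modeled unit's measured beam qualities from nominal
tube data alone, the model computes 3.98 vs 4.18 mm Al at 120 kVp (−4.8%),
12.48 vs 13.40 at 150 kVp (−6.9%), 1.94 vs 2.06 at 80 kVp (−5.7%), but
8.03 vs 7.14 at 140 kVp (+12.5%). The 140 kVp miss is structural: it
persists (+10.8%) with the K-line yield set to zero, and no value of that
yield improves 140 kVp without degrading 120/150 kVp, so the constants were
left at their literature values rather than fit per beam. Workflows that
matter tune to the *measured* HVL, which removes this model error wherever
the target is reachable.

Imported spectra (energy, fluence-per-keV samples) are rebinned by
integrating the trapezoid interpolant over each internal bin, conserving
total fluence to round-off; a single-row table is a monoenergetic line.

## HVL from transmission series

The three-point semilogarithmic method fits a quadratic in
(thickness, ln relative reading) through the three measured thicknesses
whose transmissions are nearest 50%, and returns the 50% crossing, which
must lie inside the bracketing interval. The quadratic is exact for a
single-exponential (monoenergetic) beam and second-order accurate under
hardening; on data generated from the package's own spectra it agrees with
the forward-model HVL to better than 0.05 mm Al for brackets within ±30% of
the true value — well inside the ±0.1 mm repeatability of the emulated
measurements. When four points straddle 50% symmetrically the set with two
points below 50% is preferred (hardening makes the semilog curve shallower
at depth); the alternative is selectable. Readings are assumed already
corrected for temperature/pressure and timer; chamber corrections are out of
scope. Non-monotone readings are rejected as measurement errors.

## Phantom

Voxel phantoms carry per-voxel material id and density; world coordinates
are voxel-center based, surface plane at z = SSD, arrays C-ordered with z
fastest. The native format is raw little-endian arrays plus a JSON sidecar
(dims, spacing, origin, materials); DICOM import is an adapter concern, not
a core dependency. The reference water phantom is 108 slices of 0.30 cm; at
full transverse resolution (512² × 0.081 cm) it has 28,311,552 voxels, and
the default dose-engine grid downsamples the transverse axes to 0.4 cm
(103²), which point-of-interest tallies do not resolve below anyway. The
stated 41.2 cm transverse extent and 512 × 0.081 cm = 41.47 cm are mutually
inconsistent by 0.7%; both constructions are supported and neither is
"corrected" to the other. HU mapping assigns material and density per
contiguous HU interval (optionally a linear density ramp); an uncovered HU
value is an error naming the offending voxel.

## Transport

Analog photon Monte Carlo under the kerma approximation, 1–160 keV:

- Free paths by optical-depth sampling (−ln ξ) accumulated along exact
  voxel-by-voxel ray traversal; per-voxel mu = (mu/rho)(E) · rho. Voxel
  indices use floor() so positions marginally outside the grid terminate
  correctly.
- Interaction channels drawn proportionally to the bundled partial cross
  sections. Photoelectric deposits the full photon energy locally
  (fluorescence below the tally resolution in water; W/Cu fluorescence
  irrelevant inside a water phantom). Incoherent scattering samples the
  Klein–Nishina distribution by Kahn's method and deposits the electron
  share `E − E'` locally. Coherent scattering redirects with the Thomson
  angular form `(1 + cos²θ)` without atomic form factors — a documented
  simplification with small effect on relative dose in water at these
  energies; it can be disabled by zeroing the coherent partial.
- Photons degraded below 5 keV (sub-millimeter range in water) are absorbed
  on the spot rather than rouletted, which keeps the per-history energy
  balance — deposited + escaped = launched — exact to floating-point
  round-off, and that identity is asserted in the tests.
- Scoring: `collision` (analog energy imparted in tally boxes) or
  `tracklength` (adds `E · (mu_en/rho)(E) · rho · L` per flight segment in
  the tally). Both have the same expectation by construction of the partial
  split; the track-length kerma estimator has far lower variance for small
  tallies and is used for point-of-interest dose. Tallies are axis-aligned
  boxes (default 0.4 × 0.4 × 0.3 cm³) centered on the requested points;
  "point" dose is the box average. Self-convergence studies score over a
  chamber-scale 3.5 × 3.5 × 0.6 cm³ central-axis volume: an analog
  estimator at a 0.05 cm³ box cannot reach the ~0.3% statistical precision
  that comparing half-million-history runs meaningfully requires.
- Uncertainty: history-by-history sums and sums of squares per tally;
  standard error of the per-history mean. Dose is reported per launched
  history divided by tally mass, so runs of different length are directly
  comparable.
- Reproducibility: emissions from numpy's counter-based Philox generator,
  in-kernel transport from an explicit-state PCG32 stream, both keyed by the
  run seed; identical inputs and seed give bit-identical results. The
  kernel is numba-compiled and single-threaded.

A deterministic narrow-beam primary kerma PDD
(`analysis.primary_kerma_pdd`: attenuation × inverse square, no scatter
buildup) serves as the fast comparator for spectrum-sensitivity questions —
e.g., two 120 kVp beams with different shapes but the same first HVL agree
to < 0.5% over 1–10 cm depth, the basis of the spectrum-pair equivalence
check, for which a 15% linear tilt emulates the scale of differences between
independent spectrum generators. It is not a dose engine for broad fields.

## Analysis conventions

PDDs are normalized to 100 at the extrapolated surface (least-squares
polynomial, default order 3 over the 5 shallowest points, evaluated at depth
0 — exact on polynomial data), because kV beams peak at or within a fraction
of a millimeter of the surface where chambers cannot measure; normalization
at the shallowest measured depth is a flag. Percent differences are signed
`100(a−b)/b` after linear interpolation of the reference onto the curve's
depths; summaries report both the signed range and the mean/SD of absolute
differences. Uncertainties combine in quadrature and are reported to one
decimal (2.1% setup ⊕ 0.3% reading = 2.1%). Reference-table comparison
refuses mismatched technique metadata (kVp, SSD, field) instead of silently
comparing different beams.

## Synthetic measurements

The fixtures emulate the commissioning campaign: a truth source with
station spectra tuned so HVL(x) rises linearly toward the anode side, inline
fluence reduced 5% per aperture radius on that side, flat-topped profiles
with a quadratic 10% droop outside 85% of the radius, in-air scans every
0.25–0.5 cm, and Al transmission series bracketing each station's HVL.
Reading noise is multiplicative Gaussian with SD 0.3% (the emulated
instruments' average reading uncertainty); only the magnitude is empirical,
the distribution shape is a modeling choice. Under these conditions the full
inversion recovers the in-air dose profile to < 1% RMS over the central 75%
of the aperture. Not emulated: chamber energy response, scatter into the
detector, setup drift — recovery tests certify the inversion pipeline, not
immunity to those systematics.

## Problem sizes

Default study sizes were chosen so every routine check runs interactively
on one core: 2–2.5×10^5 histories for depth-dose property checks,
5×10^5 / 1×10^6 for the self-convergence comparison, 10^5 draws for
distributional tests, and the 103 × 103 × 108 downsampled water grid for
transport. The full-resolution 512² grid is constructed (and counted) but
not transported by default.

## Known limitations

- The parametric spectrum model is accurate to roughly ±10% in HVL from
  nominal data (see above); HVL-tuned workflows are the intended use.
- No electron transport: invalid within ~0.1 mm of interfaces and for
  detectors thinner than the electron range.
- Coherent scattering lacks form factors; scatter angular distributions in
  high-Z media are approximate (high-Z media never appear in the shipped
  dose pathways).
- W and Pb mass energy-absorption values in the bundled tables are smoothed
  approximations (flagged in DATA_SOURCES.md), used only in invariants.
- Absolute dose (phi0 calibration, TG-61 formalism, backscatter factors) is
  out of scope; everything is relative.
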