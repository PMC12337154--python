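# Methods

`skullwave` quantifies how the skull degrades transcranial B-mode
imaging by decomposing the degradation into its two mechanisms — phase
aberration and reverberation clutter — with linked wave simulations.
This note records the model, the numerical choices, and the limits of
what the synthetic experiments can show.

## Wave model

The solver integrates the first-order pressure–velocity system

    rho dv/dt = -grad p
    kappa dp/dt = -div v,        kappa = 1/(rho c^2)

on a Virieux staggered grid (pressure at cell centers, velocity
components at face centers), leapfrog in time. Spatial derivatives are
4th-order staggered differences in the interior with 2nd-order end
rows; the divergence operator is constructed as the exact negative
transpose of the gradient, so the semi-discrete system conserves the
discrete energy ½ pᵀK⁻¹p + ½ v_{n-½}ᵀRv_{n+½} identically — the
rigid-box energy check measures pure time-integration and rounding
error (< 10⁻³ relative in practice). At 20 grid points per wavelength
the group arrival error over 40 mm is ≈ 0.1%, and the phase mismatch
between a fundamental and its second harmonic is small enough that
quasilinear harmonic growth follows perturbation theory to a few
percent over several centimeters; a 2nd-order scheme fails both.

Boundaries: split-field PML on the lateral and deep edges (20 cells by
default, cubic grading, ≈ −45 dB plane-wave return) and a rigid
boundary at the transducer plane, so that multiples bouncing between
the skull and the probe face — a genuine clutter path — are retained.

Absorption is a single dissipative term: pressure and velocity are
damped by exp(−α_np·c·Δt) per step, with α_np the Np/m conversion of
the map's dB·MHz⁻¹·cm⁻¹ value at the pulse center frequency. A plane
wave then decays per Beer–Lambert at that frequency (verified to < 2%
over 4 cm). Dispersion of the absorption law is deliberately not
modeled: the analyses depend on attenuation magnitude, not its
frequency law, and a single calibrated rate keeps the oracle testable.

Nonlinearity is the quadratic correction β = 1 + B/2A applied as a
pressure-dependent stiffness in the pressure update, giving the simple-
wave speed c(1 + βp/ρc²). It is off by default (clutter subtraction is
exact only in a linear system) and enabled for the harmonic-imaging
experiment. Shear waves and mode conversion are outside the model; at
the low incidence angles of deep-brain imaging their contribution is
small.

Transducer elements are line segments of grid nodes at depth 0:
transmit adds pressure (soft source, gain c·Δt/dx so the emitted peak
matches the requested amplitude under the rigid baffle, with a local
ρc² correction that makes the equivalent mass-source strength
medium-independent — the condition under which point-source
reciprocity holds discretely), receive averages pressure over the
element nodes. Default probe: 64 elements at the P4-1's 0.295 mm
pitch (an 18.9 mm aperture — the element count is reduced from the
clinical 96 so the aperture fits the scaled domains), 1.25 MHz for
point-target work and 2.5 MHz for lesion work; 2-cycle Gaussian
bursts at 0.3 MPa.

## Media

All four property grids (speed, density, absorption, B/A) share one
isotropic grid; depth 0 is the transducer face. Reference values:
soft tissue 1540 m/s, 1000 kg/m³, 0.3 dB·MHz⁻¹·cm⁻¹; cortical bone
3000 m/s, 1850 kg/m³; B/A 7.6 everywhere.

**CT conversion** segments bone by threshold and scales the segmented
scanner units linearly onto [1540, 3000] m/s and [1000, 1850] kg/m³;
the two-point air/water calibration line (1.225 / 997 kg/m³) converts
raw scanner units to density when references were scanned. Bone
absorption follows the porosity law α = α_min + (α_max−α_min)·√Φ,
Φ = (ρ_max−ρ)/(ρ_max−ρ_min): endpoint-exact and monotone; the exponent
½ is a package choice (the porosity–absorption literature fixes only
the monotone family).

**Synthetic skulls** stand in for CT-derived temporal-bone maps: a
water standoff (3 mm), outer/inner cortical tables (1.5 mm each) and a
diploe (3 mm) filled with a seeded, correlated porosity texture
(0.8 mm correlation, trabecular-separation scale), with rough
interfaces (0.15 mm). Two textures exist: `continuous` (what clinical
CT reports) and `trabecular` (a binary bone/marrow structure at 40%
pore fraction for microstructure-resolving slabs). Clinical-resolution
skulls carry 13 dB·MHz⁻¹·cm⁻¹ throughout the bone — the value that
compensates for the scattering of the unresolved microstructure —
while microstructure-resolving slabs carry the intrinsic 2.8.

**Speckle** is 15 single-pixel scatterers per wavelength-squared cell,
±0.5% density perturbations on a 1000 kg/m³ background with
0.5 dB·MHz⁻¹·cm⁻¹ absorption; anechoic lesions are 1 cm discs with the
scatterers removed and absorption zeroed. The resulting envelope
statistics are fully developed (point SNR ≈ 1.91 at matched depth).

**Point targets** are few-pixel discs whose *density* is raised by
65%·brightness (≈ 1 MRayl impedance mismatch at brightness 1). The
density-only realization keeps the echo amplitude proportional to
brightness while making the isovelocity transform exactly neutral in
skull-free scenes — the consistency anchor of the decomposition. A
`speed_contrast` knob exists for speed-scaled targets.

## The four-case decomposition

For one scene the package simulates: **homogeneous** (no skull),
**transcranial** (full scene), **clutter** (skull in a scatterer-free
background), and **isovelocity** (transcranial map with c = 1540 m/s
everywhere and density rescaled so ρ′c′ = ρc at every pixel, exact to
10⁻¹²). The **isoimpedance** case is the clutter recording subtracted
from the transcranial recording *on channel RF*, before beamforming
and envelope detection — envelope detection is nonlinear, and only
this ordering cancels the skull-only field exactly. All linked runs
share one time step (pinned to the scene-wide fastest medium), probe,
pulse and seeds; identical maps are simulated once and shared, keeping
degenerate cases bit-consistent.

Imaging is conventional: geometric transmit focusing, dynamic-receive
delay-and-sum with linear interpolation (virtual-source transmit
timing), no apodization, analytic-signal envelope along depth, 20·log10
compression to the image's own maximum or a linked reference. Lesion
scenes use a laterally swept multi-focus sequence whose strips tile the
image midway between foci.

## Readouts

* **PSF regions** — the isochronous volume is the bow-tie (aperture
  edge lines through the focus, one pulse-length waist) intersected
  with the ± one pulse-length two-way arrival band; earlier arrivals
  are the preceding region, later the trailing region; same-time pixels
  outside the bow-tie go to preceding/trailing by depth so the three
  masks partition the window. Region tables average in the dB domain
  (linear-domain averaging is an option).
* **RMS aberration** — per-element cross-correlation delays (parabolic
  sub-sample refinement, 0.3 correlation floor) between transcranial
  and homogeneous recordings, mean-removed, in ns.
* **CNR** — (mean_lesion − mean_bg)/std_bg on linear envelope; lesion
  interior eroded one pixel, background from the *same depth band* at
  lateral offsets ≥ 1.3 radii (no time-gain compensation is applied, so
  a depth-spanning annulus would inflate the background variance).
* **Spatial coherence** — receive-focused RF in a ± one pulse-length
  window about the transmit focus, correlation per inter-element lag
  averaged over pairs (and over transmits when several foci are run);
  reference curve is the Van Cittert–Zernike triangle 1 − m/N of an
  unapodized aperture. The narrow window matters: away from the focal
  plane the insonified region is defocus-widened and long-lag coherence
  drops.
* **Reverberation depth curves** — lateral mean of the envelope per
  depth, in dB re the image reference.
* **Coda envelopes** — plane-averaged analytic-signal magnitude of the
  field transmitted through a bone slab; coda energy sums the squared
  envelope after the ballistic lobe (+3 burst lengths).

## Scaled experiments and what they show

The bundled experiments run on desk-scale domains chosen as the
package's test geometry: point-target scenes 26 mm wide at 12 points
per wavelength (1.25 MHz), lesion scenes 24 mm wide at 8 points per
wavelength (2.5 MHz, 12 foci), Courant number 0.4 (0.55 for the lesion
sweeps). At these sizes the full suite reproduces the degradation
structure at trend level: preceding-region reverberation falls steeply
with target depth while trailing clutter falls slowly; the
isovelocity PSF-to-clutter ratio tracks target brightness while the
isoimpedance ratio is flat within a fraction of a dB; lesion |CNR|
of the subtracted (aberration-only) images decreases with depth while
the isovelocity (reverberation-only) images improve, crossing once;
the skull collapses aperture coherence and clutter subtraction
restores it.

Absolute region levels depend on the synthetic skull (layer
thicknesses, porosity texture, roughness are seeded package defaults,
not a measured skull) and on the 2D geometry, so they are not
comparable to measurements on a specific specimen; only orderings and
trends are asserted. The microstructure-homogenization comparison
reproduces the thick/thin dichotomy as an ordering (homogenizing a
thick diploe raises coda energy ~1.3×; thin cortical slabs change
little, mean coda level ratio ≈ 1). Pointwise agreement of thin-slab
coda envelopes is limited to ~20% RMS by an artifact inherent to
resolution degradation: any 800 µm resampling relocates the cortical
interfaces by up to half a coarse cell, time-shifting the etalon
multiples even when their levels agree. The degradation pipeline
mirrors a clinical chain — block-mean resolution loss followed by
segment-and-scale conversion (midpoint threshold), which re-sharpens
boundaries and assigns marrow absorption to sub-threshold voxels.

## Degenerate inputs and numerical guards

CFL violations, unresolved wavelengths (< 6 points per wavelength at
the map's slowest speed) and thin PMLs are rejected before stepping;
non-finite traces abort the run. Clutter subtraction requires exactly
matching geometry and time base. All-zero images refuse to normalize.
Beamforming zero-fills sample requests beyond the trace. The no-skull
consistency check gates out the transmit event (standard receive
blanking) and uses a map deep enough that the bottom-boundary return
of the transmit is never recorded; the residual four-case disagreement
is then at the single-precision floor (~5×10⁻⁷ of the image maximum).

## Known limitations

2D only (cylindrical rather than spherical spreading changes absolute
clutter levels); no shear/mode conversion; absorption without
dispersion; a single synthetic skull family rather than measured
anatomy; element directivity beyond node averaging is not modeled;
trend assertions are made at one seed per experiment — the seeds are
part of the experiment definitions.

Two degradation behaviors depend on reverberation-path structure that
the smooth synthetic slab does not fully emulate. First, in the
subtracted (aberration-only) lesion images the shallow-depth residual
is dominated by skull reverberation re-scattered by the speckle — a
second-order term the scatterer-free clutter reference cannot cancel —
which decays with depth; with the scaled 18.9 mm aperture this
outweighs the resolution-driven decline, so the subtracted-image |CNR|
*improves* with lesion depth here even though the
reverberation-dominant-shallow / aberration-dominant-deep crossover
itself is reproduced. Second, harmonic-band imaging does not reduce
the preceding clutter in this geometry: the dominant multiples bounce
specularly between the rigid transducer plane and the smooth outer
skull surface through lossless water, paying no extra absorption at
the harmonic, whereas real-skull multiples are internally scattered
through bone and attenuate twice as fast at 2f₀. A partially
absorbing (impedance) transducer-face boundary and rougher multilayer
bone would be needed to recover that benefit.
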