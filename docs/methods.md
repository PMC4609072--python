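# Methods

This note documents the models behind `mcet`, the parameters that matter,
the numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## Acoustic field model

The therapy source is modelled as a spherically curved cap (concave bowl)
of aperture diameter *D* = 19 mm and radius of curvature *R_c* = 38 mm
(equal to the geometric focal length), vibrating uniformly and radiating
into lossless water (*c* = 1500 m/s).  For such a cap the velocity-potential
spatial impulse response at a field point has a closed form: surface points
at distance *R = ct* from the point form a circle on the sphere, and

    h(t) = c · R_c · α(ct) / (π · d),

where *d* is the distance from the field point to the centre of curvature
and α the half-arc angle of that circle lying on the cap, obtained from
spherical trigonometry (α = π on axis inside the aperture cone, 0 outside
the arrival window).  The pressure is p = ρ ∂(v ∗ h)/∂t with *v* a 5-cycle
sine burst at 1.5 MHz.  The implementation samples each point's arrival
window (128 samples), evaluates the Fourier transform of *h* by quadrature
up to the third harmonic, multiplies by the burst spectrum and iω, and
reads the peak negative pressure off the reconstructed waveform.  The map
is then normalised so its spatial maximum equals the configured focal peak
(4 MPa by default), which removes all absolute source-strength constants.

Assumptions and consequences:

* **Linear and lossless.** Nonlinear steepening, tissue attenuation,
  rib aberration and microbubble shadowing are not modelled.  Fields scale
  linearly with drive amplitude, so cohorts at different pressures reuse
  one computed map.
* **Pulsed drive.** The 5-cycle burst is narrowband; the focal-lobe
  geometry is nearly identical to the CW field (verified numerically), but
  the pulsed solver is retained because it is exact for the cap and cheap.
* The amplitude maximum sits slightly pre-focal (z ≈ 31.8 mm for the
  38-mm-focus bowl), as expected for a focusing gain of ~7.5.

**Grid.** Default Δr = 0.05 mm, Δz = 0.25 mm over r ∈ [0, 5] mm,
z ∈ [13, 63] mm (≥ 25 samples across the focal lobe).  A grid with fewer
than 8 radial samples across the predicted −6 dB lobe is refused.

**Threshold geometry.** The suprathreshold set uses a closed threshold
(amplitude ≥ p_L is inside).  The boundary radius per axial sample is
located by linear interpolation between the outermost suprathreshold
sample and its neighbour, which makes extents and volumes stable under
grid refinement; the volume is the trapezoidal solid of revolution
∫ π·r_b(z)² dz (1 mm³ = 1 µL).  Lateral extent is read at the axial
position of the field maximum, axial extent along r = 0.  With the default
transducer this yields a 2.44 × 31.7 mm region above 2 MPa and a volume of
138 µL.

## Exposure model

Pulse trains hold one pulse per 1/PRF (4 kHz default).  The square
envelope spans its width with constant amplitude (a 2-ms envelope holds 8
pulses); the Gaussian envelope places one pulse at the envelope maximum
with amplitudes peak·2^−(2t/FWHM)², truncated at one FWHM from the centre
(amplitudes < peak/16), so the pulses at ±FWHM/2 carry exactly half the
peak.  A pulse is lesion-capable only if its rescaled focal peak *strictly*
exceeds p_L; the edge pulses at exactly 2 MPa therefore contribute nothing,
matching how suprathreshold pulses are counted in the treatment protocol.

The effective exposure integral is Σᵢ V(Aᵢ)·w with V(A) the suprathreshold
volume of the field linearly rescaled to pulse amplitude A, and the time
weight w defaulting to the pulse repetition interval.  The absolute µL·s
value therefore depends on a reporting convention, but the Gaussian:square
ratio does not; the ratio is the quantity of scientific interest.  With the
default field and 2-ms envelopes the ratio computes to 54.2 %, stable
under grid refinement and burst-length changes, somewhat below the ~60 %
predicted by the original FIELD II-based analysis; the residual difference
is consistent with unknown details of that simulation's volume convention
(restricting the integration axially toward a myocardial-wall span
reproduces ~60 %), and falls within the tolerance used for this quantity.

Burst scheduling is ECG-gated: one burst every `trigger_every` heartbeats
(default every 4 at 360 bpm — the rodent protocol — giving 450 bursts in a
5-minute treatment).

## Microlesion formation model

Each candidate site under local pressure *p* forms a microlesion per burst
with probability χ(p) = clamp(s·max(0, p − p_L), 0, 1), hence cumulative
probability 1 − (1 − χ)ⁿ after *n* bursts.  The linear-above-threshold form
is the simplest law consistent with the observed linear density–pressure
relation; no mechanistic form is implied.  Simulation draws Poisson counts
per 0.1-mm voxel with mean ρ·dV·P, places lesions uniformly within voxels,
draws volumes from a log-normal with arithmetic mean 2×10⁵ µm³ (σ = 0.5 in
log space; the distribution family is a modelling choice — only the mean is
constrained by calibration), and assigns each lesion a birth burst by
inverting the truncated geometric formation law.  Contrast-agent
availability is a binary gate: only bursts inside the infusion window
accumulate probability.

**Tissue slab.**  The default slab spans 10 × 10 mm laterally and 12 mm
along the beam (z ∈ [26, 38] mm), centred on the field maximum — a
myocardial path thinner than the 32-mm suprathreshold axial extent, so the
macrolesion length is wall-limited, as in vivo.  Candidate-site density is
1750 /mm³, chosen with the mean lesion volume to put the saturation
(χ→1) lesion density at 35 %, comfortably above all operating points.

**Calibration.**  Two deterministic calibrations solve for the χ scale
against an *expected-pipeline* model that mirrors the scoring measurement
(radial lesion-volume profile per axial disk, 95 % containment radius,
density = contained volume / cylinder volume) without Monte-Carlo noise:

* `calibrate_scale_to_dose_response` (the default model): the pooled
  regression of expected disk density on on-axis pressure across the 2.8
  and 4.0 MPa cohorts has slope 4.52 %/MPa.  The containment measurement
  geometrically attenuates the per-site law by roughly 0.6× (disk density
  averages the probability profile over the disk area) and probability
  accumulation saturates sublinearly, so the scale is solved by bisection
  at the realised operating point (s ≈ 6.7×10⁻⁴ per MPa per burst for the
  default geometry) rather than in the small-χ limit.
* `calibrate_scale_to_density`: the overall expected macrolesion density
  equals a target (20 % for the five-minute single-spot reference,
  yielding ≈ 50 µL macrolesions at 4 MPa).

The two anchors are mutually inconsistent under a single linear χ law (the
slope calibration yields ~8 % macrolesion density at 4 MPa, not 20 %),
which mirrors the same tension in the animal data; the package makes the
dose–response slope the default anchor and exposes the density anchor
explicitly.

With the slope-calibrated model, seeded five-animal cohorts at 2.0 / 2.8 /
4.0 MPa reproduce: zero-to-sparse lesions at 2.0 MPa (the threshold equals
the focal peak, so the suprathreshold set degenerates to the focal point),
strictly increasing macrolesion mean radius with pressure (0 → ~0.7 →
~1.1 mm, inside the 0.1–1.6 mm range observed in animals), a recovered
dose–response slope within a few percent of 4.52 %/MPa, and an x-intercept
within ~0.2 MPa of the configured 2 MPa threshold (the measured relation is
mildly concave from saturation, pulling the linear intercept slightly low).

## Section rendering and scoring

**Rendering.** Lesions are rasterised as spheres: a section whose mid-plane
lies at offset dz from a lesion centre of radius r receives a filled disk
of radius √(r² − dz²), so contiguous 10-µm sectioning conserves total
volume to within rasterisation error (< 10 %, midpoint rule).  Lesions
smaller than one pixel are painted as single pixels with a warning.
Per-section rigid jitter (uniform in ±shift, ±angle) displaces content and
is recorded as ground truth.  Sections are cut perpendicular to a
configurable heart axis, which need not equal the beam axis.

**Registration.** Adjacent sections are aligned by a coarse-to-fine
rotation search (±8° at 1°, refined at 0.1°) scored by the normalised peak
of the circular cross-correlation of Gaussian-smoothed images (σ = 2 px;
smoothing makes the score smooth in angle and robust to content turnover
between sections), followed by sub-pixel phase-correlation translation.
Because un-rotating the moving image leaves a residual shift of R⁻¹t, the
recovered shift is rotated back to give the content translation.  Absolute
offsets are chained relative to the first section; blank sections pass
through with a warning without severing the chain.  On synthetic stacks
with ±10 px / ±3° jitter the recovered offsets are accurate to < 1 px and
< 0.3°.

**Reconstruction.** Aligned binary sections are stacked and labelled in
3-D (8-connectivity in-plane, direct overlap across adjacent sections, i.e.
a merge requires ≥ 1 coincident pixel), giving per-lesion volume Σ area ×
thickness and centroids in physical coordinates (origin at the image
centre, z = section index × spacing).

**Axis, disks, macrolesion.** The beam axis is the volume-weighted
total-least-squares 3-D line (first principal direction through the
weighted centroid; sign fixed to +z for determinism).  Lesions are binned
axially into 0.5-mm disks (bins anchored at a multiple of the thickness;
bins with < 3 lesions omitted — both are this package's devices, chosen to
keep ≥ 60 disks across the beam while keeping the percentile stable);
per disk the 95 % containment radius is the nearest-rank volume-weighted
percentile of radial distances (count weighting available as an option).
Macrolesion volume is Σ π r² Δz over occupied disks, length the axial span
(inclusive of one disk thickness), mean radius the unweighted disk-radius
mean, lesion density the contained microlesion volume as a percentage of
the macrolesion volume, and the auto score the contained microlesion
volume divided by a per-cardiomyocyte volume (default 31 416 µm³, a
100 µm × 20 µm-diameter cylinder; configurable, as any fixed conversion
factor is itself a modelling choice).

## Statistics

The visual-vs-auto score calibration fits two independent segments at a
fixed breakpoint (15 000 by default): y = a₁x through the origin below it,
y = a₂x + b above it.  Continuity is deliberately not enforced — the
saturation of visual counting is the phenomenon of interest.  Points
exactly at the breakpoint belong to the low segment.  Dose–response lines
are ordinary least squares via explicit normal equations (exactly zero
slope on constant data) with x₀ = −intercept/slope as the threshold
estimate, displayed to one decimal.  Boxplot summaries use
linear-interpolation quartiles and the 1.5 IQR outlier rule; whiskers
extend to the most extreme non-outliers.  No between-group hypothesis
tests are provided.

## Planner

The clinical target is a cylinder π(d/2)²·t (26.4 mL for d = 4 cm,
t = 21 mm).  Spot count is the exact volume ratio (displayed as whole
spots, 528); the static duration multiplies by the per-spot time (2640 min
displayed) and the swept duration divides by the frame rate (47 min at
56 fps).  The swept beam is treated as fully equivalent per frame —
justified by the near-equivalence of Gaussian- and square-modulated
outcomes — with an optional efficiency factor for sensitivity analysis.

## What the synthetic experiments do not show

The generator emulates threshold-gated, probability-accumulating lesion
formation in a homogeneous slab with ideal binary histology.  It does not
model real staining variability, vasculature, cell-orientation layers,
contrast-agent shadowing, cardiac motion or section tearing; registration
operates on shared blob content rather than tissue morphology.  Passing
round trips therefore validate the pipeline's geometry and statistics, not
its robustness to real histological artefacts.

## Problem sizes

The default field grid is 101 × 201 points (~7 s to compute); simulated
animals carry ~20 000 lesions at 4 MPa; section-stack fixtures use 36
sections of 256² pixels.  These sizes keep the full test suite and the
acceptance script in the low minutes on a single CPU while leaving all
calibrated quantities grid-stable.
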