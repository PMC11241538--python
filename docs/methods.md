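# Methods

## The index and its assumptions

CCIA treats the angiographic contrast agent as an indicator-dilution
tracer. For an injected amount *I* carried by flow *Q*, the
Stewart–Hamilton relation gives Q = I / ∫C(t)dt, so the time-AUC of the
downstream concentration is proportional to 1/Q. Taking the ratio of AUCs
between the stenotic territory and an equal-sized proximal territory of
the same vessel cancels *I* (and any global gain of the imaging chain):

    CCIA = AUC_S / AUC_N.

The assumptions this rests on:

- **Linearity of signal in concentration.** Pixel attenuation is taken
  proportional to the line integral of contrast concentration through the
  lumen. X-ray physics (beam hardening, scatter) breaks strict linearity
  at high iodine loads; the index is a ratio of integrals over equal-sized
  regions of the same vessel, which cancels first-order gain errors but
  not saturation.
- **Signal polarity.** Iodinated contrast darkens the image, so the
  contrast signal is inverted attenuation: per-pixel ROI mean subtracted
  from the pre-injection baseline, clipped at zero. The baseline is the
  mean over the frames preceding the injection.
- **Integration window.** The full record from injection onward is
  integrated, with no return-to-baseline truncation: the acquisition is
  specified to run until the contrast has dissipated, and truncating at a
  detected baseline return would inject an extra, noise-sensitive decision
  into the index.
- **CCIA direction.** The index is stenotic ÷ proximal, so low values mark
  severe lesions and values slightly above 1 are legal and preserved
  (no clamping, no internal rounding).

## Proximal ROI placement

The reference region is the stenotic mask translated upstream along the
vessel centerline (arc length, not straight-line distance) so that its
downstream boundary sits 10 mm upstream of the lesion's upstream
boundary — i.e. a 10 mm clearance gap separates the two regions, keeping
the reference fully outside the lesion and its entrance effects. The
translation is a single displacement vector with nearest-pixel rounding,
which preserves the pixel count exactly; equal-sized regions make the
AUC ratio identical whether the ROI statistic is the pixel mean or sum
(the mean is used, for cross-ROI comparability of the curves).

## FFR reference

FFR = (mean Pd − Pv)/(mean Pa − Pv), with means over the **last** 10
complete cardiac cycles of the record — the tail is used so pump or
physiological start-up transients are excluded. Pv defaults to 0, which
reduces the expression to the clinical Pd/Pa; it remains an explicit
parameter so the full form is available. Window boundaries snap to the
nearest samples; at the sampling rates used (≥ 200 Hz) the residual
cycle-misalignment error is below 10⁻³ in the ratio.

## Motion stabilization

In vivo the coronary moves with the heartbeat, so the ROI territories
would smear. The pipeline: (1) R peaks from the ECG via a 5–15 Hz
Butterworth bandpass, squared-derivative envelope, 0.1 s moving average,
and peak picking with a 0.25 s refractory period; (2) a sinus-rhythm gate
— the coefficient of variation of R-R intervals must be ≤ 0.10
(inclusive), since template tracking assumes a repeatable cycle;
(3) cardiac phase per frame as the fractional position inside its R-R
interval; (4) template tracking by normalized cross-correlation (NCC) of
a user-chosen box (catheter tip or stable landmark) over a bounded search
window, with separable parabolic sub-pixel refinement of the correlation
peak — skipped when the peak is exact (score 1), where refinement could
only add bias; (5) inverse translation of each frame (bilinear
interpolation, edge-value fill).

Design choices made where the procedure was genuinely open: NCC was
chosen as the similarity metric for its invariance to affine intensity
changes, since contrast density changes frame to frame; the motion model
is pure per-frame translation (no rotation/deformation) — adequate for a
rigid phantom and for the small inter-frame excursions of a gated
acquisition, and documented as a limitation for strongly deforming
vessels; ECG phase is attached as per-frame metadata for QC and
reference-frame selection but does not gate frames by default.

## The in-silico phantom

The generator reproduces the bench conditions: nine axisymmetric stenosis
models (30/50/70 % diameter stenosis × 6/18/30 mm total length, 3 mm
linear tapers at each end, 3 mm normal diameter), pulsatile flow with
25 cm/s period-mean velocity at 60 bpm with a 60 % systolic output
fraction, a 4 mL bolus injected at 16 mL/s through 500 mm of delivery
tubing, and a 300-frame, 10 s, 30 fps acquisition.

**Transport** is a cross-section-averaged 1-D advection–dispersion
finite-volume solve, ∂(AC)/∂t + ∂(QC)/∂x = ∂(AD∂C/∂x)/∂x, with
first-order upwind advection, explicit central dispersion, and automatic
CFL sub-stepping (Courant 0.4; a configuration needing more than 2×10⁵
sub-steps per frame is rejected as unstable rather than clipped). The
scheme is conservative by construction and the solver carries
injected/outflow mass ledgers so conservation can be audited at any
frame. This is deliberately not CFD: it produces realistic time–density
curves with *exact* known flow, which is what downstream validation
needs.

**Defaults**: grid Δx = 0.5 mm over a 120 mm domain with the lesion
centered at 70 mm (leaving room for the upstream reference ROI plus its
10 mm gap), dispersion 1 mm²/s. The 500 mm delivery tubing is folded into
a pure transport delay (tubing length over mean velocity) plus a Gaussian
temporal spread of the inlet source (σ = 0.3 s), standing in for the
mixing the bolus undergoes before reaching the model; extending the grid
would cost ~5× runtime for no extra ground truth.

**Rendering** projects the lumen onto a straight-vessel image: each pixel
attenuates the background (default 3000) by gain × concentration × chord
length of the circular lumen at that pixel row, plus seeded Gaussian
noise (default SD 10; Poisson mode available); values are rounded to
integers and clipped to the 16-bit range so stacks round-trip through
TIFF bit-exactly. Calibration is 0.2 mm/px.

**Pressures** are invented plumbing (the bench measured them physically):
Pa is a synthetic two-phase aortic waveform (~95 mmHg mean), and Pd
subtracts a trans-lesion drop composed of the *excess* Poiseuille
resistance of the narrowed profile over an equal length of normal tube
(4.5 cP perfusate viscosity) plus a Borda–Carnot sudden-expansion loss,
evaluated at the instantaneous flow. This makes FFR exactly 1 for the
no-lesion geometry and strictly decreasing in both severity and length —
the bench's ordinal behavior — but the absolute values are not calibrated
to the bench hardware and are not presented as such.

**In-vivo mode** adds a static smoothed-noise pseudo-anatomy texture
(SD 60 by default) — a real angiogram's background structure is what
template matching locks onto, and a synthetic phantom has none — then
translates the whole scene along a smooth cardiac-phase-locked trajectory
(vertical sinusoid at the heart rate plus a horizontal second harmonic),
and emits a synthetic ECG whose R peaks sit exactly at cycle boundaries.
The exact per-frame displacements are returned as ground truth.

### What the phantom does and does not emulate

It emulates: bolus transit timing and dispersion, the geometric
attenuation contrast between stenotic and normal segments, pulsatile
modulation, acquisition noise, and cardiac-cycle motion. It does not
emulate: 3-D/turbulent flow and jet effects, X-ray physics, curved or
branching vessels, overlapping background vessels, respiratory motion, or
microvascular autoregulation (flow is imposed, not pressure-driven).
Consequently, passing tests demonstrate the *pipeline* — extraction,
integration, ratio, placement, tracking, inversion — is correct against
exact ground truth, and that the simulator reproduces the bench's ordinal
severity trends; they do not certify quantitative accuracy on clinical
images. The bench rig's own numeric FFR/CCIA values are physical
measurements and are treated as ordinal constraints only.

## Validation statistics

Per-patient CCIA is recomputed from the packaged 15-patient
contrast-intensity table and compared with the printed index at two
decimals (Python's round-half-to-even; no printed row lies on a half
case). Pearson correlations use the product-moment coefficient with a
two-sided p from the t transform (n − 2 df), plus the OLS best-fit line
of y on x; the CCIA–FFR correlation uses all 15 patients, the CCIA–iFR
correlation the 11 with an iFR measurement. The printed (rounded) index
column is the correlated quantity, matching how the clinical analysis was
evidently done. Replicate summaries report mean and sample SD (n − 1);
SD is flagged undefined for n = 1. The correlation of the nine bench
per-model means is computed and displayed in the validation report but
asserted against nothing: the printed per-model means do not reproduce
the bench-level correlation, which must rest on unpublished
replicate-level pairing, and the report never asserts what its own inputs
cannot reproduce. Degenerate statistical inputs (zero variance, n < 3)
raise typed errors rather than returning NaN.

## Numerical choices and problem sizes

- Trapezoidal AUC with linear interpolation at window edges: exact for
  piecewise-linear curves sampled at their breakpoints; gamma-variate
  test curves agree with the closed-form Γ-integral to 10⁻⁴ at 1 ms
  sampling.
- Conservation audits hold to better than 0.1 % of the injected amount
  (they are exact to rounding by construction); halving the grid changes
  station AUCs by far less than 1 %.
- The test suite runs the nine-geometry bench grid noise-free with 3
  replicates (the bolus field is solved once per geometry and re-rendered
  per replicate) and one beating-heart sequence at 5 px amplitude; both
  complete in well under a minute on one core, and all stochastic steps
  are seeded.

## Known limitations

Translation-only motion model; 1-D transport (no jet or recirculation
physics, so CCIA magnitudes for severe lesions are governed by lumen
geometry rather than post-stenotic hemodynamics); invented pressure and
aortic waveforms (ordinal fidelity only); no automatic lesion
segmentation (ROIs are supplied); DICOM is read-only and vendor private
tags are ignored; iFR values are consumed as given, never computed.
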