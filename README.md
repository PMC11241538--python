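# ccia — coronary contrast intensity analysis

Grading a coronary stenosis today means either eyeballing the angiogram or
threading a pressure wire past the lesion to measure fractional flow
reserve (FFR) under drug-induced hyperemia. `ccia` implements a
contrast-based alternative that needs nothing beyond the routine
angiographic acquisition: the contrast agent itself is used as an
indicator-dilution tracer, and the stenosis is graded by how its
time–density curve compares with a healthy reference segment of the same
vessel.

The package is aimed at researchers in quantitative angiography and
cardiovascular physiology who want a fully testable, end-to-end reference
implementation — including an in-silico phantom of a pulsatile
coronary-circulation bench rig, so every stage can be validated against
exact ground truth without any imaging hardware.

## The index

By the Stewart–Hamilton relation, a flow *Q* carrying an injected
indicator amount *I* satisfies

    Q = I / ∫ C(t) dt,

so the time-integral of the downstream concentration (the AUC of the
time–intensity curve) is inversely proportional to flow. Within one
vessel, the ratio of AUCs between the stenotic region S and an equal-sized
proximal region N therefore compares the average flows through the two
territories without knowing *I*:

    CCIA = AUC_S / AUC_N.

A CCIA near 1 means the lesion passes contrast like the normal segment; a
low CCIA marks a hemodynamically severe stenosis. Values slightly above 1
occur and are legal. The proximal reference region is the stenotic mask
translated upstream along the vessel centerline, with a 10 mm clearance
gap, so both regions have identical pixel counts by construction.

The pressure reference, FFR = (mean Pd − Pv)/(mean Pa − Pv) averaged over
10 cardiac cycles (Pv defaults to 0, giving Pd/Pa), is computed alongside
for validation.

## What is in the box

- `ccia.io_stack` — frame stacks (multi-page TIFF + JSON sidecar
  read/write, multi-frame DICOM read), ECG/pressure CSVs, ROI JSON, and
  the packaged 15-patient clinical results table.
- `ccia.tic_core` — time–intensity extraction, trapezoidal AUC, the CCIA
  index, Stewart–Hamilton flow, automatic proximal-ROI placement.
- `ccia.motion_stabilize` — R-peak detection, sinus-rhythm check, cardiac
  phase assignment, normalized-cross-correlation template tracking with
  sub-pixel refinement, and inverse-motion stabilization for beating-heart
  sequences.
- `ccia.hemodynamics` — cycle-windowed FFR.
- `ccia.phantom_sim` — the in-silico bench rig: nine axisymmetric stenosis
  geometries (30/50/70 %DS × 6/18/30 mm), pulsatile flow (25 cm/s mean,
  60 bpm), a mass-conserving 1-D advection–dispersion bolus solver,
  projection rendering at 30 fps × 10 s, synthetic pressures and ECG, and
  a beating-heart mode with exact ground-truth motion.
- `ccia.stats_validate` — per-patient CCIA recomputation, Pearson
  correlations with FFR/iFR, replicate summaries, and a one-shot
  validation report.

## Worked example

Simulate the default phantom (50 % diameter stenosis, 18 mm long) and
grade it with both indices:

```python
from ccia import phantom_sim as ps, tic_core as tc, hemodynamics as hd

cfg = ps.SimConfig()                      # 50 %DS, 18 mm, bench protocol
bolus = ps.advect_bolus(cfg)              # 1-D concentration field
stack = ps.render_frames(bolus, cfg)      # 300-frame angiographic stack
roi = ps.lesion_roi(cfg)                  # stenotic mask + centerline

res = tc.compute_ccia_from_stack(stack, roi, baseline_frames=30,
                                 window=(1.0, stack.times[-1]))
f = hd.ffr(ps.pressure_traces(cfg), period=1.0, n_cycles=10)
print(f"CCIA = {res.ccia:.3f}  (AUC_S = {res.auc_stenotic:.1f}, "
      f"AUC_N = {res.auc_proximal:.1f})")
print(f"FFR  = {f.ffr:.3f}  (mean Pa = {f.mean_pa:.1f} mmHg, "
      f"mean Pd = {f.mean_pd:.1f} mmHg)")
```

prints

```
CCIA = 0.529  (AUC_S = 486.5, AUC_N = 920.1)
FFR  = 0.911  (mean Pa = 94.7 mmHg, mean Pd = 86.2 mmHg)
```

The stenotic AUC is about half the proximal AUC — contrast transits the
narrowed segment with roughly half the attenuating volume — while the
synthetic pressure pair shows the corresponding trans-lesion gradient.
`ccia.run_grid()` repeats this over all nine bench geometries and returns
a tidy table; CCIA falls monotonically with stenosis severity at every
length, and FFR falls with both severity and length.

The same pipeline is exposed on the command line: `ccia simulate`,
`ccia compute`, `ccia stabilize`, `ccia ffr`, `ccia validate`.

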