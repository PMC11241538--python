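"""In-silico phantom of a bench coronary circulation rig.

Reproduces, in software, the measurement conditions of a pulsatile
flow loop pushing perfusate through axisymmetric acrylic stenosis models:
a contrast bolus (4 mL at 16 mL/s) is injected upstream, advected through
a 3 mm vessel carrying a 25 cm/s mean, 60 bpm pulsatile flow, and imaged
at 30 fps for 10 s. The phantom supplies every downstream test with exact
ground truth: the concentration field, the rendered projection stack, the
pressure traces, a synthetic ECG, and (in in-vivo mode) the true
cardiac-phase-locked motion.

Transport is a mass-conserving 1-D cross-section-averaged
advection–dispersion finite-volume solve,

    d(A C)/dt + d(Q C)/dx = d(A D dC/dx)/dx,

with first-order upwind advection and automatic CFL sub-stepping — not
CFD; it is sufficient to generate realistic time–density curves with known
flow. The 500 mm of delivery tubing between injector and model is folded
into a pure transport delay plus a Gaussian temporal spread of the inlet
source rather than extending the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .errors import SignalError, ValidationError
from .io_stack import EcgTrace, FrameStack, PressureTraces, RoiSpec
from .tic_core import Injection

__all__ = [
    "StenosisGeometry",
    "FlowWaveform",
    "SimConfig",
    "BolusField",
    "table1_geometries",
    "diameter_profile",
    "pulsatile_flow",
    "advect_bolus",
    "render_frames",
    "lesion_roi",
    "pressure_traces",
    "synthetic_ecg",
    "simulate_invivo",
    "config_from_yaml",
    "run_grid",
]

MMHG_PER_PA = 1.0 / 133.322


@dataclass
class StenosisGeometry:
    """Axisymmetric stenosis: linear inlet taper, constant throat, outlet taper.

    ``h_over_r`` is the stenotic-to-normal *diameter* ratio; percent
    diameter stenosis is ``100 * (1 - h_over_r)``. Lengths are in mm:
    ``li`` inlet taper, ``xs`` constant throat, ``lo`` outlet taper.
    """

    h_over_r: float
    li: float = 3.0
    xs: float = 0.0
    lo: float = 3.0
    normal_diameter: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.h_over_r <= 1:
            raise ValidationError(f"h_over_r must be in (0, 1], got {self.h_over_r}")
        if self.li < 0 or self.xs < 0 or self.lo < 0:
            raise ValidationError("taper and throat lengths must be >= 0")
        if self.normal_diameter <= 0:
            raise ValidationError("normal_diameter must be > 0")

    @property
    def percent_ds(self) -> float:
        # round away binary dust so 1 - 0.7 reports exactly 30 %DS
        return round(100.0 * (1.0 - self.h_over_r), 9)

    @property
    def total_length(self) -> float:
        return self.li + self.xs + self.lo

    @classmethod
    def from_severity(cls, percent_ds: float, total_length: float,
                      taper: float = 3.0) -> "StenosisGeometry":
        """Build a bench-style geometry: 3 mm tapers, throat filling the rest."""
        xs = total_length - 2 * taper
        if xs < 0:
            raise ValidationError(
                f"total_length {total_length} shorter than the two {taper} mm tapers")
        return cls(h_over_r=1.0 - percent_ds / 100.0, li=taper, xs=xs, lo=taper)


def table1_geometries() -> list[StenosisGeometry]:
    """The nine bench stenosis models: 30/50/70 %DS x 6/18/30 mm total length."""
    out = []
    for ds in (30.0, 50.0, 70.0):
        for total in (6.0, 18.0, 30.0):
            out.append(StenosisGeometry.from_severity(ds, total))
    return out


@dataclass
class FlowWaveform:
    """Pulsatile velocity waveform in the normal segment.

    A raised half-sine during the systolic fraction of each cycle atop a
    constant diastolic base, scaled so the period-mean velocity equals
    ``mean_velocity`` (cm/s). ``pulse_amp`` is the systolic bump height as
    a multiple of the base; 0 gives steady flow.
    """

    mean_velocity: float = 25.0   # cm/s
    heart_rate: float = 60.0      # bpm
    systolic_fraction: float = 0.6
    pulse_amp: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_velocity <= 0 or self.heart_rate <= 0:
            raise ValidationError("mean_velocity and heart_rate must be > 0")
        if not 0 < self.systolic_fraction <= 1:
            raise ValidationError("systolic_fraction must be in (0, 1]")
        if self.pulse_amp < 0:
            raise ValidationError("pulse_amp must be >= 0")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    def velocity(self, t: np.ndarray | float) -> np.ndarray:
        """Velocity (mm/s) in the normal segment at time(s) t."""
        phase = np.mod(np.asarray(t, dtype=float), self.period) / self.period
        fs = self.systolic_fraction
        bump = np.where(phase < fs, np.sin(np.pi * np.minimum(phase, fs) / fs), 0.0)
        # period-mean of bump is (2/pi)*fs; scale base so the mean is exact
        base = (self.mean_velocity * 10.0) / (1.0 + self.pulse_amp * (2.0 / np.pi) * fs)
        return base * (1.0 + self.pulse_amp * bump)


def pulsatile_flow(flow: FlowWaveform, t: np.ndarray | float,
                   normal_diameter: float = 3.0) -> np.ndarray | float:
    """Volumetric flow (mL/s) through the normal segment at time(s) t."""
    area = np.pi * (normal_diameter / 2.0) ** 2  # mm^2
    q_mm3 = flow.velocity(t) * area              # mm^3/s
    return q_mm3 / 1000.0


@dataclass
class SimConfig:
    """Full phantom configuration; defaults are the bench protocol."""

    geometry: StenosisGeometry = field(
        default_factory=lambda: StenosisGeometry.from_severity(50.0, 18.0))
    flow: FlowWaveform = field(default_factory=FlowWaveform)
    injection: Injection = field(
        default_factory=lambda: Injection(amount=4.0, rate=16.0, start_time=1.0))
    grid_dx: float = 0.5          # mm
    dispersion_coeff: float = 1.0  # mm^2/s
    frame_rate: float = 30.0      # fps
    duration: float = 10.0        # s
    mm_per_px: float = 0.2
    noise_sd: float = 10.0        # additive Gaussian render noise
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0
    domain_length_mm: float = 120.0
    lesion_center_mm: float = 70.0
    upstream_length_mm: float = 500.0  # injector-to-model tubing -> pure delay
    inlet_spread_s: float = 0.3   # Gaussian sigma of the inlet source (tubing mixing)
    background: float = 3000.0    # render background level
    gain: float = 150.0           # signal per (concentration x mm chord)
    vessel_margin_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.grid_dx <= 0:
            raise ValidationError("grid_dx must be > 0")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValidationError("duration and frame_rate must be > 0")
        if self.background < 0 or self.gain < 0:
            raise ValidationError("background and gain must be >= 0")
        lesion_half = self.geometry.total_length / 2.0
        if (self.lesion_center_mm - lesion_half < 0
                or self.lesion_center_mm + lesion_half > self.domain_length_mm):
            raise ValidationError("lesion does not fit inside the domain")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def lesion_start(self) -> float:
        return self.lesion_center_mm - self.geometry.total_length / 2.0

    @property
    def lesion_end(self) -> float:
        return self.lesion_center_mm + self.geometry.total_length / 2.0


def diameter_profile(geometry: StenosisGeometry, x: np.ndarray | float,
                     lesion_start: float = 0.0,
                     domain_length: float | None = None) -> np.ndarray | float:
    """Lumen diameter (mm) at axial position(s) ``x`` (mm).

    The lesion occupies ``[lesion_start, lesion_start + total_length]``;
    diameter is the normal diameter outside it, tapers linearly to
    ``h = h_over_r * normal_diameter`` over the inlet length, stays at the
    throat diameter, and tapers back over the outlet length.
    """
    x = np.asarray(x, dtype=float)
    if domain_length is not None and (np.any(x < 0) or np.any(x > domain_length)):
        raise ValidationError("x outside the domain")
    g = geometry
    d_normal, h = g.normal_diameter, g.h_over_r * g.normal_diameter
    xr = x - lesion_start
    d = np.full(x.shape, d_normal)
    if g.li > 0:
        sel = (xr >= 0) & (xr < g.li)
        d = np.where(sel, d_normal + (h - d_normal) * xr / g.li, d)
    sel = (xr >= g.li) & (xr <= g.li + g.xs)
    d = np.where(sel, h, d)
    if g.lo > 0:
        sel = (xr > g.li + g.xs) & (xr <= g.total_length)
        d = np.where(sel, h + (d_normal - h) * (xr - g.li - g.xs) / g.lo, d)
    return d if d.ndim else float(d)


@dataclass
class BolusField:
    """Solved concentration field with conservation bookkeeping.

    ``conc[t, i]`` is the cross-section-averaged tracer concentration
    (volume fraction) in cell ``i`` at frame time ``t``. ``mass_injected``
    and ``mass_out`` are cumulative (mL) at each frame time; the mass in
    the domain plus ``mass_out`` equals ``mass_injected`` to rounding.
    """

    x: np.ndarray          # cell centers, mm
    times: np.ndarray      # frame times, s
    conc: np.ndarray       # (n_frames, n_cells)
    area: np.ndarray       # cell cross-sections, mm^2
    dx: float
    config: SimConfig

    def mass_in_domain(self) -> np.ndarray:
        return (self.conc * self.area[None, :]).sum(axis=1) * self.dx / 1000.0

    mass_injected: np.ndarray = field(default=None)  # type: ignore[assignment]
    mass_out: np.ndarray = field(default=None)       # type: ignore[assignment]

    def station_auc(self, x_mm: float) -> float:
        """Time-AUC of concentration at the station nearest ``x_mm`` (conc*s)."""
        i = int(np.argmin(np.abs(self.x - x_mm)))
        return float(np.trapezoid(self.conc[:, i], self.times))


def _source_cumulative(t: np.ndarray, injection: Injection, delay: float,
                       sigma: float) -> np.ndarray:
    """Cumulative injected tracer (mL) reaching the inlet by time(s) t.

    The injector's boxcar (amount/rate seconds at ``rate``) convolved with
    a Gaussian of SD ``sigma`` and shifted by the tubing transit ``delay``;
    closed form via the integrated normal CDF so mass is exact.
    """
    t0 = injection.start_time + delay
    dur = injection.duration
    if sigma <= 0:
        u = np.clip(t - t0, 0.0, dur)
        return injection.rate * u

    def g(u: np.ndarray) -> np.ndarray:
        z = u / sigma
        return u * 0.5 * (1 + special.erf(z / np.sqrt(2))) + \
            sigma * np.exp(-0.5 * z ** 2) / np.sqrt(2 * np.pi)

    return injection.rate * (g(t - t0) - g(t - t0 - dur))


def advect_bolus(config: SimConfig, max_substeps_per_frame: int = 200_000
                 ) -> BolusField:
    """Solve bolus transport through the phantom on a 1-D finite-volume grid.

    Upwind advection with automatic CFL sub-stepping (courant 0.4) and
    explicit central dispersion; the scheme is conservative by
    construction, and the returned field carries the injected/outflow mass
    ledgers so conservation can be audited at any frame.
    """
    g = config
    n = int(round(g.domain_length_mm / g.grid_dx))
    dx = g.domain_length_mm / n
    x = (np.arange(n) + 0.5) * dx
    d = np.asarray(diameter_profile(g.geometry, x, g.lesion_start))
    area = np.pi * (d / 2.0) ** 2                      # mm^2
    area_face = 0.5 * (area[:-1] + area[1:])           # interior faces

    frame_times = np.arange(g.n_frames) / g.frame_rate
    dt_frame = 1.0 / g.frame_rate

    v_peak = float(np.max(g.flow.velocity(np.linspace(0, g.flow.period, 2001))))
    u_max = v_peak * area.max() / area.min()  # fastest cell is the throat
    dt_adv = 0.4 * dx / u_max
    dt_disp = (0.25 * dx ** 2 / g.dispersion_coeff
               if g.dispersion_coeff > 0 else np.inf)
    dt_target = min(dt_adv, dt_disp)
    n_sub = max(1, int(np.ceil(dt_frame / dt_target)))
    if n_sub > max_substeps_per_frame:
        raise SignalError(
            f"unstable configuration: needs {n_sub} sub-steps per frame "
            f"(u_max={u_max:.0f} mm/s, dx={dx} mm); coarsen or slow the flow")
    dt = dt_frame / n_sub

    mean_u = g.flow.mean_velocity * 10.0
    delay = g.upstream_length_mm / mean_u

    conc = np.zeros((g.n_frames, n))
    mass = np.zeros(n)  # tracer volume per cell, mm^3
    c = np.zeros(n)
    cum_out = 0.0
    mass_injected = np.zeros(g.n_frames)
    mass_out = np.zeros(g.n_frames)
    inj_scale = 1000.0  # mL -> mm^3

    D = g.dispersion_coeff
    for f in range(g.n_frames):
        t_frame = frame_times[f]
        conc[f] = mass / (area * dx)
        mass_injected[f] = _source_cumulative(
            np.asarray(t_frame), g.injection, delay, g.inlet_spread_s)
        mass_out[f] = cum_out / inj_scale
        if f == g.n_frames - 1:
            break
        sub_t = t_frame + dt * np.arange(n_sub + 1)
        cum_src = _source_cumulative(sub_t, g.injection, delay,
                                     g.inlet_spread_s) * inj_scale
        src_per_step = np.diff(cum_src)  # mm^3 entering cell 0 each sub-step
        q_sub = np.asarray(pulsatile_flow(
            g.flow, sub_t[:-1], g.geometry.normal_diameter)) * 1000.0  # mm^3/s
        for k in range(n_sub):
            c = mass / (area * dx)
            q = q_sub[k]
            flux_adv = q * c[:-1]                      # interior faces, upwind
            flux_disp = -D * area_face * (c[1:] - c[:-1]) / dx
            flux = flux_adv + flux_disp
            out = q * c[-1]
            mass[0] += dt * (src_per_step[k] / dt - flux[0])
            mass[1:-1] += dt * (flux[:-1] - flux[1:])
            mass[-1] += dt * (flux[-1] - out)
            cum_out += dt * out
    return BolusField(x, frame_times, conc, area, dx, g,
                      mass_injected=mass_injected, mass_out=mass_out)


# ---------------------------------------------------------------------------
# rendering

def _render_geometry(config: SimConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-pixel chord thickness map (mm) and column axial centers (mm)."""
    g = config
    ncols = int(round(g.domain_length_mm / g.mm_per_px))
    half_h = g.geometry.normal_diameter / 2.0 + g.vessel_margin_mm
    nrows = int(round(2 * half_h / g.mm_per_px))
    col_x = (np.arange(ncols) + 0.5) * g.mm_per_px
    row_y = (np.arange(nrows) + 0.5) * g.mm_per_px - half_h
    d = np.asarray(diameter_profile(g.geometry, col_x, g.lesion_start))
    rad2 = (d / 2.0) ** 2
    chord = 2.0 * np.sqrt(np.maximum(0.0, rad2[None, :] - row_y[:, None] ** 2))
    return chord, col_x, nrows


def render_frames(bolus: BolusField, config: SimConfig | None = None
                  ) -> FrameStack:
    """Project the concentration field to a straight-vessel image stack.

    Each pixel over the vessel attenuates the background in proportion to
    concentration times the chord thickness of the circular lumen at that
    pixel row; Gaussian (or Poisson) noise is added, values are rounded to
    integers and clipped to the 16-bit range, so stacks round-trip through
    TIFF bit-exactly.
    """
    g = config or bolus.config
    chord, col_x, nrows = _render_geometry(g)
    c_cols = np.empty((g.n_frames, len(col_x)))
    for f in range(g.n_frames):
        c_cols[f] = np.interp(col_x, bolus.x, bolus.conc[f])
    frames = g.background - g.gain * c_cols[:, None, :] * chord[None, :, :]
    rng = np.random.default_rng(g.seed)
    if g.noise_sd > 0:
        if g.noise_model == "poisson":
            frames = rng.poisson(np.maximum(frames, 0.0)).astype(float)
        else:
            frames = frames + rng.normal(0.0, g.noise_sd, frames.shape)
    frames = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max)
    times = np.arange(g.n_frames) / g.frame_rate
    return FrameStack(frames, times, g.mm_per_px, g.frame_rate)


def lesion_roi(config: SimConfig) -> RoiSpec:
    """The stenotic ROI of a rendered phantom: lumen pixels over the lesion.

    The mask covers pixels inside the lumen for axial positions within the
    lesion extent (the region where the vessel narrows before returning to
    its normal width); the centerline runs along the vessel axis from
    inflow (left) to outflow (right).
    """
    g = config
    chord, col_x, nrows = _render_geometry(g)
    in_lesion = (col_x >= g.lesion_start) & (col_x <= g.lesion_end)
    mask = (chord > 0) & in_lesion[None, :]
    center_row = (nrows - 1) / 2.0
    ncols = len(col_x)
    centerline = np.column_stack([np.full(ncols, center_row), np.arange(ncols)])
    return RoiSpec(mask, centerline, g.mm_per_px)


# ---------------------------------------------------------------------------
# pressures

PERFUSATE_VISCOSITY_PAS = 4.5e-3   # 4.5 cP
PERFUSATE_DENSITY = 1050.0         # kg/m^3


def _aortic_waveform(t: np.ndarray, period: float) -> np.ndarray:
    """Synthetic two-phase aortic pressure (mmHg): systolic bump over a
    diastolic base. Plumbing, not physiology — only its cycle mean and
    periodicity matter downstream."""
    phase = np.mod(t, period) / period
    fs = 0.45
    bump = np.where(phase < fs, np.sin(np.pi * np.minimum(phase, fs) / fs) ** 2, 0.0)
    decay = np.where(phase >= fs, 8.0 * np.exp(-(phase - fs) / 0.25), 0.0)
    return 85.0 + 35.0 * bump + decay


def stenosis_pressure_drop(geometry: StenosisGeometry, q_ml_s: np.ndarray,
                           viscosity: float = PERFUSATE_VISCOSITY_PAS,
                           density: float = PERFUSATE_DENSITY) -> np.ndarray:
    """Trans-lesion pressure drop (mmHg) at volumetric flow ``q_ml_s``.

    Excess Poiseuille resistance of the narrowed profile over an equal
    length of normal tube, plus a Borda–Carnot sudden-expansion loss at
    the outlet; both strictly increasing in %DS and the Poiseuille term in
    throat length, mirroring the bench trends.
    """
    q = np.asarray(q_ml_s, dtype=float) * 1e-6  # m^3/s
    g = geometry
    n_int = 400
    x = np.linspace(0.0, g.total_length, n_int)
    d_mm = np.asarray(diameter_profile(g, x, 0.0))
    d = d_mm * 1e-3
    d_norm = g.normal_diameter * 1e-3
    kernel = 1.0 / d ** 4 - 1.0 / d_norm ** 4
    resist = (128.0 * viscosity / np.pi) * np.trapezoid(kernel, x * 1e-3)
    dp_pois = resist * q  # Pa
    a_norm = np.pi * (d_norm / 2) ** 2
    a_min = np.pi * (g.h_over_r * d_norm / 2) ** 2
    u1 = q / a_min
    u2 = q / a_norm
    dp_bc = 0.5 * density * (u1 - u2) ** 2  # Pa
    return (dp_pois + dp_bc) * MMHG_PER_PA


def pressure_traces(config: SimConfig, sampling_rate: float = 200.0,
                    duration: float | None = None) -> PressureTraces:
    """Synthetic Pa/Pd pair for the configured phantom.

    Pa is the reference aortic waveform; Pd subtracts the instantaneous
    trans-lesion drop evaluated at the pulsatile flow. Long enough for the
    standard 10-cycle FFR window by default.
    """
    g = config
    if duration is None:
        duration = max(g.duration, 12.0 * g.flow.period)
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    pa = _aortic_waveform(t, g.flow.period)
    q = np.asarray(pulsatile_flow(g.flow, t, g.geometry.normal_diameter))
    dp = stenosis_pressure_drop(g.geometry, q)
    pd = np.maximum(pa - dp, 1.0)
    return PressureTraces(t, pa, pd)


# ---------------------------------------------------------------------------
# in vivo mode

def synthetic_ecg(duration: float, heart_rate: float = 60.0,
                  sampling_rate: float = 500.0, noise_sd: float = 0.02,
                  seed: int = 0) -> EcgTrace:
    """Synthetic single-lead ECG with R spikes at exact cycle boundaries.

    Gaussian R waves (sigma 12 ms) at t = 0, T, 2T, ... plus smaller P and
    T waves and optional Gaussian noise; the R-peak times are the
    ground-truth cardiac cycle starts used by the in-vivo phantom.
    """
    period = 60.0 / heart_rate
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    v = np.zeros_like(t)
    n_beats = int(np.floor(duration / period)) + 1
    for k in range(n_beats):
        tc = k * period
        v += 1.0 * np.exp(-0.5 * ((t - tc) / 0.012) ** 2)        # R
        v += 0.15 * np.exp(-0.5 * ((t - tc + 0.16) / 0.04) ** 2)  # P
        v += 0.25 * np.exp(-0.5 * ((t - tc - 0.25) / 0.05) ** 2)  # T
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, v.shape)
    return EcgTrace(t, v, sampling_rate)


def cardiac_motion(times: np.ndarray, period: float,
                   amplitude_px: float) -> np.ndarray:
    """Smooth cardiac-phase-locked (dy, dx) trajectory, zero at t = 0."""
    w = 2 * np.pi / period
    dy = amplitude_px * np.sin(w * times)
    dx = 0.6 * amplitude_px * np.sin(2 * w * times)
    return np.column_stack([dy, dx])


def simulate_invivo(config: SimConfig, motion_amplitude_px: float = 5.0,
                    ecg_noise_sd: float = 0.02,
                    background_texture_sd: float = 60.0
                    ) -> tuple[FrameStack, EcgTrace, "np.ndarray"]:
    """Render the phantom with beating-heart motion and a matched ECG.

    A static pseudo-anatomy texture (smoothed seeded Gaussian field of SD
    ``background_texture_sd``) is added so that template matching has
    structure to lock onto, as the surrounding anatomy provides in a real
    angiogram; the whole scene then translates along a smooth
    cardiac-phase-locked trajectory. Returns the moving stack, the
    synthetic ECG (R peaks exactly at cycle boundaries), and the
    ground-truth per-frame (dy, dx) displacements relative to frame 0.
    """
    from scipy import ndimage

    bolus = advect_bolus(config)
    static = render_frames(bolus, config)
    if background_texture_sd > 0:
        rng = np.random.default_rng(config.seed + 2)
        texture = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, static.frames.shape[1:]), sigma=2.0)
        texture = np.round(background_texture_sd / max(texture.std(), 1e-12)
                           * texture)
        frames0 = np.clip(static.frames + texture[None], 0,
                          np.iinfo(np.uint16).max)
        static = FrameStack(frames0, static.times, static.mm_per_px,
                            static.frame_rate)
    disp = cardiac_motion(static.times, config.flow.period, motion_amplitude_px)
    if motion_amplitude_px == 0:
        return static, synthetic_ecg(config.duration, config.flow.heart_rate,
                                     noise_sd=ecg_noise_sd,
                                     seed=config.seed + 1), disp
    frames = np.empty_like(static.frames)
    for i in range(static.n_frames):
        dy, dx = disp[i]
        if dy == 0.0 and dx == 0.0:
            frames[i] = static.frames[i]
        else:
            frames[i] = ndimage.shift(static.frames[i], (dy, dx), order=1,
                                      mode="nearest")
    frames = np.maximum(frames, 0.0)
    moving = FrameStack(frames, static.times.copy(), static.mm_per_px,
                        static.frame_rate)
    ecg = synthetic_ecg(config.duration, config.flow.heart_rate,
                        noise_sd=ecg_noise_sd, seed=config.seed + 1)
    return moving, ecg, disp


def config_from_yaml(path) -> SimConfig:
    """Build a SimConfig from a YAML file mirroring its fields.

    Nested mappings ``geometry``, ``flow`` and ``injection`` construct the
    corresponding dataclasses; all other keys map directly onto SimConfig
    fields.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    if "geometry" in doc:
        kwargs["geometry"] = StenosisGeometry(**doc.pop("geometry"))
    if "flow" in doc:
        kwargs["flow"] = FlowWaveform(**doc.pop("flow"))
    if "injection" in doc:
        kwargs["injection"] = Injection(**doc.pop("injection"))
    kwargs.update(doc)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# the full bench grid

def run_grid(replicates: int = 3, seed: int = 0,
             base_config: SimConfig | None = None) -> pd.DataFrame:
    """Run the nine bench geometries x replicates end to end.

    For each geometry, the bolus field is solved once and each replicate is
    rendered with its own noise seed, then CCIA (via the full ROI pipeline)
    and FFR (from the synthetic pressures) are computed. Returns a tidy
    table with columns length, percent_ds, replicate, ccia, ffr.
    """
    from .hemodynamics import ffr as compute_ffr
    from .tic_core import compute_ccia_from_stack

    base = base_config or SimConfig()
    rows = []
    for geom in table1_geometries():
        cfg = replace(base, geometry=geom)
        bolus = advect_bolus(cfg)
        pres = pressure_traces(cfg)
        ffr_value = compute_ffr(pres, period=cfg.flow.period, n_cycles=10).ffr
        roi = lesion_roi(cfg)
        baseline = max(1, int(cfg.injection.start_time * cfg.frame_rate))
        for rep in range(replicates):
            cfg_r = replace(cfg, seed=seed + 1000 * rep + int(geom.percent_ds)
                            + int(geom.total_length))
            stack = render_frames(bolus, cfg_r)
            res = compute_ccia_from_stack(
                stack, roi, baseline,
                window=(cfg.injection.start_time, stack.times[-1]))
            rows.append({"length": geom.total_length,
                         "percent_ds": geom.percent_ds,
                         "replicate": rep, "ccia": res.ccia,
                         "ffr": ffr_value})
    return pd.DataFrame(rows)
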