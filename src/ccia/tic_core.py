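"""Time–intensity curves, AUC integration, and the CCIA index.

Coronary contrast intensity analysis (CCIA) grades a stenosis from routine
angiography alone: the contrast time–intensity curve is extracted in the
stenotic region and in an equal-sized region placed upstream along the
vessel, each is integrated over the acquisition, and the index is the ratio

    CCIA = AUC_stenotic / AUC_proximal.

By the Stewart–Hamilton indicator-dilution relation (flow = injected amount
divided by the concentration–time integral), an AUC ratio between two
territories fed by the same injection is an inverse flow ratio, so a low
CCIA marks a hemodynamically severe lesion. Contrast *attenuates* X-ray
images, so the signal is inverted attenuation: baseline minus frame mean,
clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RoiError, SignalError, ValidationError
from .io_stack import FrameStack, RoiSpec

__all__ = [
    "TimeIntensityCurve",
    "Injection",
    "CciaResult",
    "extract_signal",
    "auc",
    "ccia",
    "stewart_hamilton_flow",
    "define_proximal_roi",
    "compute_ccia_from_stack",
]


@dataclass
class TimeIntensityCurve:
    """Baseline-subtracted contrast signal within one ROI.

    ``values`` are in inverted-attenuation units (>= 0, higher = more
    contrast); ``baseline_level`` is the pre-injection per-pixel mean the
    signal is referenced to.
    """

    times: np.ndarray
    values: np.ndarray
    roi_pixel_count: int
    baseline_level: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValidationError("times and values lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("curve times must be strictly increasing")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("curve values must be finite and >= 0")


@dataclass
class Injection:
    """A contrast bolus: ``amount`` mL delivered at ``rate`` mL/s."""

    amount: float = 4.0
    rate: float = 16.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.amount <= 0 or self.rate <= 0:
            raise ValidationError("injection amount and rate must be > 0")

    @property
    def duration(self) -> float:
        return self.amount / self.rate


@dataclass
class CciaResult:
    """The CCIA index together with its ingredient AUCs."""

    auc_proximal: float
    auc_stenotic: float
    ccia: float
    proximal_curve: TimeIntensityCurve | None = None
    stenotic_curve: TimeIntensityCurve | None = None

    def __post_init__(self) -> None:
        for name in ("auc_proximal", "auc_stenotic", "ccia"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v}")


def extract_signal(stack: FrameStack, mask: np.ndarray,
                   baseline_frames: int) -> TimeIntensityCurve:
    """Extract the inverted-attenuation contrast curve within a mask.

    The baseline is the per-pixel mean over the mask across the first
    ``baseline_frames`` frames (which must precede the injection); the
    signal at each frame is ``max(0, baseline - frame mean over mask)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frames.shape[1:]:
        raise RoiError(
            f"mask shape {mask.shape} does not match frames {stack.frames.shape[1:]}")
    if not mask.any():
        raise RoiError("empty ROI mask")
    if not 1 <= baseline_frames < stack.n_frames:
        raise SignalError(
            f"baseline_frames must be in [1, {stack.n_frames - 1}], got {baseline_frames}")
    roi = stack.frames[:, mask]  # (n_frames, n_pixels)
    means = roi.mean(axis=1)
    baseline = float(means[:baseline_frames].mean())
    values = np.maximum(0.0, baseline - means)
    return TimeIntensityCurve(stack.times, values, int(mask.sum()), baseline)


def auc(curve: TimeIntensityCurve, t_start: float | None = None,
        t_end: float | None = None) -> float:
    """Trapezoidal integral of the curve over ``[t_start, t_end]``.

    Window edges falling between samples are handled by linear
    interpolation, so the integral is exact for piecewise-linear curves
    sampled at their breakpoints.
    """
    t, v = curve.times, curve.values
    if t_start is None:
        t_start = float(t[0])
    if t_end is None:
        t_end = float(t[-1])
    if not t_start < t_end:
        raise ValidationError(f"empty window [{t_start}, {t_end}]")
    if t_start < t[0] or t_end > t[-1]:
        raise ValidationError(
            f"window [{t_start}, {t_end}] outside curve support [{t[0]}, {t[-1]}]")
    inner = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inner], [t_end]))
    vv = np.concatenate(([np.interp(t_start, t, v)], v[inner],
                         [np.interp(t_end, t, v)]))
    if len(tt) < 2:
        raise ValidationError("fewer than 2 samples in window")
    return float(np.trapezoid(vv, tt))


def ccia(auc_proximal: float, auc_stenotic: float) -> CciaResult:
    """The CCIA index: stenotic AUC divided by proximal AUC.

    Values above 1 are legal (slight proximal-distal imbalance or noise);
    nothing is clamped and nothing is rounded internally.
    """
    if not (np.isfinite(auc_proximal) and auc_proximal > 0):
        raise ValidationError(f"proximal AUC must be > 0, got {auc_proximal}")
    if not (np.isfinite(auc_stenotic) and auc_stenotic > 0):
        raise ValidationError(f"stenotic AUC must be > 0, got {auc_stenotic}")
    return CciaResult(auc_proximal, auc_stenotic, auc_stenotic / auc_proximal)


def stewart_hamilton_flow(injection: Injection, curve_auc: float,
                          calibration_gain: float = 1.0) -> float:
    """Indicator-dilution flow estimate: injected amount over concentration AUC.

    ``calibration_gain`` converts image-signal units to concentration units
    (signal per unit concentration); the returned flow is in mL/s when the
    concentration is a volume fraction.
    """
    if not (np.isfinite(curve_auc) and curve_auc > 0):
        raise ValidationError(f"AUC must be > 0, got {curve_auc}")
    if calibration_gain <= 0:
        raise ValidationError("calibration_gain must be > 0")
    return injection.amount / (curve_auc / calibration_gain)


def _arc_coords(centerline: np.ndarray) -> np.ndarray:
    """Cumulative arc length (px) at each centerline point."""
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    return np.concatenate(([0.0], np.cumsum(seg)))


def _point_at_arc(centerline: np.ndarray, arc: np.ndarray,
                  s: float) -> np.ndarray:
    """Linear interpolation of the centerline at arc-length ``s``."""
    r = np.interp(s, arc, centerline[:, 0])
    c = np.interp(s, arc, centerline[:, 1])
    return np.array([r, c])


def define_proximal_roi(roi: RoiSpec, gap_mm: float = 10.0) -> np.ndarray:
    """Place the equal-sized proximal reference ROI upstream of the lesion.

    The stenotic mask is translated upstream along the centerline so that
    its downstream boundary sits ``gap_mm`` (default 10 mm) of centerline
    arc length upstream of the stenotic region's upstream boundary. The
    translation is a single displacement vector with nearest-pixel
    rounding, so the pixel count is preserved exactly.
    """
    mask, cl = roi.stenotic_mask, roi.centerline
    arc_px = _arc_coords(cl)
    # project each mask pixel onto its nearest centerline point
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows, cols]).astype(float)
    d2 = ((pts[:, None, :] - cl[None, :, :]) ** 2).sum(axis=2)
    s_pix = arc_px[np.argmin(d2, axis=1)]
    s_up, s_down = float(s_pix.min()), float(s_pix.max())
    gap_px = gap_mm / roi.calibration
    shift_px = (s_down - s_up) + gap_px  # lesion extent + clearance gap
    s_target = s_down - shift_px
    if s_target < arc_px[0]:
        raise RoiError(
            f"centerline too short: need arc {shift_px:.1f} px upstream of the lesion")
    disp = _point_at_arc(cl, arc_px, s_target) - _point_at_arc(cl, arc_px, s_down)
    dr, dc = int(round(disp[0])), int(round(disp[1]))
    shifted = np.zeros_like(mask)
    r2, c2 = rows + dr, cols + dc
    if (r2.min() < 0 or c2.min() < 0 or r2.max() >= mask.shape[0]
            or c2.max() >= mask.shape[1]):
        raise RoiError("translated proximal ROI exits the image bounds")
    shifted[r2, c2] = True
    return shifted


def compute_ccia_from_stack(stack: FrameStack, roi: RoiSpec,
                            baseline_frames: int,
                            window: tuple[float, float] | None = None,
                            gap_mm: float = 10.0) -> CciaResult:
    """Full CCIA pipeline on one stack: ROI placement, curves, AUCs, ratio.

    ``window`` is the integration interval in seconds; by default the whole
    record from the first post-baseline frame onward is integrated (the
    acquisition runs until the contrast has dissipated, so no
    return-to-baseline truncation is applied).
    """
    proximal_mask = define_proximal_roi(roi, gap_mm)
    cs = extract_signal(stack, roi.stenotic_mask, baseline_frames)
    cn = extract_signal(stack, proximal_mask, baseline_frames)
    t0, t1 = window if window is not None else (stack.times[0], stack.times[-1])
    auc_s = auc(cs, t0, t1)
    auc_n = auc(cn, t0, t1)
    result = ccia(auc_n, auc_s)
    result.proximal_curve = cn
    result.stenotic_curve = cs
    return result
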