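"""Read and write angiographic frame stacks, ECG/pressure traces, and ROIs.

All downstream modules operate on the in-memory domain types defined here;
this module is the only place that touches the filesystem. The canonical
on-disk stack format is a multi-page 16-bit TIFF with a JSON sidecar carrying
frame times and the mm-per-pixel calibration; multi-frame DICOM is supported
read-only. Pixel coordinates are 0-based ``(row, column)`` everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, RoiError, ValidationError

__all__ = [
    "FrameStack",
    "EcgTrace",
    "PressureTraces",
    "RoiSpec",
    "read_stack",
    "write_stack",
    "read_table",
    "read_ecg",
    "read_pressures",
    "read_roi",
    "write_roi",
    "load_table2",
]


@dataclass
class FrameStack:
    """An ordered stack of grayscale angiographic frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Non-negative grayscale intensities.
    times : ndarray, shape (n_frames,)
        Acquisition time of each frame in seconds, strictly increasing.
    mm_per_px : float
        Spatial calibration, millimetres per pixel (> 0).
    frame_rate : float
        Nominal frames per second.
    """

    frames: np.ndarray
    times: np.ndarray
    mm_per_px: float
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be 3-D (n, h, w); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] == 0:
            raise ValidationError("frame stack is empty")
        if len(self.times) != self.frames.shape[0]:
            raise ValidationError(
                f"{len(self.times)} timestamps for {self.frames.shape[0]} frames"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValidationError("intensities must be finite and >= 0")
        if not (np.isfinite(self.mm_per_px) and self.mm_per_px > 0):
            raise ValidationError(f"mm_per_px must be > 0, got {self.mm_per_px}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class EcgTrace:
    """A uniformly sampled single-lead ECG."""

    sample_times: np.ndarray
    voltage: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if len(self.sample_times) < 2:
            raise ValidationError("ECG needs at least 2 samples")
        if len(self.sample_times) != len(self.voltage):
            raise ValidationError("times and voltage lengths differ")
        dt = np.diff(self.sample_times)
        if np.any(dt <= 0):
            raise ValidationError("ECG sample times must be strictly increasing")
        if np.ptp(dt) > 1e-6:
            raise ValidationError("ECG sampling must be uniform (1e-6 s tolerance)")

    @property
    def duration(self) -> float:
        return float(self.sample_times[-1] - self.sample_times[0])


@dataclass
class PressureTraces:
    """Paired aortic (Pa) and distal (Pd) pressure recordings in mmHg.

    ``pv`` is the venous pressure constant of the full FFR expression
    (Pd - Pv)/(Pa - Pv); it defaults to 0, under which FFR reduces to Pd/Pa.
    """

    sample_times: np.ndarray
    pa: np.ndarray
    pd: np.ndarray
    pv: float = 0.0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.pa = np.asarray(self.pa, dtype=float)
        self.pd = np.asarray(self.pd, dtype=float)
        n = len(self.sample_times)
        if not (len(self.pa) == len(self.pd) == n):
            raise ValidationError("sample_times, pa, pd must have equal lengths")
        if np.any(self.pa <= 0):
            raise ValidationError("aortic pressure must be positive everywhere")


@dataclass
class RoiSpec:
    """A stenotic ROI mask plus a directed vessel centerline.

    The centerline is an ordered ``(row, col)`` pixel path directed from
    inflow (proximal) to outflow (distal); arc length along it is the
    coordinate used to place the equal-sized proximal ROI upstream.
    """

    stenotic_mask: np.ndarray
    centerline: np.ndarray
    calibration: float  # mm per pixel

    def __post_init__(self) -> None:
        self.stenotic_mask = np.asarray(self.stenotic_mask, dtype=bool)
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.stenotic_mask.ndim != 2 or not self.stenotic_mask.any():
            raise RoiError("stenotic mask must be a non-empty 2-D boolean mask")
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise RoiError("centerline needs at least 2 (row, col) points")
        if not (np.isfinite(self.calibration) and self.calibration > 0):
            raise ValidationError("calibration must be > 0 mm/px")
        # densify to ~1 px spacing so sparse polylines are checked fairly
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        arc = np.concatenate(([0.0], np.cumsum(seg)))
        n_dense = max(2, int(np.ceil(arc[-1])) + 1)
        s = np.linspace(0.0, arc[-1], n_dense)
        dense_r = np.interp(s, arc, self.centerline[:, 0])
        dense_c = np.interp(s, arc, self.centerline[:, 1])
        rows = np.clip(np.round(dense_r).astype(int), 0,
                       self.stenotic_mask.shape[0] - 1)
        cols = np.clip(np.round(dense_c).astype(int), 0,
                       self.stenotic_mask.shape[1] - 1)
        if not self.stenotic_mask[rows, cols].any():
            raise RoiError("centerline does not intersect the stenotic mask")


# ---------------------------------------------------------------------------
# frame stacks

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as multi-page 16-bit TIFF + JSON sidecar.

    Frame values are rounded to the nearest integer and must fit uint16;
    ``read_stack`` inverts the result bit-exactly for integer-valued data.
    """
    path = Path(path)
    data = np.round(stack.frames)
    if data.max() > np.iinfo(np.uint16).max:
        raise FormatError("intensities exceed the 16-bit range")
    try:
        tifffile.imwrite(path, data.astype(np.uint16))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise FormatError(f"cannot write {path}: {exc}") from exc
    sidecar = {
        "times": stack.times.tolist(),
        "mm_per_px": float(stack.mm_per_px),
        "frame_rate": float(stack.frame_rate),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_stack(path: str | Path, calibration: float | None = None,
               frame_rate: float = 30.0) -> FrameStack:
    """Read a multi-page TIFF (+ optional sidecar) or multi-frame DICOM.

    Timing comes from the sidecar / DICOM frame-time metadata when present,
    else ``index / frame_rate``. Calibration comes from metadata pixel
    spacing when present, else the ``calibration`` override; it is an error
    when neither source provides it.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path, calibration, frame_rate)
    if suffix in (".dcm", ".dicom") or suffix == "":
        return _read_dicom(path, calibration, frame_rate)
    # fall back on content sniffing
    try:
        return _read_tiff(path, calibration, frame_rate)
    except Exception:
        return _read_dicom(path, calibration, frame_rate)


def _read_tiff(path: Path, calibration: float | None,
               frame_rate: float) -> FrameStack:
    try:
        frames = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"expected grayscale pages, got shape {frames.shape}")
    times = None
    mm_per_px = calibration
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        times = np.asarray(meta["times"], dtype=float)
        if "mm_per_px" in meta:
            mm_per_px = float(meta["mm_per_px"])
        frame_rate = float(meta.get("frame_rate", frame_rate))
    if times is None:
        times = np.arange(frames.shape[0]) / frame_rate
    if mm_per_px is None:
        raise FormatError(
            f"{path}: no pixel-spacing metadata and no calibration override"
        )
    return FrameStack(frames.astype(float), times, mm_per_px, frame_rate)


def _read_dicom(path: Path, calibration: float | None,
                frame_rate: float) -> FrameStack:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        frames = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"unreadable DICOM {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError("expected a grayscale multi-frame DICOM")
    # frame timing: FrameTime is in ms; CineRate/RecommendedDisplayFrameRate in fps
    if getattr(ds, "FrameTime", None):
        frame_rate = 1000.0 / float(ds.FrameTime)
    elif getattr(ds, "CineRate", None):
        frame_rate = float(ds.CineRate)
    elif getattr(ds, "RecommendedDisplayFrameRate", None):
        frame_rate = float(ds.RecommendedDisplayFrameRate)
    times = np.arange(frames.shape[0]) / frame_rate
    mm_per_px = calibration
    spacing = getattr(ds, "PixelSpacing", None) or getattr(
        ds, "ImagerPixelSpacing", None)
    if spacing is not None:
        mm_per_px = float(spacing[0])
    if mm_per_px is None:
        raise FormatError(
            f"{path}: no PixelSpacing/ImagerPixelSpacing and no override")
    return FrameStack(frames.astype(float), times, mm_per_px, frame_rate)


# ---------------------------------------------------------------------------
# tables and traces

def read_table(path: str | Path, schema: dict[str, type] | None = None
               ) -> pd.DataFrame:
    """Read a CSV into a DataFrame, enforcing a ``{column: dtype}`` contract.

    Every column named in ``schema`` must be present; numeric columns must
    parse as numbers (empty cells become NaN/null, matching the "-" entries
    of the clinical results table).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        for col, typ in schema.items():
            if typ is float:
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError) as exc:
                    raise FormatError(
                        f"{path}: column {col!r} must be numeric") from exc
    return df


TABLE2_SCHEMA = {
    "patient": float, "vessel": str, "proximal": float, "stenotic": float,
    "distal": float, "ccia": float, "ifr": float, "ffr": float,
}


def load_table2() -> pd.DataFrame:
    """Load the packaged 15-patient clinical results table.

    Columns: patient, vessel, proximal/stenotic/distal contrast intensity,
    printed CCIA, iFR (null where not measured) and FFR.
    """
    path = Path(__file__).parent / "data" / "table2.csv"
    return read_table(path, TABLE2_SCHEMA)


def read_ecg(path: str | Path) -> EcgTrace:
    """Read an ECG CSV with columns ``time,voltage``."""
    df = read_table(path, {"time": float, "voltage": float})
    t = df["time"].to_numpy(float)
    if len(t) < 2:
        raise FormatError("ECG trace needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return EcgTrace(t, df["voltage"].to_numpy(float), fs)


def write_ecg(ecg: EcgTrace, path: str | Path) -> None:
    pd.DataFrame({"time": ecg.sample_times, "voltage": ecg.voltage}).to_csv(
        path, index=False)


def read_pressures(path: str | Path, pv: float = 0.0) -> PressureTraces:
    """Read a pressure CSV with columns ``time,pa,pd``."""
    df = read_table(path, {"time": float, "pa": float, "pd": float})
    return PressureTraces(df["time"].to_numpy(float), df["pa"].to_numpy(float),
                          df["pd"].to_numpy(float), pv)


def write_pressures(traces: PressureTraces, path: str | Path) -> None:
    pd.DataFrame({"time": traces.sample_times, "pa": traces.pa,
                  "pd": traces.pd}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROIs

def _mask_to_rle(mask: np.ndarray) -> list[list[int]]:
    flat = mask.ravel()
    edges = np.flatnonzero(np.diff(np.r_[0, flat.view(np.int8), 0]))
    starts, ends = edges[::2], edges[1::2]
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def _rle_to_mask(rle: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in rle:
        flat[start:start + length] = True
    return flat.reshape(shape)


def write_roi(roi: RoiSpec, path: str | Path) -> None:
    """Serialize an ROI as JSON (run-length-encoded mask + centerline)."""
    doc = {
        "shape": list(roi.stenotic_mask.shape),
        "mask_rle": _mask_to_rle(roi.stenotic_mask),
        "centerline": roi.centerline.tolist(),
        "mm_per_px": float(roi.calibration),
    }
    Path(path).write_text(json.dumps(doc))


def read_roi(path: str | Path) -> RoiSpec:
    """Read an ROI JSON: either an RLE mask or a polygon, plus centerline."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"unreadable ROI JSON {path}: {exc}") from exc
    try:
        shape = tuple(doc["shape"])
        centerline = np.asarray(doc["centerline"], dtype=float)
        calibration = float(doc["mm_per_px"])
        if "mask_rle" in doc:
            mask = _rle_to_mask(doc["mask_rle"], shape)
        elif "polygon" in doc:
            from skimage.draw import polygon

            poly = np.asarray(doc["polygon"], dtype=float)
            rr, cc = polygon(poly[:, 0], poly[:, 1], shape)
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
        else:
            raise KeyError("mask_rle or polygon")
    except KeyError as exc:
        raise FormatError(f"ROI JSON {path} missing field {exc}") from exc
    return RoiSpec(mask, centerline, calibration)
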