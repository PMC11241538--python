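"""Pressure-derived fractional flow reserve (FFR).

FFR = (mean Pd - Pv) / (mean Pa - Pv), with the means taken over whole
cardiac cycles in steady state. With the venous pressure Pv at its default
of 0 this reduces to the familiar Pd/Pa. The hyperemic resistances that
appear in the derivation cancel and are never computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SignalError, ValidationError
from .io_stack import PressureTraces

__all__ = ["FfrResult", "cycle_window", "ffr"]


@dataclass
class FfrResult:
    mean_pa: float
    mean_pd: float
    ffr: float
    n_cycles: int
    pv: float = 0.0


def cycle_window(traces: PressureTraces, period: float,
                 n_cycles: int = 10) -> PressureTraces:
    """Trim to the last ``n_cycles`` complete periods of the record.

    Averaging over the final cycles skips pump start-up transients; window
    boundaries are snapped to the samples nearest the period marks.
    """
    if period <= 0 or n_cycles < 1:
        raise ValidationError("period and n_cycles must be positive")
    t = traces.sample_times
    span = t[-1] - t[0]
    needed = n_cycles * period
    if span + 1e-9 < needed:
        raise SignalError(
            f"record spans {span:.3f} s < {n_cycles} cycles x {period} s")
    t_start = t[-1] - needed
    i0 = int(np.searchsorted(t, t_start - 1e-9))
    return PressureTraces(t[i0:], traces.pa[i0:], traces.pd[i0:], traces.pv)


def ffr(traces: PressureTraces, period: float = 1.0, n_cycles: int = 10,
        pv: float | None = None) -> FfrResult:
    """FFR from cycle-averaged pressures over the last ``n_cycles`` periods."""
    if pv is None:
        pv = traces.pv
    window = cycle_window(traces, period, n_cycles)
    mean_pa = float(np.mean(window.pa))
    mean_pd = float(np.mean(window.pd))
    if mean_pa <= pv:
        raise ValidationError(
            f"mean Pa ({mean_pa:.2f}) must exceed Pv ({pv:.2f})")
    value = (mean_pd - pv) / (mean_pa - pv)
    return FfrResult(mean_pa, mean_pd, value, n_cycles, pv)
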