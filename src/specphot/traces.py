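"""Ratiometric normalization, photobleaching baseline, and dF/F0.

The control fluorophore (tdTomato) is insensitive to the biology of
interest, so the sensor/control ratio r(t) = a_sensor(t)/a_control(t)
cancels common-mode artifacts — excitation power drift, fiber motion —
exactly.  Slow photobleaching is corrected by ordinary least squares on
the pre-stimulation window (default the first minute): the fitted line,
extrapolated over the whole session, is the theoretical baseline F0(t),
and the reported signal is dF/F0 % = 100 * (F(t) - F0(t)) / F0(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ProtocolSpec
from .unmix import CoefficientTraces

__all__ = [
    "RatioTrace",
    "BaselineFit",
    "DffTrace",
    "ratio_trace",
    "fit_baseline",
    "compute_dff",
]

_MIN_BASELINE_FRAMES = 10


@dataclass
class RatioTrace:
    """Sensor/control abundance ratio with a validity mask.

    Frames where the control channel drops below ``floor`` times its median
    are marked invalid (ratio undefined/unstable there) and excluded from
    all downstream fits and summaries.
    """

    frame_times: np.ndarray
    values: np.ndarray
    sensor_id: str
    control_id: str
    valid: np.ndarray

    @property
    def n_invalid(self) -> int:
        return int(np.sum(~self.valid))


@dataclass
class BaselineFit:
    """Straight-line baseline F0(t) = intercept + slope * t."""

    slope: float
    intercept: float
    fit_window: tuple
    r2: float
    residual_sd: float
    n_frames: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass
class DffTrace:
    """Percent fluorescence change relative to the fitted baseline."""

    frame_times: np.ndarray
    values: np.ndarray  # percent
    valid: np.ndarray
    source_id: str
    baseline: BaselineFit


def ratio_trace(
    traces: CoefficientTraces,
    sensor_id: str,
    control_id: str,
    floor: float = 0.1,
) -> RatioTrace:
    """Elementwise sensor/control ratio from unmixed coefficient traces."""
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must be in (0, 1)")
    for name in (sensor_id, control_id):
        if name not in traces.channels:
            raise KeyError(f"channel {name!r} not in {traces.channels}")
    sensor = traces.channel(sensor_id)
    control = traces.channel(control_id)
    threshold = floor * float(np.median(control))
    valid = control > max(threshold, 0.0)
    if not np.any(valid):
        raise ValueError(
            f"control channel {control_id!r} entirely below its floor"
        )
    values = np.full(sensor.shape, np.nan)
    values[valid] = sensor[valid] / control[valid]
    return RatioTrace(
        frame_times=traces.frame_times,
        values=values,
        sensor_id=sensor_id,
        control_id=control_id,
        valid=valid,
    )


def _trace_arrays(trace) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    """Accept a RatioTrace or a bare (times, values) single-channel trace."""
    if isinstance(trace, RatioTrace):
        name = f"{trace.sensor_id}/{trace.control_id}"
        return trace.frame_times, trace.values, trace.valid, name
    t, y = trace
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    return t, y, np.isfinite(y), "trace"


def fit_baseline(
    trace,
    window: tuple = (0.0, 60.0),
    protocol: ProtocolSpec | None = None,
) -> BaselineFit:
    """OLS straight line over the pre-stimulation window.

    ``trace`` is a :class:`RatioTrace` or a ``(frame_times, values)`` pair
    for a single-channel (coefficient-wise) fit.  If a protocol is given,
    the window must end at or before the first stimulation epoch.
    """
    t, y, valid, _ = _trace_arrays(trace)
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("baseline window must have positive length")
    if protocol is not None and protocol.epochs:
        first = protocol.epochs[0].start_s
        if hi > first + 1e-9:
            raise ValueError(
                f"baseline window [{lo}, {hi}] overlaps the first epoch "
                f"(starts at {first} s)"
            )
    mask = valid & (t >= lo) & (t < hi)
    n = int(np.sum(mask))
    if n < _MIN_BASELINE_FRAMES:
        raise ValueError(
            f"baseline window contains {n} valid frames "
            f"(needs >= {_MIN_BASELINE_FRAMES})"
        )
    tw, yw = t[mask], y[mask]
    slope, intercept = np.polyfit(tw, yw, 1)
    pred = intercept + slope * tw
    resid = yw - pred
    tss = float(np.sum((yw - yw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    return BaselineFit(
        slope=float(slope),
        intercept=float(intercept),
        fit_window=(lo, hi),
        r2=r2,
        residual_sd=float(np.std(resid, ddof=2)) if n > 2 else 0.0,
        n_frames=n,
    )


def compute_dff(trace, fit: BaselineFit) -> DffTrace:
    """dF/F0 in percent: 100 * (F - F0) / F0 with F0 the fitted line."""
    t, y, valid, name = _trace_arrays(trace)
    f0 = fit.predict(t)
    if np.any(f0 <= 0):
        raise ValueError(
            "fitted baseline crosses zero within the session "
            "(over-aggressive bleaching fit)"
        )
    values = np.full(y.shape, np.nan)
    values[valid] = 100.0 * (y[valid] - f0[valid]) / f0[valid]
    return DffTrace(
        frame_times=t,
        values=values,
        valid=valid,
        source_id=name,
        baseline=fit,
    )
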