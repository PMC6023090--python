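"""Biosensor performance metrics from constant-potential chronoamperometry.

A calibration run injects the analyte stepwise (typically at 1 min
intervals) while the working electrode sits at a fixed oxidative
potential.  Each injection produces a first-order current rise
i(t) = i_pre + di (1 - exp(-(t - t0)/tau)); the fitted asymptotes build
the calibration curve, whose linear-portion slope is the sensitivity,
the 3 sigma rule on the blank gives the limit of detection, and
t95 = tau ln 20 is the response time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import CalibrationError, ScheduleError
from .traces import AmperogramTrace

__all__ = [
    "StepSegment",
    "StepFit",
    "Calibration",
    "segment_steps",
    "fit_step",
    "response_time",
    "build_calibration",
    "selectivity_profile",
    "LN20",
]

#: t95 / tau for a first-order rise: time to reach 95% of the asymptote
LN20 = math.log(20.0)


@dataclass(frozen=True)
class StepSegment:
    """One injection's stretch of the trace, labelled with cumulative concentration."""

    time: np.ndarray
    current: np.ndarray
    t_start: float
    conc_before: float  # mol/L in the cell before this injection
    conc_after: float  # mol/L after
    analyte: str


@dataclass(frozen=True)
class StepFit:
    """Exponential-rise fit of one concentration step."""

    i_pre: float  # A
    delta_i_ss: float  # steady-state increment, A
    tau: float  # s
    t95: float  # s, = tau * ln 20
    r_squared: float
    conc_after: float  # mol/L
    converged: bool = True
    null_step: bool = False
    noise_sd: float = 0.0  # residual SD of the fit, A

    @property
    def i_ss(self) -> float:
        """Fitted steady-state current (asymptote, robust to truncated steps)."""
        return self.i_pre + self.delta_i_ss


@dataclass(frozen=True)
class Calibration:
    """Concentration-to-current calibration of one analyte."""

    points: tuple[tuple[float, float], ...]  # (mol/L, steady-state current above blank, A)
    sensitivity: float  # A per mol/L
    intercept: float  # A
    r_squared: float
    linear_range: tuple[float, float]  # mol/L
    lod: float  # mol/L, 3 sigma / sensitivity
    blank_sigma: float  # A
    t95_mean: float  # s
    t95_sd: float  # s
    analyte: str = "histamine"

    @property
    def sensitivity_uA_per_mM(self) -> float:
        return self.sensitivity * 1e6 * 1e-3


def segment_steps(trace: AmperogramTrace) -> list[StepSegment]:
    """Split a calibration trace into one segment per scheduled injection.

    Each segment spans its injection time up to the next injection (or
    the end of the trace) and is labelled with the cumulative analyte
    concentration after the addition.
    """
    if trace.schedule is None or len(trace.schedule) == 0:
        raise ScheduleError("trace carries no injection schedule")
    times = trace.schedule.times
    if times[0] < trace.time[0] or times[-1] >= trace.time[-1]:
        raise ScheduleError(
            f"injection times [{times[0]}, {times[-1]}] s must lie inside the trace "
            f"span [{trace.time[0]}, {trace.time[-1]}] s"
        )
    cum = trace.schedule.cumulative_conc
    segments = []
    for j, event in enumerate(trace.schedule.events):
        t_end = times[j + 1] if j + 1 < len(times) else np.inf
        mask = (trace.time >= event.time) & (trace.time < t_end)
        segments.append(
            StepSegment(
                time=trace.time[mask],
                current=trace.current[mask],
                t_start=event.time,
                conc_before=float(cum[j] - event.delta_conc),
                conc_after=float(cum[j]),
                analyte=event.analyte,
            )
        )
    return segments


def _rise(t: np.ndarray, i_pre: float, di: float, tau: float) -> np.ndarray:
    return i_pre + di * -np.expm1(-t / tau)


def fit_step(segment: StepSegment) -> StepFit:
    """Least-squares exponential-rise fit of one step; t95 = tau ln 20.

    A step whose fitted increment is below 3x the residual noise SD is
    flagged ``null_step``; a failed optimisation comes back with
    ``converged=False`` and NaN parameters rather than raising, so that
    callers can log and exclude it.
    """
    if len(segment.time) < 20:
        raise CalibrationError(
            f"segment at t={segment.t_start} s has {len(segment.time)} samples; need >= 20"
        )
    t = segment.time - segment.t_start
    y = segment.current
    span = float(t[-1] - t[0])
    tail = y[-max(5, len(y) // 10):].mean()
    p0 = (float(y[0]), float(tail - y[0]), max(span / 10.0, 1e-3))
    try:
        popt, _ = curve_fit(
            _rise,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 50.0 * span]),
            maxfev=10000,
        )
    except RuntimeError:
        return StepFit(
            i_pre=math.nan,
            delta_i_ss=math.nan,
            tau=math.nan,
            t95=math.nan,
            r_squared=0.0,
            conc_after=segment.conc_after,
            converged=False,
        )
    i_pre, di, tau = (float(p) for p in popt)
    resid = y - _rise(t, *popt)
    noise_sd = float(np.std(resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return StepFit(
        i_pre=i_pre,
        delta_i_ss=di,
        tau=tau,
        t95=tau * LN20,
        r_squared=max(0.0, r2),
        conc_after=segment.conc_after,
        converged=True,
        null_step=abs(di) < 3.0 * noise_sd,
        noise_sd=noise_sd,
    )


def response_time(
    step_fits: Sequence[StepFit],
    k: int = 3,
    linear_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Mean and SD of the first ``k`` usable t95 values (s).

    The convention averages three successive step changes within the
    linear range; non-converged and null steps never count.
    """
    usable = [
        f
        for f in step_fits
        if f.converged
        and not f.null_step
        and (linear_range is None or linear_range[0] <= f.conc_after <= linear_range[1])
    ]
    if len(usable) < k:
        raise CalibrationError(f"only {len(usable)} usable step fits; need {k}")
    t95 = np.array([f.t95 for f in usable[:k]])
    return float(t95.mean()), float(t95.std(ddof=1)) if k > 1 else 0.0


def _blank_stats(trace: AmperogramTrace, blank_window: float) -> tuple[float, float]:
    """Mean and SD of the linearly detrended pre-injection blank."""
    t_first = trace.schedule.times[0]
    t0 = max(trace.time[0], t_first - blank_window)
    mask = (trace.time >= t0) & (trace.time < t_first)
    if mask.sum() < 4:
        raise CalibrationError("blank window contains fewer than 4 samples")
    tb, yb = trace.time[mask], trace.current[mask]
    coeffs = np.polyfit(tb, yb, 1)
    resid = yb - np.polyval(coeffs, tb)
    return float(yb.mean()), float(np.std(resid))


def build_calibration(
    trace: AmperogramTrace,
    step_fits: Sequence[StepFit] | None = None,
    blank_window: float = 60.0,
    r2_min: float = 0.99,
    max_rel_dev: float = 0.05,
    k_t95: int = 3,
    analyte: str | None = None,
) -> Calibration:
    """Calibration curve, sensitivity, linear range, 3 sigma LOD and t95.

    Points are (cumulative concentration, fitted steady-state current
    minus the blank mean).  The linear range is the longest low-end
    contiguous run whose straight-line fit has R^2 >= ``r2_min`` with
    every point within ``max_rel_dev`` of the fit (deviations smaller
    than 3x the blank noise never disqualify a point); the sensitivity is
    the slope over that run and LOD = 3 * blank sigma / sensitivity.
    Non-converged fits are excluded; needs >= 4 usable points.
    """
    if trace.schedule is None or len(trace.schedule) == 0:
        raise ScheduleError("trace carries no injection schedule")
    if blank_window < 30.0:
        raise CalibrationError(f"blank window must span >= 30 s, got {blank_window}")
    if step_fits is None:
        step_fits = [fit_step(s) for s in segment_steps(trace)]
    blank_mean, blank_sigma = _blank_stats(trace, blank_window)

    usable = [f for f in step_fits if f.converged]
    if len(usable) < 4:
        raise CalibrationError(f"only {len(usable)} converged step fits; need >= 4")
    conc = np.array([f.conc_after for f in usable])
    resp = np.array([f.i_ss - blank_mean for f in usable])
    order = np.argsort(conc)
    conc, resp = conc[order], resp[order]
    usable = [usable[j] for j in order]
    if np.ptp(resp) == 0:
        raise CalibrationError("degenerate calibration: all steady-state currents equal")

    noise_floor = 3.0 * blank_sigma
    chosen = None
    for k in range(len(conc), 3, -1):
        x, y = conc[:k], resp[:k]
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
        dev_ok = np.all(
            np.abs(y - yhat) <= np.maximum(max_rel_dev * np.abs(yhat), noise_floor)
        )
        if r2 >= r2_min and dev_ok:
            chosen = (k, float(slope), float(intercept), r2)
            break
    if chosen is None:
        raise CalibrationError("no low-end contiguous run satisfies the linearity rule")
    k, slope, intercept, r2 = chosen
    if slope <= 0:
        raise CalibrationError(f"non-positive sensitivity: {slope:.3e} A/(mol/L)")
    linear_range = (float(conc[0]), float(conc[k - 1]))
    lod = 3.0 * blank_sigma / slope

    try:
        t95_mean, t95_sd = response_time(usable, k=k_t95, linear_range=linear_range)
    except CalibrationError:
        t95_mean, t95_sd = math.nan, math.nan

    label = analyte or (trace.schedule.events[0].analyte if trace.schedule else "histamine")
    return Calibration(
        points=tuple((float(c), float(r)) for c, r in zip(conc, resp)),
        sensitivity=slope,
        intercept=intercept,
        r_squared=r2,
        linear_range=linear_range,
        lod=lod,
        blank_sigma=blank_sigma,
        t95_mean=t95_mean,
        t95_sd=t95_sd,
        analyte=label,
    )


def selectivity_profile(calibrations: Mapping[str, Calibration]) -> dict[str, float]:
    """Sensitivities normalized to histamine = 1.0, in descending order.

    The amine-oxidase biosensor responds to several biogenic amines;
    reporting sensitivity relative to histamine makes sensors comparable.
    """
    key = next((k for k in calibrations if k.lower() == "histamine"), None)
    if key is None:
        raise CalibrationError(
            f"histamine calibration required for normalization; got {sorted(calibrations)}"
        )
    ref = calibrations[key].sensitivity
    if ref <= 0:
        raise CalibrationError("histamine sensitivity must be positive")
    rel = {k: c.sensitivity / ref for k, c in calibrations.items()}
    return dict(sorted(rel.items(), key=lambda kv: -kv[1]))
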