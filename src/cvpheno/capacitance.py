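"""Capacitance extraction from CV traces, media de-embedding, and peak-time
readout.

The core relation is ``i(t) = C * dv(t)/dt``: for a capacitive load the
measured current is proportional to the rate of change of the applied
potential, with the capacitance as the constant of proportionality.  Solving
pointwise gives a time-indexed capacitance estimate ``C(t) = i(t)/(dv/dt)``.
The quotient is ill-conditioned near sweep vertices where ``dv/dt`` passes
through zero, so samples close to a slope sign change (and samples whose
slope magnitude falls below a fraction of the maximum) are masked invalid.

De-embedding removes the background contribution of the cells-free media by
pointwise division: each sample-capacitance value is divided by the
time-matched media capacitance.  Both the dimensionless ratio and a rescaled
version (ratio times a reference media capacitance, in farads) are carried,
since reports in this field quote de-embedded values in µF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .waveform import CVTrace


class MaskingError(ValueError):
    """Raised when validity masking leaves no usable samples."""


class SupportError(ValueError):
    """Raised when two traces share no valid time support."""


@dataclass
class CapacitanceTrace:
    """Per-sample capacitance estimate with a validity mask.

    ``capacitance`` is NaN at invalid samples; ``meta`` inherits the source
    trace metadata plus the extraction settings.
    """

    time: np.ndarray
    capacitance: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.capacitance = np.asarray(self.capacitance, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.time.size == self.capacitance.size == self.valid.size):
            raise ValueError("time/capacitance/valid lengths differ")
        if not self.valid.any():
            raise ValueError("a capacitance trace needs at least one valid sample")
        if not np.isfinite(self.capacitance[self.valid]).all():
            raise ValueError("capacitance must be finite at valid samples")

    @property
    def values(self) -> np.ndarray:
        return self.capacitance

    def __len__(self) -> int:
        return self.time.size


@dataclass
class DeembeddedTrace:
    """Media-normalised capacitance: dimensionless ratio plus a rescaled
    (farad) version obtained by multiplying with the media capacitance at the
    reference time."""

    time: np.ndarray
    ratio: np.ndarray
    rescaled: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.rescaled = np.asarray(self.rescaled, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.time.size == self.ratio.size == self.rescaled.size == self.valid.size):
            raise ValueError("time/ratio/rescaled/valid lengths differ")
        if not self.valid.any():
            raise ValueError("a de-embedded trace needs at least one valid sample")
        ok = self.ratio[self.valid]
        if not (np.isfinite(ok).all() and (ok > 0).all()):
            raise ValueError("ratio must be finite and positive at valid samples")

    @property
    def values(self) -> np.ndarray:
        """Farad-scale values (the rescaled series)."""
        return self.rescaled

    def __len__(self) -> int:
        return self.time.size


def estimate_dvdt(trace: CVTrace) -> np.ndarray:
    """Per-sample voltage derivative: central differences, one-sided at the
    endpoints.  Exact (±s_rate) away from vertices for a triangular wave."""
    if len(trace) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(trace.voltage, trace.time)


def _vertex_indices(voltage: np.ndarray) -> np.ndarray:
    """Indices of sweep turning points, including both endpoints."""
    step_sign = np.sign(np.diff(voltage))
    turns = np.flatnonzero(step_sign[1:] != step_sign[:-1]) + 1
    return np.unique(np.concatenate([[0], turns, [voltage.size - 1]]))


def _smooth_valid_runs(values: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average applied independently within each contiguous
    valid run; the window shrinks at run edges."""
    out = values.copy()
    if window <= 1:
        return out
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    kernel = np.ones(window)
    for run in np.split(idx, breaks):
        x = values[run]
        num = np.convolve(x, kernel, mode="same")
        den = np.convolve(np.ones_like(x), kernel, mode="same")
        out[run] = num / den
    return out


def extract_capacitance(
    trace: CVTrace,
    vertex_exclusion: int = 3,
    min_slope_frac: float = 0.5,
    smooth_window: int = 5,
) -> CapacitanceTrace:
    """Estimate ``C(t) = i(t) / (dv/dt)(t)`` with vertex masking and smoothing.

    Parameters
    ----------
    vertex_exclusion
        Samples within this distance of a slope sign change (or trace end)
        are marked invalid.
    min_slope_frac
        Samples where ``|dv/dt|`` falls below this fraction of its maximum
        are marked invalid (guards the ill-conditioned quotient).
    smooth_window
        Odd width of the centered moving average applied within valid runs;
        0 or 1 disables smoothing.
    """
    if not 0 <= min_slope_frac < 1:
        raise ValueError("min_slope_frac must be in [0, 1)")
    if vertex_exclusion < 0:
        raise ValueError("vertex_exclusion must be non-negative")
    if smooth_window > 1 and smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd (or <= 1 to disable)")

    dvdt = estimate_dvdt(trace)
    max_slope = float(np.max(np.abs(dvdt)))
    if max_slope == 0:
        raise MaskingError("voltage is constant; no slope to divide by")
    valid = np.abs(dvdt) >= min_slope_frac * max_slope

    vertices = _vertex_indices(trace.voltage)
    idx = np.arange(len(trace))
    dist = np.min(np.abs(idx[:, None] - vertices[None, :]), axis=1)
    valid &= dist > vertex_exclusion

    if not valid.any():
        raise MaskingError(
            f"no valid samples left after masking (vertex_exclusion={vertex_exclusion}, "
            f"min_slope_frac={min_slope_frac}); relax the masking parameters"
        )

    cap = np.full(len(trace), np.nan)
    cap[valid] = trace.current[valid] / dvdt[valid]
    cap = _smooth_valid_runs(cap, valid, smooth_window)

    meta = {
        **trace.meta,
        "vertex_exclusion": vertex_exclusion,
        "min_slope_frac": min_slope_frac,
        "smooth_window": smooth_window,
    }
    return CapacitanceTrace(trace.time, cap, valid, meta=meta)


def find_peak_time(ctrace) -> float:
    """Time of the global maximum over valid samples; ties break earliest."""
    vals = np.where(ctrace.valid, ctrace.values, -np.inf)
    return float(ctrace.time[int(np.argmax(vals))])


def capacitance_at(ctrace, t: float, tolerance: float = 0.5) -> float:
    """Value at the valid sample nearest to ``t`` (within ``tolerance`` s)."""
    vt = ctrace.time[ctrace.valid]
    vv = ctrace.values[ctrace.valid]
    j = int(np.argmin(np.abs(vt - t)))
    if abs(vt[j] - t) > tolerance:
        raise ValueError(
            f"no valid sample within {tolerance} s of t={t} s "
            f"(nearest at {vt[j]:.6g} s)"
        )
    return float(vv[j])


def deembed(
    sample: CapacitanceTrace,
    media: CapacitanceTrace,
    reference_time: float | None = None,
    media_floor: float = 1e-15,
) -> DeembeddedTrace:
    """Divide a sample capacitance trace pointwise by the media trace.

    The media series is linearly interpolated between its valid samples onto
    the sample grid.  ``rescaled`` multiplies the ratio by the media
    capacitance at ``reference_time`` (default: the media trace's own peak
    time), restoring farad units.
    """
    tm = media.time[media.valid]
    cm = media.capacitance[media.valid]
    support = (sample.time >= tm[0]) & (sample.time <= tm[-1])
    valid = sample.valid & support
    if not valid.any():
        raise SupportError("sample and media traces share no valid time support")
    media_interp = np.interp(sample.time, tm, cm)
    low = np.abs(media_interp[valid]) < media_floor
    if low.any():
        t_bad = sample.time[valid][low][0]
        raise ValueError(
            f"media capacitance below floor ({media_floor:g} F) at t={t_bad:.6g} s; "
            "cannot de-embed"
        )
    ratio = np.full(len(sample), np.nan)
    ratio[valid] = sample.capacitance[valid] / media_interp[valid]

    if reference_time is None:
        reference_time = find_peak_time(media)
    c_ref = capacitance_at(media, reference_time, tolerance=np.inf)
    rescaled = ratio * c_ref

    meta = {
        **sample.meta,
        "deembed_reference_time_s": float(reference_time),
        "media_reference_capacitance_F": c_ref,
    }
    return DeembeddedTrace(sample.time, ratio, rescaled, valid, meta=meta)


# --------------------------------------------------------------------------
# delimited-text output for capacitance and de-embedded traces


def write_capacitance_csv(ctrace, sink) -> None:
    """Write a capacitance or de-embedded trace in the package CSV dialect.

    Columns are ``time_s, capacitance_F, valid`` for a
    :class:`CapacitanceTrace` and ``time_s, ratio, rescaled_F, valid`` for a
    :class:`DeembeddedTrace`; settings are echoed as ``#`` metadata lines.
    """
    from pathlib import Path

    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="\n") as fh:
            write_capacitance_csv(ctrace, fh)
        return
    for key in sorted(ctrace.meta):
        val = ctrace.meta[key]
        text = repr(float(val)) if isinstance(val, (float, np.floating)) else str(val)
        sink.write(f"# {key}={text}\n")
    if isinstance(ctrace, DeembeddedTrace):
        sink.write("time_s,ratio,rescaled_F,valid\n")
        for t, r, s, ok in zip(ctrace.time, ctrace.ratio, ctrace.rescaled, ctrace.valid):
            sink.write(f"{float(t)!r},{float(r)!r},{float(s)!r},{int(ok)}\n")
    else:
        sink.write("time_s,capacitance_F,valid\n")
        for t, c, ok in zip(ctrace.time, ctrace.capacitance, ctrace.valid):
            sink.write(f"{float(t)!r},{float(c)!r},{int(ok)}\n")
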