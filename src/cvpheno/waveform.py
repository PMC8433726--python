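"""Cyclic-voltammetry excitation waveforms and trace I/O.

A staircase cyclic-voltammetry (CV) sweep ramps the applied potential linearly
between two vertex potentials at a fixed scan rate, acquiring one sample per
potential step.  This module defines the excitation program
(:class:`VoltageProgram`), the sampled trace container (:class:`CVTrace`), the
waveform builder, and a plain-text interchange format for traces.

The CSV dialect is UTF-8, comma-delimited, ``.`` decimal, with a header row
naming ``time_s, voltage_V, current_A`` and optional ``#``-prefixed
``key=value`` metadata lines before the header.  Unit variants in the header
(``time_ms``, ``voltage_mV``, ``current_uA`` ...) are converted to SI on
ingest.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Union

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when a trace file violates the documented CSV dialect."""


#: relative tolerance for the integer-step-count check
_STEP_TOL = 1e-6

#: relative tolerance for time-grid uniformity
_GRID_TOL = 1e-9


@dataclass(frozen=True)
class VoltageProgram:
    """Triangular CV excitation definition.

    Parameters
    ----------
    v_min, v_max
        Vertex potentials in volts; the sweep turns around at these values.
    e_step
        Potential increment per acquisition step (V).
    s_rate
        Scan rate (V/s).  The step duration is ``e_step / s_rate``.
    start_vertex
        ``"high"`` starts at ``v_max`` descending, ``"low"`` at ``v_min``
        ascending.
    n_cycles
        Number of full up-down cycles.
    """

    v_min: float = -0.9
    v_max: float = 0.9
    e_step: float = 0.002
    s_rate: float = 0.04
    start_vertex: str = "high"
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if not self.v_max > self.v_min:
            raise ValueError(f"v_max ({self.v_max}) must exceed v_min ({self.v_min})")
        if not self.e_step > 0:
            raise ValueError(f"e_step must be positive, got {self.e_step}")
        if not self.s_rate > 0:
            raise ValueError(f"s_rate must be positive, got {self.s_rate}")
        if self.start_vertex not in ("low", "high"):
            raise ValueError(f"start_vertex must be 'low' or 'high', got {self.start_vertex!r}")
        if not (isinstance(self.n_cycles, (int, np.integer)) and self.n_cycles >= 1):
            raise ValueError(f"n_cycles must be a positive integer, got {self.n_cycles!r}")
        span = self.v_max - self.v_min
        n = span / self.e_step
        if n < 1 - _STEP_TOL:
            raise ValueError("potential span must cover at least one e_step")
        if abs(n - round(n)) > _STEP_TOL * max(n, 1.0):
            raise ValueError(
                f"(v_max - v_min)/e_step = {n:.9g} is not an integer within tolerance; "
                "choose e_step that divides the potential span"
            )

    @property
    def n_steps(self) -> int:
        """Number of potential steps per half-sweep."""
        return int(round((self.v_max - self.v_min) / self.e_step))

    @property
    def step_duration(self) -> float:
        """Duration of one potential step (s)."""
        return self.e_step / self.s_rate

    @property
    def half_sweep_duration(self) -> float:
        return self.n_steps * self.step_duration

    @property
    def n_samples(self) -> int:
        """Total samples including the initial point."""
        return 2 * self.n_steps * self.n_cycles + 1

    def to_dict(self) -> dict:
        return {
            "v_min": self.v_min,
            "v_max": self.v_max,
            "e_step": self.e_step,
            "s_rate": self.s_rate,
            "start_vertex": self.start_vertex,
            "n_cycles": self.n_cycles,
        }


def build_waveform(program: VoltageProgram) -> tuple[np.ndarray, np.ndarray]:
    """Sample the triangular excitation once per potential step.

    Returns
    -------
    time, voltage
        Arrays of length ``program.n_samples``.  The finite-difference slope
        between consecutive samples is ``±s_rate``; vertex samples sit at the
        turning potentials.
    """
    n = program.n_steps
    dt = program.step_duration
    k = np.arange(1, n + 1)
    down = program.v_max - k * program.e_step
    up = program.v_min + k * program.e_step
    if program.start_vertex == "high":
        cycle = np.concatenate([down, up])
        v0 = program.v_max
    else:
        cycle = np.concatenate([up, down])
        v0 = program.v_min
    voltage = np.concatenate([[v0], np.tile(cycle, program.n_cycles)])
    time = np.arange(voltage.size) * dt
    return time, voltage


@dataclass
class CVTrace:
    """A sampled CV trace: time (s), voltage (V), current (A) plus metadata.

    ``meta`` conventionally carries ``sample_id``, ``cell_type`` (one of
    ``THP1 | DC | MAC | MEDIA``), ``concentration`` (cells per 500 µL) and
    ``replicate``.
    """

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        n = self.time.size
        if not (self.voltage.size == n and self.current.size == n):
            raise ValueError(
                f"time/voltage/current lengths differ: {n}/{self.voltage.size}/{self.current.size}"
            )
        if n < 3:
            raise ValueError(f"a CV trace needs at least 3 samples, got {n}")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"time must be strictly increasing (violated at row {bad})")
        dt0 = self.time[-1] / (n - 1) if self.time[0] == 0 else np.mean(dt)
        if np.any(np.abs(dt - dt0) > _GRID_TOL * max(abs(dt0), 1e-300)):
            raise ValueError("time grid is not uniform within tolerance")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


# header-name -> (canonical name, multiplier to SI)
_COLUMN_UNITS = {
    "time_s": ("time", 1.0),
    "time_ms": ("time", 1e-3),
    "voltage_v": ("voltage", 1.0),
    "voltage_mv": ("voltage", 1e-3),
    "current_a": ("current", 1.0),
    "current_ma": ("current", 1e-3),
    "current_ua": ("current", 1e-6),
    "current_na": ("current", 1e-9),
}

Source = Union[str, Path, IO[str]]


def _parse_meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def read_cv_csv(source: Source) -> CVTrace:
    """Read a CV trace from the documented delimited-text dialect.

    ``#``-prefixed ``key=value`` lines become ``meta`` entries; the header
    must name a time, a voltage and a current column (unit suffixes are
    converted to SI).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_cv_csv(fh)
    meta: dict = {}
    body_lines: list[str] = []
    for raw in source:
        if raw.startswith("#"):
            stripped = raw[1:].strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                meta[key.strip()] = _parse_meta_value(val.strip())
            continue
        if raw.strip():
            body_lines.append(raw)
    if not body_lines:
        raise FormatError("no header row found")
    try:
        frame = pd.read_csv(io.StringIO("".join(body_lines)), float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas reports the offending row
        raise FormatError(f"malformed delimited text: {exc}") from exc
    columns: dict[str, np.ndarray] = {}
    for name in frame.columns:
        key = name.strip().lower()
        if key not in _COLUMN_UNITS:
            raise FormatError(
                f"unrecognised column {name!r}; expected time_s/voltage_V/current_A "
                "(or a documented unit variant)"
            )
        canonical, scale = _COLUMN_UNITS[key]
        if canonical in columns:
            raise FormatError(f"duplicate {canonical} column ({name!r})")
        values = pd.to_numeric(frame[name], errors="coerce").to_numpy(dtype=float)
        if np.isnan(values).any():
            bad = int(np.argmax(np.isnan(values))) + 2  # +1 header, +1 one-based
            raise FormatError(f"non-numeric value in column {name!r} at row {bad}")
        columns[canonical] = values * scale
    missing = {"time", "voltage", "current"} - set(columns)
    if missing:
        raise FormatError(f"missing column(s): {', '.join(sorted(missing))}")
    return CVTrace(columns["time"], columns["voltage"], columns["current"], meta=meta)


def _format_meta(meta: Mapping) -> list[str]:
    lines = []
    for key in sorted(meta):
        val = meta[key]
        if isinstance(val, (float, np.floating)):
            text = repr(float(val))
        else:
            text = str(val)
        lines.append(f"# {key}={text}")
    return lines


def write_cv_csv(trace: CVTrace, sink: Source) -> None:
    """Write a trace in the documented dialect; byte-deterministic output."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="\n") as fh:
            write_cv_csv(trace, fh)
        return
    for line in _format_meta(trace.meta):
        sink.write(line + "\n")
    sink.write("time_s,voltage_V,current_A\n")
    for t, v, i in zip(trace.time, trace.voltage, trace.current):
        sink.write(f"{float(t)!r},{float(v)!r},{float(i)!r}\n")
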