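"""Equivalent-circuit simulation of cell-suspension CV traces and synthetic
micrographs with exact ground truth.

Electrical model
----------------
The electrode/media system is a capacitor ``c_media`` (optionally behind a
series resistance ``r_series``).  Suspended cells add membrane capacitance in
parallel: each cell contributes ``c_spec * area`` where ``c_spec`` is the
specific membrane capacitance (~0.01 F/m² for biological membranes) and the
per-cell effective area is drawn log-normally around ``a_cell`` with
coefficient of variation ``area_cv``.  The total is

    C_tot = c_media + c_spec * sum(per-cell areas)

For ``r_series = 0`` the capacitive current is ``C_tot * dv/dt``; otherwise
the capacitor voltage follows ``r_series * C_tot * dv_c/dt = v - v_c``,
integrated per acquisition step with the exact exponential update for a
linear ramp (unconditionally stable, and exact because the staircase
excitation is piecewise linear).  A Gaussian-shaped cathodic (reduction) peak
centred at ``faradaic_peak_v`` is added on the negative-going branch only,
plus i.i.d. Gaussian current noise.

The per-cell *electrical* effective area is a lumped coupling parameter: it
absorbs electrode geometry and field-coverage effects and is calibrated so
that simulated totals sit in the sub-microfarad band typical of two-electrode
media measurements, while remaining proportional to the morphological cell
area (so larger cell types always contribute more capacitance).

Imaging model
-------------
:func:`synthesize_micrograph` rasterises non-overlapping cell silhouettes —
disks (round monocytes), star polygons with radial arms (dendritic cells) and
irregular low-eccentricity blobs (spread macrophages) — on a jittered grid
that guarantees a minimum background gap between objects, and records exact
per-object pixel areas as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from skimage import draw as _draw
from skimage import filters as _filters

from .waveform import CVTrace, VoltageProgram, build_waveform


class PlacementError(RuntimeError):
    """Raised when requested objects cannot be placed without overlap."""


@dataclass(frozen=True)
class SuspensionModel:
    """Equivalent-circuit ground truth for one suspension sample.

    All quantities are SI: capacitances in F, areas in m², currents in A,
    potentials in V, resistance in Ω.  ``n_cells`` is the count in the 500 µL
    sample volume.
    """

    c_media: float = 0.8e-6
    c_spec: float = 0.01
    a_cell: float = 1.5e-8
    area_cv: float = 0.2
    n_cells: int = 0
    r_series: float = 0.0
    faradaic_peak_v: float = -0.2
    faradaic_peak_i: float = 0.0
    faradaic_width: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_media > 0:
            raise ValueError("c_media must be positive")
        if not self.c_spec > 0:
            raise ValueError("c_spec must be positive")
        if not self.a_cell > 0:
            raise ValueError("a_cell must be positive")
        if self.area_cv < 0:
            raise ValueError("area_cv must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.r_series < 0:
            raise ValueError("r_series must be non-negative")
        if not self.faradaic_width > 0:
            raise ValueError("faradaic_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def expected_total_capacitance(self) -> float:
        """Mean total capacitance, before per-cell area sampling."""
        return self.c_media + self.n_cells * self.c_spec * self.a_cell


def _draw_cell_areas(model: SuspensionModel, rng: np.random.Generator) -> np.ndarray:
    """Log-normal per-cell areas with mean ``a_cell`` and CV ``area_cv``."""
    if model.n_cells == 0:
        return np.empty(0)
    sigma2 = math.log1p(model.area_cv**2)
    mu = math.log(model.a_cell) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=model.n_cells)


def _faradaic_current(model: SuspensionModel, voltage: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Cathodic reduction peak, Gaussian in potential, negative-going branch only."""
    if model.faradaic_peak_i == 0:
        return np.zeros_like(voltage)
    shape = np.exp(-0.5 * ((voltage - model.faradaic_peak_v) / model.faradaic_width) ** 2)
    return np.where(direction < 0, -model.faradaic_peak_i * shape, 0.0)


def _rc_current(voltage: np.ndarray, dt: float, r: float, c: float) -> np.ndarray:
    """Current through R into C driven by a piecewise-linear staircase ramp.

    Exact per-step exponential update of ``tau dv_c/dt = v - v_c`` with
    ``tau = r*c``; sampled at step ends.  The first sample carries zero
    current (the capacitor starts at the applied potential).
    """
    tau = r * c
    decay = math.exp(-dt / tau)
    slope = np.diff(voltage) / dt
    # exact update over one linear segment:
    #   v_c[k+1] = decay*v_c[k] + (1-decay)*(v[k+1] - m*tau) + decay*m*dt
    drive = (1.0 - decay) * (voltage[1:] - slope * tau) + decay * slope * dt
    v_c0 = voltage[0]
    zi = np.array([decay * v_c0])
    v_c_rest, _ = _signal.lfilter([1.0], [1.0, -decay], drive, zi=zi)
    current = np.empty_like(voltage)
    current[0] = 0.0
    current[1:] = (voltage[1:] - v_c_rest) / r
    return current


def simulate_trace(model: SuspensionModel, program: VoltageProgram) -> CVTrace:
    """Simulate one CV trace; identical (model, program) gives identical output.

    The realised total capacitance (after per-cell area sampling) is recorded
    in ``meta['c_tot_F']``.
    """
    time, voltage = build_waveform(program)
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    areas = _draw_cell_areas(model, rng)
    c_tot = model.c_media + model.c_spec * float(areas.sum())

    dv = np.diff(voltage)
    direction = np.empty_like(voltage)
    direction[1:] = np.sign(dv)
    direction[0] = direction[1]

    if model.r_series == 0:
        dvdt = direction * program.s_rate
        i_cap = c_tot * dvdt
    else:
        i_cap = _rc_current(voltage, program.step_duration, model.r_series, c_tot)

    i_far = _faradaic_current(model, voltage, direction)
    noise = rng.normal(0.0, model.noise_sd, size=voltage.size) if model.noise_sd > 0 else 0.0
    current = i_cap + i_far + noise

    meta = {
        "cell_type": "MEDIA" if model.n_cells == 0 else "UNKNOWN",
        "concentration": int(model.n_cells),
        "c_tot_F": c_tot,
        "c_media_F": model.c_media,
        "r_series_ohm": model.r_series,
        "s_rate_V_per_s": program.s_rate,
        "e_step_V": program.e_step,
        "seed": int(model.seed),
    }
    return CVTrace(time, voltage, current, meta=meta)


def _subseed(master: int, index: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_concentration_series(
    model: SuspensionModel,
    program: VoltageProgram,
    concentrations: Sequence[int],
    cell_type: str = "UNKNOWN",
) -> list[CVTrace]:
    """One trace per concentration; sub-seeds derive from the master seed.

    A zero concentration yields a cells-free trace labelled ``MEDIA``.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration list must not be empty")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    traces = []
    for idx, n in enumerate(concentrations):
        sub = replace(model, n_cells=int(n), seed=_subseed(model.seed, idx))
        trace = simulate_trace(sub, program)
        trace.meta["cell_type"] = "MEDIA" if n == 0 else cell_type
        trace.meta["replicate"] = idx
        trace.meta["sample_id"] = f"{cell_type}_c{int(n)}"
        traces.append(trace)
    return traces


# --------------------------------------------------------------------------
# synthetic micrographs


@dataclass(frozen=True)
class CellTypeProfile:
    """Morphological profile of one cell type for image synthesis."""

    name: str
    mean_area: float  # µm²
    shape_class: str  # round | branched | spread
    area_cv: float = 0.2

    def __post_init__(self) -> None:
        if not self.mean_area > 0:
            raise ValueError("mean_area must be positive")
        if self.shape_class not in ("round", "branched", "spread"):
            raise ValueError(f"unknown shape_class {self.shape_class!r}")
        if self.area_cv < 0:
            raise ValueError("area_cv must be non-negative")


#: Default morphologies: round suspended monocytes, branched dendritic cells,
#: large spread macrophages.  Mean spread areas increase THP1 < DC < MAC.
DEFAULT_PROFILES: dict[str, CellTypeProfile] = {
    "THP1": CellTypeProfile("THP1", mean_area=150.0, shape_class="round", area_cv=0.20),
    "DC": CellTypeProfile("DC", mean_area=300.0, shape_class="branched", area_cv=0.25),
    "MAC": CellTypeProfile("MAC", mean_area=450.0, shape_class="spread", area_cv=0.25),
}

#: Dimensionless electrical coupling: effective electrode-interface area per
#: cell relative to the morphological area.  Lumped sensitivity factor.
DEFAULT_COUPLING = 100.0


def electrical_model(
    profile: CellTypeProfile,
    coupling: float = DEFAULT_COUPLING,
    **overrides,
) -> SuspensionModel:
    """Suspension model whose per-cell area scales with the type morphology."""
    a_cell = profile.mean_area * 1e-12 * coupling  # µm² -> m², times coupling
    return SuspensionModel(a_cell=a_cell, area_cv=profile.area_cv, **overrides)


@dataclass
class SyntheticImage:
    """A synthetic micrograph with exact per-object ground truth."""

    pixels: np.ndarray
    truth_mask: np.ndarray
    truth_areas: pd.DataFrame  # columns: object_id, cell_type, area_px
    pixel_size: float  # µm per pixel
    seed: int


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _disk_footprint(area_px: float, rng: np.random.Generator):
    r = math.sqrt(area_px / math.pi)
    rr, cc = _draw.disk((0.0, 0.0), r)
    return rr, cc


def _rasterize_centered(x: np.ndarray, y: np.ndarray):
    """Rasterize a polygon given origin-centred float vertices.

    ``skimage.draw.polygon`` silently clips negative indices, so shift into a
    positive frame first and shift the integer pixel coords back.  Thin
    features (star-arm tips) can rasterize into detached pixels; only the
    largest 8-connected component is kept so every object is one component.
    """
    from skimage import measure as _measure

    off = int(math.ceil(-min(x.min(), y.min()))) + 1
    rr, cc = _draw.polygon(y + off, x + off)
    side = int(max(rr.max(), cc.max())) + 1
    patch = np.zeros((side, side), dtype=bool)
    patch[rr, cc] = True
    labels = _measure.label(patch, connectivity=2)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = int(np.argmax(counts))
        rr, cc = np.nonzero(labels == keep)
    return rr - off, cc - off


def _star_footprint(area_px: float, rng: np.random.Generator):
    n_arms = int(rng.integers(5, 9))
    theta0 = rng.uniform(0, 2 * math.pi)
    angles = theta0 + np.arange(2 * n_arms) * math.pi / n_arms
    inner = rng.uniform(0.30, 0.45)
    radii = np.where(np.arange(2 * n_arms) % 2 == 0, 1.0, inner)
    x, y = radii * np.cos(angles), radii * np.sin(angles)
    scale = math.sqrt(area_px / _shoelace(x, y))
    return _rasterize_centered(x * scale, y * scale)


def _blob_footprint(area_px: float, rng: np.random.Generator):
    theta = np.linspace(0, 2 * math.pi, 32, endpoint=False)
    r = 1.0 + 0.12 * rng.uniform(-1, 1) * np.cos(2 * theta + rng.uniform(0, 2 * math.pi))
    r += 0.08 * rng.uniform(-1, 1) * np.cos(3 * theta + rng.uniform(0, 2 * math.pi))
    x, y = r * np.cos(theta), r * np.sin(theta)
    scale = math.sqrt(area_px / _shoelace(x, y))
    return _rasterize_centered(x * scale, y * scale)


_FOOTPRINTS = {"round": _disk_footprint, "branched": _star_footprint, "spread": _blob_footprint}


def synthesize_micrograph(
    profiles: Iterable[CellTypeProfile],
    counts: Mapping[str, int],
    image_shape: tuple[int, int] | None = None,
    pixel_size: float = 0.5,
    seed: int = 0,
    foreground: float = 0.85,
    background: float = 0.15,
    contrast_margin: float = 0.3,
    noise_sd: float = 0.0,
    blur_sigma: float = 0.0,
    min_gap: int = 2,
) -> SyntheticImage:
    """Render non-overlapping cell silhouettes with exact pixel-area truth.

    Objects are placed on a shuffled jittered grid whose cell size exceeds
    twice the largest object extent plus ``min_gap``, so objects can never
    touch (guaranteeing that 8-connected labelling separates them).  If
    ``image_shape`` is None a square canvas just large enough is chosen.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if foreground - background < contrast_margin:
        raise ValueError(
            f"foreground/background contrast {foreground - background:.3g} is below "
            f"the required margin {contrast_margin:.3g}"
        )
    profiles = list(profiles)
    by_name = {p.name: p for p in profiles}
    unknown = set(counts) - set(by_name)
    if unknown:
        raise ValueError(f"counts given for unknown profiles: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # sample every footprint first so the required grid pitch is known
    footprints: list[tuple[str, np.ndarray, np.ndarray]] = []
    for profile in profiles:  # fixed profile order keeps this deterministic
        n = int(counts.get(profile.name, 0))
        sigma2 = math.log1p(profile.area_cv**2)
        mu = math.log(profile.mean_area) - sigma2 / 2.0
        for _ in range(n):
            area_um2 = rng.lognormal(mu, math.sqrt(sigma2))
            area_px = area_um2 / pixel_size**2
            rr, cc = _FOOTPRINTS[profile.shape_class](area_px, rng)
            footprints.append((profile.name, rr, cc))

    n_obj = len(footprints)
    if n_obj == 0:
        shape = image_shape or (256, 256)
        pixels = np.full(shape, background)
        mask = np.zeros(shape, dtype=np.int32)
        truth = pd.DataFrame(columns=["object_id", "cell_type", "area_px"])
        return _finish_image(pixels, mask, truth, pixel_size, seed, rng, noise_sd, blur_sigma)

    extents = [max(int(np.abs(rr).max()), int(np.abs(cc).max())) + 1 for _, rr, cc in footprints]
    pitch = 2 * (max(extents) + min_gap)
    if image_shape is None:
        side = math.ceil(math.sqrt(n_obj))
        image_shape = (side * pitch + min_gap, side * pitch + min_gap)
    grid_rows = image_shape[0] // pitch
    grid_cols = image_shape[1] // pitch
    capacity = grid_rows * grid_cols
    if n_obj > capacity:
        raise PlacementError(
            f"cannot place {n_obj} objects: image {image_shape} holds at most "
            f"{capacity} objects of extent {max(extents)} px with gap {min_gap} px; "
            "enlarge the image or reduce counts"
        )
    slots = rng.permutation(capacity)[:n_obj]

    pixels = np.full(image_shape, background)
    mask = np.zeros(image_shape, dtype=np.int32)
    records = []
    half_gap = min_gap / 2.0
    for obj_id, ((name, rr, cc), ext, slot) in enumerate(zip(footprints, extents, slots), start=1):
        gr, gc = divmod(int(slot), grid_cols)
        lo = ext + half_gap
        hi = pitch - ext - half_gap
        r0 = gr * pitch + int(round(rng.uniform(lo, hi)))
        c0 = gc * pitch + int(round(rng.uniform(lo, hi)))
        rows, cols = rr + r0, cc + c0
        mask[rows, cols] = obj_id
        pixels[rows, cols] = foreground
        records.append({"object_id": obj_id, "cell_type": name, "area_px": int(rr.size)})

    truth = pd.DataFrame.from_records(records)
    counted = np.bincount(mask.ravel())[1:]
    if not np.array_equal(counted, truth["area_px"].to_numpy()):
        raise AssertionError("ground-truth bookkeeping violated (overlapping objects)")
    return _finish_image(pixels, mask, truth, pixel_size, seed, rng, noise_sd, blur_sigma)


def _finish_image(pixels, mask, truth, pixel_size, seed, rng, noise_sd, blur_sigma) -> SyntheticImage:
    if blur_sigma > 0:
        pixels = _filters.gaussian(pixels, sigma=blur_sigma, preserve_range=True)
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    return SyntheticImage(pixels, mask, truth, pixel_size, seed)
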