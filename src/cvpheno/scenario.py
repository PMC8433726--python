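"""End-to-end scenario orchestration: simulate a dilution series per cell
type, extract and de-embed capacitance, build concentration responses,
summarize and classify, and run the imaging verification arm — all
deterministically from one master seed.

The default configuration mirrors the study conditions this package
emulates: a −0.9→0.9 V staircase sweep with 2 mV steps at 0.04 V/s,
concentrations 10…10⁵ cells per 500 µL plus a cells-free media sample,
media capacitance near 0.8 µF, a cathodic reduction peak at −0.2 V, current
noise at 2 % of the media capacitive amplitude, and 200 imaged cells per
type.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import capacitance as _cap
from . import imaging as _imaging
from . import phenotyping as _pheno
from . import simulate as _sim
from .waveform import VoltageProgram, write_cv_csv

log = logging.getLogger("cvpheno")


@dataclass
class CellTypeSettings:
    """Per-type electrical + morphological configuration."""

    profile: _sim.CellTypeProfile
    coupling: float = _sim.DEFAULT_COUPLING


@dataclass
class RunConfig:
    """Validated configuration for one end-to-end run."""

    program: VoltageProgram = field(default_factory=VoltageProgram)
    cell_types: dict[str, CellTypeSettings] = field(
        default_factory=lambda: {
            name: CellTypeSettings(profile=profile)
            for name, profile in _sim.DEFAULT_PROFILES.items()
        }
    )
    concentrations: tuple[int, ...] = (10, 100, 1_000, 10_000, 100_000)
    c_media: float = 0.8e-6  # F
    c_spec: float = 0.01  # F/m²
    r_series: float = 100.0  # Ω
    noise_frac: float = 0.02  # current noise s.d. as a fraction of c_media*s_rate
    faradaic_peak_v: float = -0.2  # V
    faradaic_peak_i: float = 1.0e-8  # A
    faradaic_width: float = 0.05  # V
    vertex_exclusion: int = 3
    min_slope_frac: float = 0.5
    smooth_window: int = 5
    peak_policy: str | float = "median"
    k_lowest: int = 3
    alpha: float = 0.05
    cells_per_type_imaged: int = 200
    pixel_size: float = 0.5  # µm/px
    image_noise_sd: float = 0.02
    image_blur_sigma: float = 0.0
    min_object_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            raise ValueError("at least one cell type is required")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if not 0 <= self.noise_frac:
            raise ValueError("noise_frac must be non-negative")
        if self.k_lowest < 1:
            raise ValueError("k_lowest must be positive")
        if self.cells_per_type_imaged < 2:
            raise ValueError("need at least 2 imaged cells per type")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["program"] = self.program.to_dict()
        d["cell_types"] = {
            name: {
                "mean_area_um2": ct.profile.mean_area,
                "shape_class": ct.profile.shape_class,
                "area_cv": ct.profile.area_cv,
                "coupling": ct.coupling,
            }
            for name, ct in self.cell_types.items()
        }
        d["concentrations"] = list(self.concentrations)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "program" in data:
            data["program"] = VoltageProgram(**data["program"])
        if "cell_types" in data:
            types = {}
            for name, spec in data["cell_types"].items():
                spec = dict(spec)
                coupling = spec.pop("coupling", _sim.DEFAULT_COUPLING)
                profile = _sim.CellTypeProfile(
                    name=name,
                    mean_area=spec["mean_area_um2"],
                    shape_class=spec["shape_class"],
                    area_cv=spec.get("area_cv", 0.2),
                )
                types[name] = CellTypeSettings(profile=profile, coupling=coupling)
            data["cell_types"] = types
        if "concentrations" in data:
            data["concentrations"] = tuple(int(c) for c in data["concentrations"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # -- derived pieces ----------------------------------------------------

    @property
    def noise_sd(self) -> float:
        """Current noise s.d. in A (fraction of the media capacitive amplitude)."""
        return self.noise_frac * self.c_media * self.program.s_rate

    def model_for(self, name: str, seed: int) -> _sim.SuspensionModel:
        ct = self.cell_types[name]
        return _sim.electrical_model(
            ct.profile,
            coupling=ct.coupling,
            c_media=self.c_media,
            c_spec=self.c_spec,
            r_series=self.r_series,
            noise_sd=self.noise_sd,
            faradaic_peak_v=self.faradaic_peak_v,
            faradaic_peak_i=self.faradaic_peak_i,
            faradaic_width=self.faradaic_width,
            seed=seed,
        )


@dataclass
class ScenarioResult:
    summary: _pheno.PhenotypeSummary
    classification: _pheno.ClassificationResult
    responses: dict[str, _pheno.ConcentrationResponse]
    monotonicity: dict[str, _pheno.MonotonicityResult]
    pairwise_capacitance: dict[tuple[str, str], _pheno.TTestResult]
    area_comparison: _imaging.AreaComparison
    outdir: Path | None


def _type_seed(master: int, kind: str, index: int) -> int:
    offset = {"electrical": 0, "imaging": 1000}[kind]
    ss = np.random.SeedSequence(master, spawn_key=(offset + index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_electrical_arm(config: RunConfig):
    """Simulate, extract, de-embed and build a response per cell type.

    Returns ``(responses, deembedded, monotonicity)`` keyed by type name.
    The concentration series of each type includes its own cells-free media
    trace (concentration 0) used for de-embedding.
    """
    responses: dict[str, _pheno.ConcentrationResponse] = {}
    deembedded: dict[str, list[_cap.DeembeddedTrace]] = {}
    monotonicity: dict[str, _pheno.MonotonicityResult] = {}
    names = sorted(config.cell_types)
    for idx, name in enumerate(names):
        model = config.model_for(name, seed=_type_seed(config.seed, "electrical", idx))
        series = _sim.simulate_concentration_series(
            model, config.program, (0, *config.concentrations), cell_type=name
        )
        extracted = [
            _cap.extract_capacitance(
                t,
                vertex_exclusion=config.vertex_exclusion,
                min_slope_frac=config.min_slope_frac,
                smooth_window=config.smooth_window,
            )
            for t in series
        ]
        media_ct = extracted[0]
        de_traces = [_cap.deembed(ct, media_ct) for ct in extracted[1:]]
        deembedded[name] = de_traces
        response = _pheno.build_concentration_response(de_traces, peak_policy=config.peak_policy)
        responses[name] = response
        if len(response) < 2:
            continue
        mono = _pheno.check_monotonicity(response)
        monotonicity[name] = mono
        if not mono.monotone:
            log.warning(
                "non-monotone concentration response for %s at step %s "
                "(often pipetting/sample-prep error at high concentration)",
                name, mono.first_violation,
            )
    return responses, deembedded, monotonicity


def run_imaging_arm(config: RunConfig):
    """Synthesize one micrograph per type, segment, and compare areas.

    Returns ``(area_comparison, images, segmentations)``.
    """
    areas_by_type: dict[str, np.ndarray] = {}
    images: dict[str, _sim.SyntheticImage] = {}
    segs: dict[str, _imaging.SegmentationResult] = {}
    names = sorted(config.cell_types)
    for idx, name in enumerate(names):
        profile = config.cell_types[name].profile
        image = _sim.synthesize_micrograph(
            [profile],
            {name: config.cells_per_type_imaged},
            pixel_size=config.pixel_size,
            seed=_type_seed(config.seed, "imaging", idx),
            noise_sd=config.image_noise_sd,
            blur_sigma=config.image_blur_sigma,
        )
        seg = _imaging.segment_cells(image.pixels, min_object_size=config.min_object_size)
        areas_by_type[name] = _imaging.measure_areas(seg, config.pixel_size)
        images[name] = image
        segs[name] = seg
    comparison = _imaging.compare_type_areas(areas_by_type, alpha=config.alpha)
    return comparison, images, segs


def run_scenario(config: RunConfig, outdir=None) -> ScenarioResult:
    """Full pipeline: electrical arm, phenotype summary/classification,
    pairwise tests, imaging arm, and (optionally) an output bundle."""
    responses, deembedded, monotonicity = run_electrical_arm(config)
    summary = _pheno.summarize_phenotype(responses, k_lowest=config.k_lowest)
    classification = _pheno.classify_by_size_order(summary)

    pairwise: dict[tuple[str, str], _pheno.TTestResult] = {}
    names = sorted(responses) if config.k_lowest >= 2 else []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = _pheno.student_t_two_tailed(
                responses[a].capacitance[: config.k_lowest],
                responses[b].capacitance[: config.k_lowest],
                alpha=config.alpha,
            )

    comparison, images, segs = run_imaging_arm(config)

    out_path = Path(outdir) if outdir is not None else None
    if out_path is not None:
        _write_bundle(out_path, config, responses, deembedded, monotonicity,
                      summary, classification, pairwise, comparison, images, segs)

    return ScenarioResult(
        summary=summary,
        classification=classification,
        responses=responses,
        monotonicity=monotonicity,
        pairwise_capacitance=pairwise,
        area_comparison=comparison,
        outdir=out_path,
    )


def result_to_dict(result: ScenarioResult) -> dict:
    """JSON-ready summary of a scenario run (µF-scale human units)."""
    return {
        "phenotype": {
            name: {
                "mean_uF": s.mean * 1e6,
                "sem_uF": s.sem * 1e6,
                "n": s.n,
                "rank": s.rank,
                "concentrations_used": list(s.concentrations_used),
                "label": result.classification.assignments.get(name),
                "monotone_response": (
                    bool(result.monotonicity[name].monotone)
                    if name in result.monotonicity else None
                ),
            }
            for name, s in result.summary.stats.items()
        },
        "classification": {
            "inconclusive": result.classification.inconclusive,
            "reason": result.classification.reason,
            "assignments": result.classification.assignments,
        },
        "pairwise_capacitance_t": {
            f"{a}_vs_{b}": {"t": r.t, "df": r.df, "p": r.p, "significant": r.significant}
            for (a, b), r in result.pairwise_capacitance.items()
        },
        "imaging": {
            "ordering": list(result.area_comparison.ordering),
            "stats": {
                name: {"mean_um2": s.mean, "sem_um2": s.sem, "n": s.n}
                for name, s in result.area_comparison.stats.items()
            },
            "pairwise_t": {
                f"{a}_vs_{b}": {"t": r.t, "df": r.df, "p": r.p, "significant": r.significant}
                for (a, b), r in result.area_comparison.pairwise.items()
            },
        },
    }


def _write_bundle(outdir: Path, config, responses, deembedded, monotonicity,
                  summary, classification, pairwise, comparison, images, segs) -> None:
    import imageio.v3 as iio

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "capacitance").mkdir(exist_ok=True)
    (outdir / "traces").mkdir(exist_ok=True)
    (outdir / "images").mkdir(exist_ok=True)

    config.to_yaml(outdir / "config.yaml")

    # regenerate raw traces for the bundle (same seeds as the analysis pass)
    names = sorted(config.cell_types)
    for idx, name in enumerate(names):
        model = config.model_for(name, seed=_type_seed(config.seed, "electrical", idx))
        series = _sim.simulate_concentration_series(
            model, config.program, (0, *config.concentrations), cell_type=name
        )
        for trace in series:
            write_cv_csv(trace, outdir / "traces" / f"{trace.meta['sample_id']}.csv")
        for de in deembedded[name]:
            conc = de.meta["concentration"]
            _cap.write_capacitance_csv(de, outdir / "capacitance" / f"{name}_c{conc}_deembedded.csv")

    for name, image in images.items():
        lo, hi = image.pixels.min(), image.pixels.max()
        scaled = ((image.pixels - lo) / max(hi - lo, 1e-12) * 255).astype(np.uint8)
        iio.imwrite(outdir / "images" / f"{name}.png", scaled)
        mask8 = (segs[name].labels > 0).astype(np.uint8) * 255
        iio.imwrite(outdir / "images" / f"{name}_mask.png", mask8)
        image.truth_areas.to_csv(outdir / "images" / f"{name}_truth.csv", index=False)

    result = ScenarioResult(summary, classification, responses, monotonicity,
                            pairwise, comparison, None)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result_to_dict(result), fh, indent=2, sort_keys=True)
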