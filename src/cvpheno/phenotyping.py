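"""Concentration–response analysis and size-order phenotype classification.

Capacitance readings taken at a common reference time (the median of
per-trace peak times by default, or a user-fixed time) are assembled into a
concentration response per cell type.  Averaging the readings at the lowest
``k`` concentrations gives one mean ± SEM per type; because membrane
capacitance is proportional to cell surface area, sorting the means in
descending order assigns the size-ordered labels macrophage (MAC, largest)
> dendritic cell (DC) > THP-1 monocyte (smallest).

Group comparisons use the pooled-variance two-tailed Student's t-test at
α = 0.05 (Welch's correction available behind a flag).  Pairwise p-values
are reported raw, without multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats as _stats

from .capacitance import capacitance_at, find_peak_time

#: canonical size-ordered labels, largest mean capacitance first
SIZE_ORDER_LABELS = ("MAC", "DC", "THP1")


@dataclass
class ConcentrationResponse:
    """Capacitance readings at a reference time across a dilution series."""

    cell_type: str
    concentrations: np.ndarray  # cells per 500 µL, strictly increasing
    capacitance: np.ndarray  # F, one reading per concentration
    reference_time: float  # s

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.capacitance = np.asarray(self.capacitance, dtype=float)
        if self.concentrations.size != self.capacitance.size:
            raise ValueError("concentrations and capacitance lengths differ")
        if self.concentrations.size < 1:
            raise ValueError("a response needs at least one point")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return self.concentrations.size


class MonotonicityResult(NamedTuple):
    monotone: bool
    differences: np.ndarray
    first_violation: int | None  # index of the first decreasing step, if any


@dataclass
class TypeStats:
    mean: float  # F
    sem: float  # F
    n: int
    concentrations_used: tuple[float, ...]
    rank: int = 0  # 1 = largest mean


@dataclass
class PhenotypeSummary:
    """Per-type mean capacitance over the selected concentrations, with
    ranking (1 = largest mean)."""

    stats: dict[str, TypeStats]
    k_lowest: int


@dataclass
class ClassificationResult:
    assignments: dict[str, str]  # input key -> size-order label
    inconclusive: bool
    reason: str = ""


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool
    alpha: float
    degenerate: bool = False  # zero pooled variance edge case


def build_concentration_response(
    ctraces: Iterable,
    peak_policy: str | float = "median",
    tolerance: float = 0.5,
) -> ConcentrationResponse:
    """Read one capacitance value per concentration at a shared reference time.

    ``ctraces`` is an iterable of capacitance or de-embedded traces whose
    ``meta`` carries ``cell_type`` and ``concentration``.  ``peak_policy``
    is ``"median"`` (reference time = median of per-trace peak times) or an
    explicit time in seconds.
    """
    traces = list(ctraces)
    if not traces:
        raise ValueError("need at least one trace")
    types = {t.meta.get("cell_type", "UNKNOWN") for t in traces}
    if len(types) > 1:
        raise ValueError(f"mixed cell types in one response: {sorted(types)}")
    cell_type = types.pop()

    if peak_policy == "median":
        reference_time = float(np.median([find_peak_time(t) for t in traces]))
    elif isinstance(peak_policy, (int, float)):
        reference_time = float(peak_policy)
    else:
        raise ValueError(f"peak_policy must be 'median' or a time in s, got {peak_policy!r}")

    pairs = []
    for trace in traces:
        conc = float(trace.meta["concentration"])
        value = capacitance_at(trace, reference_time, tolerance=tolerance)
        pairs.append((conc, value))
    pairs.sort(key=lambda cv: cv[0])
    conc, cap = zip(*pairs)
    return ConcentrationResponse(cell_type, np.array(conc), np.array(cap), reference_time)


def check_monotonicity(response: ConcentrationResponse) -> MonotonicityResult:
    """True iff capacitance is non-decreasing across ordered concentrations."""
    if len(response) < 2:
        raise ValueError("monotonicity needs at least two points")
    diffs = np.diff(response.capacitance)
    bad = np.flatnonzero(diffs < 0)
    return MonotonicityResult(
        monotone=bad.size == 0,
        differences=diffs,
        first_violation=int(bad[0]) if bad.size else None,
    )


def summarize_phenotype(
    responses: Mapping[str, ConcentrationResponse] | Sequence[ConcentrationResponse],
    k_lowest: int = 3,
) -> PhenotypeSummary:
    """Mean ± SEM per type over the ``k_lowest`` smallest concentrations,
    ranked by descending mean.

    Averaging the low end of the dilution series avoids the pipetting-driven
    irreproducibility typical of the highest concentrations.
    """
    if not isinstance(responses, Mapping):
        responses = {r.cell_type: r for r in responses}
    if k_lowest < 1:
        raise ValueError("k_lowest must be at least 1")
    stats: dict[str, TypeStats] = {}
    for name, resp in responses.items():
        if len(resp) < k_lowest:
            raise ValueError(
                f"response {name!r} has {len(resp)} concentrations, fewer than k_lowest={k_lowest}"
            )
        used = resp.capacitance[:k_lowest]
        concs = tuple(resp.concentrations[:k_lowest])
        mean = float(np.mean(used))
        sem = float(np.std(used, ddof=1) / math.sqrt(k_lowest)) if k_lowest > 1 else 0.0
        stats[name] = TypeStats(mean=mean, sem=sem, n=k_lowest, concentrations_used=concs)
    # rank 1 = largest mean; ties broken by name for determinism
    ordered = sorted(stats, key=lambda k: (-stats[k].mean, k))
    for rank, name in enumerate(ordered, start=1):
        stats[name].rank = rank
    return PhenotypeSummary(stats=stats, k_lowest=k_lowest)


def classify_by_size_order(
    summary: PhenotypeSummary,
    rel_tol: float = 1e-9,
) -> ClassificationResult:
    """Assign MAC/DC/THP1 to three summarized samples by descending mean
    capacitance.  Means tied within ``rel_tol`` (relative) make the
    classification inconclusive rather than forcing an arbitrary order."""
    if len(summary.stats) != 3:
        raise ValueError(f"size-order classification needs exactly 3 samples, got {len(summary.stats)}")
    ordered = sorted(summary.stats.items(), key=lambda kv: (-kv[1].mean, kv[0]))
    means = [s.mean for _, s in ordered]
    for hi, lo in zip(means, means[1:]):
        scale = max(abs(hi), abs(lo), 1e-300)
        if abs(hi - lo) <= rel_tol * scale:
            return ClassificationResult(
                assignments={},
                inconclusive=True,
                reason=f"means {hi:.6g} and {lo:.6g} tie within relative tolerance {rel_tol:g}",
            )
    assignments = {name: label for (name, _), label in zip(ordered, SIZE_ORDER_LABELS)}
    return ClassificationResult(assignments=assignments, inconclusive=False)


def student_t_two_tailed(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Two-sample two-tailed Student's t-test (pooled variance by default).

    Degenerate inputs (zero variance in both groups) follow the convention
    t = 0, p = 1 for equal means and p = 0 (flagged) for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values only")
    df = float(a.size + b.size - 2)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0, significant=False, alpha=alpha, degenerate=True)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t=t, df=df, p=0.0, significant=True, alpha=alpha, degenerate=True)
    res = _stats.ttest_ind(a, b, equal_var=not welch)
    df = float(getattr(res, "df", df))
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), df=df, p=p, significant=p < alpha, alpha=alpha)
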