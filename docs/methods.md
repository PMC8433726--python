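# Methods

## Problem setting

Dendritic cells (DCs) and macrophages (MACs) differentiated in vitro from
THP-1 monocytes are hard to tell apart with surface-marker panels, because
the markers cross-react. A label-free alternative reads out cell size
instead: the membrane of a cell behaves as a capacitor with a roughly
constant specific capacitance (~1 µF/cm², i.e. 0.01 F/m²), so the total
capacitance added by a suspension of cells to an electrode/media system
scales with total membrane area. Since spread area orders
MAC > DC > THP-1, so should the capacitance — and that ordering is enough
to assign the three labels to three unlabeled samples.

`cvpheno` implements this measurement-analysis chain end to end on
synthetic data: no raw instrument traces are publicly deposited for this
kind of experiment, so the package pairs every analysis stage with a
generator whose ground truth is known exactly.

## Excitation and acquisition model

Staircase cyclic voltammetry between vertex potentials `v_min = −0.9 V` and
`v_max = 0.9 V`, potential increment `E_step = 2 mV`, scan rate
`S_rate = 0.04 V/s`, one sample per potential step (step duration
`E_step/S_rate = 50 ms`; 1801 samples and 90 s per cycle). The sweep starts
at the high vertex by default and is configurable. Sampled voltages follow
the ideal triangle; vertex samples sit exactly at the turning potentials.

Some instrument exports quote the scan rate in "s per step"; this package
standardizes on V/s and derives the step duration, which is the
dimensionally coherent reading.

## Equivalent-circuit suspension model

A sample is modelled as a single lumped capacitance

```
C_tot = c_media + c_spec * Σ_i A_i
```

with `c_media` the cells-free electrode/media capacitance (default 0.8 µF),
`c_spec = 0.01 F/m²`, and per-cell effective areas `A_i` drawn log-normally
with configurable mean and coefficient of variation (positive-support size
distribution). Optional elements:

- **Series resistance** `r_series` (default 100 Ω in scenarios). The
  capacitor branch follows `r_series·C_tot·dv_c/dt = v − v_c`. Because the
  staircase drive is piecewise linear, the ODE is integrated with the exact
  per-segment exponential update
  `v_c[k+1] = e·v_c[k] + (1−e)(v[k+1] − m·τ) + e·m·Δt` with
  `e = exp(−Δt/τ)`, `τ = r_series·C_tot` and `m` the segment slope. This is
  unconditionally stable and exact for this drive class, which matters
  because the acquisition step (50 ms) is typically much longer than τ
  (0.1 ms at 100 Ω and 1 µF) — a regime where explicit Euler would diverge.
  The update reproduces the closed-form RC ramp response, verified in the
  test suite against an independently coded recursion.
- **Faradaic reduction peak**: a Gaussian-in-potential cathodic current
  centred at −0.2 V (width 0.05 V, amplitude 10 nA by default), applied on
  the negative-going branch only. Only the peak location is empirically
  anchored; the Gaussian shape is a modelling choice.
- **Current noise**: i.i.d. Gaussian, default s.d. 2 % of the media
  capacitive amplitude `c_media·S_rate` (0.64 nA under defaults).

With `r_series = 0` the current is simply `C_tot·dv/dt` plus peak and
noise. Identical (model, program, seed) triples produce bit-identical
traces; dilution series derive per-trace sub-seeds from the master seed via
`numpy.random.SeedSequence` spawn keys.

### The electrical coupling factor

The per-cell *electrical* area is `coupling × morphological area`
(dimensionless coupling, default 100). A literal membrane-capacitance
budget for ≤10³ cells is orders of magnitude below the µF-scale per-sample
increments that two-electrode media measurements report at those
concentrations; the coupling is a lumped sensitivity factor (electrode
geometry, field coverage) that keeps the generated responses in the
reported 0.8–1.3 µF band while preserving strict proportionality between
capacitance and cell area — the relation the classification rests on.
Absolute microfarad values are explicitly not a target of this package;
only orderings and recovery properties are asserted.

## Capacitance extraction

`C(t) = i(t)/(dv/dt)(t)` with `dv/dt` from central differences (one-sided
at the endpoints; exact ±S_rate away from vertices for the ideal
triangle). The quotient is ill-conditioned where `dv/dt → 0`, so samples
are masked invalid when they are within `vertex_exclusion = 3` samples of
a slope sign change (or trace end) or when `|dv/dt|` falls below
`min_slope_frac = 0.5` of its maximum. A centred moving average
(`smooth_window = 5`, odd, applied within contiguous valid runs only)
suppresses noise without bleeding across vertices. Defaults were chosen
for the 1801-sample study grid; all three are parameters and are echoed
into output metadata.

The sign convention (current divided by signed slope) yields positive
capacitance on both branches for a passive load. The Faradaic peak biases
the estimate upward by exactly `i_f(v)/S_rate` on the cathodic branch and
leaves the anodic branch unbiased; medians over valid samples are robust
to this localized bias (<0.3 % error at the default amplitudes, verified
in the recovery tests).

## De-embedding

The media (cells-free) capacitance trace is divided out pointwise:
`ratio(t) = C_sample(t)/C_media(t)`, with the media linearly interpolated
between its valid samples if grids differ, and a hard error if the media
value falls below 1e−15 F anywhere it is needed. Because practitioners
plot de-embedded values in µF rather than as a dimensionless ratio, the
package also emits `rescaled = ratio × C_media(t_ref)` where `t_ref`
defaults to the media trace's own peak time. Media de-embedded against
itself gives ratio exactly 1 at every valid sample (floating-point exact:
interpolation at matching grid points returns node values).

De-embedding is deliberately a time-series operation, not a single scalar
division; the scalar peak-time reading is recovered by composing with
`capacitance_at`.

## Peak time and concentration response

The per-trace peak time is the argmax of the smoothed valid series (ties
break earliest). A dilution series is summarized by reading each trace at
one common reference time — the median of per-trace peak times by default,
or a user-fixed time (e.g. the canonical 29.2 s reading) — via
nearest-valid-sample lookup with a 0.5 s tolerance. In simulated traces
the capacitance maximum falls where the reduction peak crosses −0.2 V on
the descending branch (t ≈ 27.5 s on the default grid), so the peak-time
machinery is exercised even though a pure capacitor has no time structure.

The phenotype summary averages the readings at the `k_lowest = 3` smallest
concentrations (the high end of a dilution series is the part most
corrupted by pipetting error; non-monotone responses are detected and
logged as warnings, never silently dropped). Classification sorts the
three per-type means in descending order and assigns MAC/DC/THP1; means
tied within a relative tolerance of 1e−9 refuse classification with an
explicit inconclusive status rather than forcing an arbitrary order.

Group comparisons use the pooled-variance two-tailed Student's t
(`df = n_a + n_b − 2`), with Welch's form behind a flag. Zero-variance
edge cases are handled by convention before delegating to
`scipy.stats.ttest_ind`: equal-mean degenerate groups give t = 0, p = 1;
unequal-mean degenerate groups give p = 0 and are flagged. P-values are
reported raw — no multiple-testing correction is applied, and this is
stated in the output rather than hidden.

## Imaging arm

The verification arm measures cell areas directly. The generator
rasterizes three silhouette classes — disks (round suspended monocytes,
150 µm² mean), star polygons with 5–8 radial arms (dendritic cells,
300 µm²), and irregular low-eccentricity blobs (spread macrophages,
450 µm²) — at 0.5 µm/px with log-normal area scatter (CV 0.20–0.25).
Objects are placed on a shuffled, jittered grid whose pitch exceeds twice
the largest object extent plus a 2 px gap, so objects can never touch;
exceeding the grid capacity raises a placement error. Per-object pixel
areas are recorded exactly at rasterization time (polygon footprints keep
only their largest 8-connected component so one cell is always one
component). Foreground/background contrast is validated against a margin
before optional Gaussian blur and additive noise.

Segmentation is the simplest standard pipeline, fully logged: global Otsu
threshold (or a fixed value), 8-connected component labelling, removal of
components below `min_object_size = 30 px`, and `area = pixels ×
pixel_size²`. No watershed splitting is attempted — the generator
guarantees separation, and touching cells are a documented limitation for
real micrographs. Mean areas per type are compared exactly like the
capacitance means; on a joint synthetic experiment both arms should, and
in the acceptance runs do, produce the same MAC > DC > THP-1 ordering.

## What the generator does and does not emulate

Emulated: staircase CV geometry and amplitudes, media-dominated totals in
the sub-µF band, concentration- and cell-size-dependent capacitance
increments, a cathodic reduction peak, additive instrument noise,
non-overlapping cell silhouettes with type-specific shape and size.

Not emulated: electrode polarization physics and Debye-layer effects
(de-embedding is motivated by them but the generator does not model them),
Butler–Volmer kinetics, suspension inhomogeneity and incomplete
differentiation, pipetting error at high concentrations, touching or
overlapping cells, uneven illumination, and 3-D morphology. Passing tests
therefore demonstrate the correctness and robustness of the *analysis*
under the stated model, not the physical accuracy of any specific µF
value on a real instrument.

## Problem sizes

The seeded-ensemble checks use 100 runs for the ordering-recovery and
cross-arm properties (full 5-point dilution series per cell type
electrically; 25 cells per type in the joint imaging runs), 50 seeds × 4
capacitance levels for parameter recovery, 20 random models for the
de-embedding identity, and 200 cells per type for the single-image area
ordering — sizes chosen so the whole verification battery reruns from
scratch in well under a minute on one core.

## Known limitations

- The additive-capacitance model treats cells as independent parallel
  contributions; whether real cells restructure the double layer instead
  is not resolved by the data this emulates.
- The coupling factor is calibrated to a magnitude band, not fitted to any
  dataset; absolute capacitance values are not meaningful.
- Classification requires exactly three samples and assumes the three
  types are present once each.
- The CSV dialect stores full-precision floats via `repr`; files are
  byte-deterministic but larger than rounded exports.
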