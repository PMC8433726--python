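# cvpheno

Label-free phenotyping of innate immune cells from cyclic-voltammetry (CV)
capacitance, with a synthetic equivalent-circuit simulator and an imaging
verification arm.

## The problem

THP-1 monocytes differentiated in vitro into dendritic cells (DCs) and
macrophages (MACs) are notoriously hard to distinguish with surface-marker
panels, because the canonical markers (CD83, CD197, HLA-DR, CD1c, CD11c)
cross-react between the types. An electrical readout sidesteps markers
entirely: a cell membrane is a capacitor with near-universal specific
capacitance (~1 µF/cm²), so the capacitance a suspension adds to an
electrode/media system scales with total membrane area, and spread area
orders MAC > DC > THP-1. Measuring capacitance therefore measures size,
and size ordering assigns the labels.

`cvpheno` is for experimenters and method developers who want that analysis
chain as tested, reproducible code: the core computation

```
i(t) = C · dv(t)/dt   ⟹   C(t) = i(t) / (dv/dt)(t)
```

applied to staircase CV traces (−0.9→0.9 V, E_step 2 mV, scan rate
0.04 V/s), with validity masking near sweep vertices, media de-embedding by
pointwise division `C_sample(t)/C_media(t)`, peak-time readout of a dilution
series (10–10⁵ cells per 500 µL), mean ± SEM over the three lowest
concentrations, pooled-variance two-tailed Student's t-tests, and
size-order classification. Because raw potentiostat traces for this kind of
experiment are not publicly deposited, the package includes a first-class
synthetic arm — an equivalent-circuit trace simulator (media capacitance,
series resistance, a cathodic reduction peak at −0.2 V, calibrated noise)
and a micrograph generator with exact per-cell ground truth — so every
stage is verifiable against known truth.

## Worked example

```python
from cvpheno import RunConfig, run_scenario, result_to_dict

result = run_scenario(RunConfig(seed=42))
for name, s in sorted(result.summary.stats.items(), key=lambda kv: kv[1].rank):
    print(f"{name:5s} mean {s.mean*1e6:.4f} µF  SEM {s.sem*1e6:.4f} µF  "
          f"rank {s.rank}  -> {result.classification.assignments[name]}")
print("imaging ordering:", result.area_comparison.ordering)
```

prints

```
MAC   mean 1.3058 µF  SEM 0.1957 µF  rank 1  -> MAC
DC    mean 1.2352 µF  SEM 0.1265 µF  rank 2  -> DC
THP1  mean 1.1722 µF  SEM 0.0694 µF  rank 3  -> THP1
imaging ordering: ('MAC', 'DC', 'THP1')
```

Each line is one (blinded) sample's mean de-embedded capacitance over the
three lowest concentrations, its standard error, its rank by descending
mean, and the size-order label that rank implies — the largest-capacitance
sample is called MAC, the middle DC, the smallest THP1, here all three
correctly. The last line is the independent verification arm: mean
segmented cell areas from synthetic micrographs (200 cells per type by
default) sorted descending, agreeing with the electrical ordering.

The same scenario runs from the shell, writing traces, de-embedded series,
images, masks and a JSON summary:

```sh
cvpheno replicate --seed 42 --out run_out
```

Other subcommands (`simulate`, `extract`, `deembed`, `analyze`, `segment`)
expose the individual stages; see `cvpheno --help`. Model and physics
choices, defaults and limitations are documented in
[docs/methods.md](docs/methods.md).

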