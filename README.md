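# pfr — pressure-flow-regime analysis of neuromonitoring data

`pfr` classifies the relationship between cerebral perfusion pressure and
brain blood flow in multimodality neuromonitoring recordings, the kind
collected at the bedside of severe traumatic-brain-injury patients.
Pressure-guided neurocritical care implicitly assumes that flow follows the
perfusion-pressure gradient; this package makes that assumption testable,
interval by interval, and ships everything needed to exercise the method
without access to restricted clinical data.

## Who it is for

Researchers in computational physiology and neurocritical-care informatics
who work with monitored ABP and ICP waveforms (nominally 125 Hz),
thermodiffusion brain-tissue perfusion (1 Hz), and related channels, and who
want a tested, reproducible implementation of model-based pressure-flow
classification, the Mx/PRx autoregulation indices, and the regime-level
statistics built on them.

## The method

The driving gradient is CPP, `∇p = ABP − ICP`. A zero-dimensional
compartmental model ties cerebral blood flow to it through two non-negative
cerebral-autoregulation (CA) parameters,

```
Q(t) = α₁ ∇p(t) + α₂ d∇p/dt,          α₁, α₂ ≥ 0,
```

with `α₁` a vessel-bed conductance and `α₂` a compliance-like coefficient.
Holding `α` constant over each 1-min window, `pfr` infers a model flow from
CPP by bound-constrained least squares (roughness-penalized, prior-anchored;
the absolute flow scale is unidentifiable from pressure alone and is
anchored, which the next step removes anyway).

The model flow is then calibrated to the observed perfusion with a linear
correction `m·Q + b` after standardizing both signals to unit variance, so
the slope `m ∈ [−1, 1]` is scale-free across probe placements. Its sign and
magnitude decide the pressure-flow regime (PFR) of each 100–140 min
interval:

| slope                | label | reading                                      |
|----------------------|-------|----------------------------------------------|
| `m > 0.2`            | pPFR  | pressure-passive flow, impaired CA           |
| `\|m\| ≤ 0.2`        | zPFR  | no net coordination (CA active, in balance)  |
| `m < −0.2`           | nPFR  | flow opposes pressure                        |

Because the model can only produce flow non-negatively oriented with CPP,
anti-correlated perfusion *must* show up as a negative calibration slope —
that is what makes the nPFR regime detectable.

Around this core the package provides:

* a synthetic generator of labeled epochs (pulsatile ABP, slowly varying
  ICP, perfusion with a prescribed coupling schedule, gaps and artifacts);
* interval extraction (perfusion gaps up to 10 min tolerated) and
  quality-control screens on physical thresholds (ABP negative/outlier,
  perfusion above 130 mL/hg/min or 5-min mean above 95, ICP above 100 mmHg
  sustained beyond 5 min);
* the windowed autoregulation indices Mx (30 correlations of 12-s flow/CPP
  averages) and PRx (30 correlations of 10-s ABP/ICP averages);
* regime-level statistics: joint (PRx, Mx) densities, a two-sample 2-D
  Kolmogorov–Smirnov test (Fasano–Franceschini statistic, permutation
  p-values), the joint-index impairment boundary `Mx = c·(1 − PRx)`
  (default c = 0.43), group distribution comparisons, and
  automatic-relevance-determination predictor ranking.

## Worked example

```python
import pfr

# one labeled 2-h epoch with negative pressure-flow coordination
spec = pfr.SyntheticSpec.for_regime("nPFR", seed=3)
labeled = pfr.generate_regime_epoch(spec)

interval = pfr.extract_intervals(labeled.epoch)[0]
print(pfr.qc_filter(interval).passed)

rec = pfr.analyze_interval(interval, pfr.RunConfig())
print(rec["label"], round(rec["m"], 3), round(rec["mx_mean"], 3))
```

prints

```
True
nPFR -0.997 -0.988
```

The interval passes quality control; the standardized calibration slope is
−0.997 (model flow almost perfectly anti-correlated with perfusion), so the
interval is labeled nPFR, and the mean flow index Mx ≈ −0.99 agrees that
flow opposes pressure throughout. The same flow is available from the shell:

```bash
pfr simulate --regime npfr --duration-min 120 --seed 3 --out ep.h5 --format hdf5
pfr classify --in ep.h5 --out label.json      # -> nPFR (m=-0.997)
pfr run --seed 2 --out results/               # full pipeline + manifest
```

## Layout

```
src/pfr/
  channels.py      timestamped channel container, block averaging, CPP
  io.py            csv-dir / HDF5 epoch round-trip
  synthetic.py     labeled epoch generator, artifact injection
  qc.py            interval extraction and quality control
  model.py         compartmental model: forward flow + constrained inversion
  classify.py      standardized calibration slope and regime labels
  indices.py       Mx / PRx moving correlations, neutral-Mx comparison
  regime_stats.py  densities, 2-D KS, discriminant, group stats, ARD ranking
  pipeline.py      end-to-end orchestration with reproducibility manifest
  cli.py           `pfr` command-line verbs
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
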