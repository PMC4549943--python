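# fetaltdi

ECG-free analysis of fetal myocardial color tissue-Doppler velocity traces.

The package segments each cardiac cycle of an AV-plane velocity trace into
six phases (atrial contraction, pre-ejection, ejection, post-ejection,
rapid filling, slow filling) from shifts in the acceleration trace — no
ECG required — and extracts peak myocardial velocities (Sm, Em, Am), phase
durations, and a 1–3 trace-quality score.  A built-in synthetic fetal-heart
generator produces velocity fields with exact ground-truth event times, so
region-of-interest (ROI) size effects and detection accuracy can be studied
quantitatively.

## Components

| module                 | role |
| ---------------------- | ---- |
| `fetaltdi.core`        | domain types (traces, segmentations, ROIs, results) and CSV/JSON readers-writers |
| `fetaltdi.synthetic`   | synthetic AV-plane velocity fields and ROI-sampled traces with exact ground truth |
| `fetaltdi.preprocess`  | moving-average smoothing, the four-setting filter bank, differentiation |
| `fetaltdi.cycles`      | autocorrelation period estimation and atrial-onset (cycle start) location |
| `fetaltdi.events`      | acceleration-shift detection, template-based phase assignment, full pipeline |
| `fetaltdi.quality`     | 1–3 acceleration quality score and per-wall averages |
| `fetaltdi.report`      | Sm/Em/Am and interval extraction, ROI percent-differences, feasibility summaries, ROI recommendations |
| `fetaltdi.cli`         | `fetaltdi` command-line entry point |

## Command line

```sh
# synthetic recordings (CSV trace tables + ground-truth JSON side-files)
fetaltdi simulate --ga 38 --n 5 --seed 7 --noise 0.5 --out data/

# automated analysis of a trace table (column 1 = time s, others = cm/s)
fetaltdi analyze --in data/trace_000.csv --out result.json
fetaltdi analyze --in trace.csv --invert --strict   # exit 2 on failure

# trace-quality scores
fetaltdi score --in data/trace_000.csv

# ROI-size study: percent differences vs the 2x2 mm reference ROI
fetaltdi roi-study --ga 33 --seed 1 --out roi.csv

# feasibility summary over result files
fetaltdi report result1.json result2.json --out summary.json
```

All commands accept `--config cfg.yaml` to override analysis parameters
(filter windows, heart-rate range, template priors/tolerances, quality
thresholds; see `AnalysisConfig.from_yaml` for the schema).  `--seed`
controls all randomness; identical seeds give byte-identical outputs.

## Conventions

* Velocity polarity is canonical: the systolic peak is positive, the
  diastolic peaks negative.  Pass `--invert` (or `invert: true` in the
  config) for recordings with opposite probe orientation.
* A cycle starts at the atrial-contraction onset; phases are half-open
  intervals, so the six durations sum exactly to the cycle length.
* Velocity percent-differences between ROIs are computed on magnitudes, so
  attenuation with larger ROIs is negative; quantiles use linear
  interpolation; printed percentages round half away from zero.

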