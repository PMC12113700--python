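# cereb-band-psd

Behavior-resolved spectral band-power analysis of extracellular
cerebellar recordings, together with a seeded synthetic-cohort generator
that reproduces the statistical structure the analysis assumes — so every
stage of the pipeline is testable without any recorded data.

The pipeline: behavior-annotated sessions (simulated or read from disk)
→ zero-phase band-pass (300–3000 Hz) and mains-harmonic notch filtering
→ 5-s behavior-aligned trace extraction with saturation/excursion QC
→ periodogram PSD and six-band AUC / bandwidth-normalized PSD
→ nonparametric statistics (exact Mann–Whitney per week, Friedman with
Holm-adjusted Wilcoxon post hocs across weeks, Spearman duration–power
correlation, behavior-duration comparisons, Lilliefors/Levene
diagnostics) → CSV report tables plus a run log.

## Layout

| Module | Role |
| --- | --- |
| `cereb_band_psd.core` | Domain types: sessions, episodes, schedules |
| `cereb_band_psd.synthetic` | Seeded cohort generator (power-law background, behavior schedules, injected effects, artifacts) |
| `cereb_band_psd.io` | Session serialization: JSON manifest + float32 signals + CSV episodes |
| `cereb_band_psd.preprocessing` | Butterworth band-pass, notch bank, trace tiling, artifact rules |
| `cereb_band_psd.spectral` | Periodogram PSD, band AUC, bandwidth-normalized PSD |
| `cereb_band_psd.stats` | Exact/first-principles nonparametric tests |
| `cereb_band_psd.pipeline` | Orchestration, report tables, run log |
| `cereb_band_psd.cli` | `cereb-band-psd` command-line interface |

## CLI

```sh
# simulate a cohort (YAML/JSON config mirrors CohortDesign fields)
cereb-band-psd simulate --config design.yaml --out sessions/ --seed 1

# validate one stored session
cereb-band-psd validate sessions/E01_w1/manifest.json

# extract QC-passing traces from one session
cereb-band-psd extract --manifest sessions/E01_w1/manifest.json --out traces/

# run the full analysis (simulate in-line, or point --sessions at a directory)
cereb-band-psd analyze --design design.yaml --config analysis.yaml \
    --out report/ --seed 1 [--plots]

# summarize significant rows of a written report
cereb-band-psd report --dir report/
```

## Notes

- Every source of randomness flows through explicit integer seeds;
  sessions are independently reproducible via a documented
  `SeedSequence` scheme.
- Band integrals use half-open bins `[f1, f2)` with the final band
  closed, so the six bands partition 300–3000 Hz exactly.
- The experimental unit defaults to the rat (mean of up to five trace
  values per cell); the aggregation rule is a config switch stamped into
  every output table.
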