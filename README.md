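# heartloc

Localization of heart-sound components (S1, S2, S3, S4) inside
heart-sound-corrupted lung-sound recordings.

The detector works on mono PCM WAV recordings (any rate; 8 kHz typical):

1. **Normalize** the mixed signal by its absolute maximum.
2. **Low-pass filter** it (10th-order Butterworth, 150 Hz, zero-phase) to
   emphasize the heart-sound band against broadband lung sounds and murmurs.
3. Extract the **discrete Hilbert envelope** (DFT-based analytic signal,
   with the even/odd record-length spectral weightings).
4. **Smooth** the envelope (5th-order Butterworth, cutoff in 7–25 Hz).
5. Detect alternating envelope **extrema** and assemble each maximum with
   its flanking minima into a candidate peak.
6. Score each peak by the **area of the scalene triangle** spanned by its
   three extrema (semiperimeter/Heron evaluation, numerically stabilized).
7. Keep peaks whose area exceeds an **adaptive threshold** derived from the
   spread of the area vector, and report each kept peak's min-to-min span
   as a heart-sound segment (adjacent spans sharing a minimum are merged).

The package also ships a synthetic-data generator (parametric S1–S4 trains,
band-shaped breathing noise, and random 4-tap convolutive mixing whose
lung-filter tap norm encodes the low/medium/high breathing-flow stratum)
and per-sample / per-event evaluation metrics (FNR, FPR, ACC, DER).

## CLI

```sh
# generate a labelled synthetic mixture
heartloc simulate --flow high --mixture normal-abnormal --duration 20 \
    --seed 7 --out mix.wav --truth truth.csv

# localize heart-sound segments
heartloc localize mix.wav --out segments.csv \
    [--config cfg.yaml] [--smooth-cutoff 15] [--threshold-scale 1.0] \
    [--filter-mode zerophase] [--mask-out mask.wav]

# score predictions against ground truth (n = record length in samples)
heartloc evaluate --pred segments.csv --truth truth.csv --n 160000 [--per-event]
```

`segments.csv` columns: `start_sample,end_sample,start_sec,end_sec,peak_sample,area`.
A YAML config may set any `RunConfig` field (`hs_filter_cutoff_hz`,
`hs_filter_order`, `smooth_cutoff_hz`, `smooth_order`, `threshold_scale`,
`threshold_stat`, `filter_mode`, `x_scale`, `y_scale`); CLI flags override it.

## Library

```python
from heartloc import make_mixture, localize_hs, evaluate_segments, RunConfig

r = make_mixture("normal-normal", "medium", duration_s=10.0, seed=0)
segments = localize_hs(r.signal, RunConfig())
report = evaluate_segments(segments, r.truth.segments, r.signal.n)
print(report.as_dict())  # FNR/FPR/ACC/DER percentages
```

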