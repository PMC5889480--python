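# caxstm — Ca²⁺ transient analysis on spatio-temporal maps

`caxstm` quantifies localized intracellular Ca²⁺ release events in
elongated cells — interstitial cells of Cajal (ICC) and similar
GCaMP-expressing cells imaged at high frame rates — from fluorescence
movie stacks. It is aimed at labs doing in-situ Ca²⁺ imaging of
gut pacemaker/neuroeffector cells who need a reproducible, scriptable
version of the classic spatio-temporal (ST) map workflow: whole-cell
ROI → position×time map → event detection → per-event metrics →
stimulus-window statistics.

## What it computes

1. **Stabilisation.** Rigid tissue drift is estimated per frame by
   phase cross-correlation against a reference frame (subpixel by
   local upsampling) and removed.
2. **ST maps.** Each whole-cell ROI is reduced to a centerline
   (principal axis, or skeleton for curved cells); pixel fluorescence
   is averaged transversely into position bins, giving
   `F(x, t)` with `x` in µm along the cell. Baseline `F₀(x)` is the
   mean of the lowest decile of each bin's time series, and
   ΔF/F₀ = (F − F₀)/F₀.
3. **Event detection.** The ΔF/F₀ map is differentiated in time
   (backward difference, Δt = 0.5 s), smoothed along position
   (Gaussian, SD 1.0 bin, box 3.3 µm, unit-sum kernel), thresholded at
   SNR ≥ 25 dB above the robust noise SD (amplitude convention:
   threshold = σ·10^(25/20)), and segmented into connected "particles".
   Each particle is expanded on the ΔF/F₀ layer to its event
   footprint — the contiguous region ≥ half the event's peak.
4. **Metrics.** Per event: amplitude (max ΔF/F₀), duration (FDHM, full
   duration at half-maximum of the peak-bin trace, interpolated),
   spatial spread (µm of cell at ≥ half amplitude, union over frames),
   propagation velocity (slope of half-max front positions vs time),
   initiation site; per cell: firing frequency (events·s⁻¹) and
   firing-site count (single-linkage clustering of initiation sites).
5. **Stimulus windows.** For electrical field stimulation (EFS)
   trains, events are assigned by peak time to fixed half-open
   windows: `pre [onset−5, onset)`, `initial [onset, onset+2)`,
   `late [onset+T−3, onset+T)`, `post [onset+T, onset+T+5)`, capturing
   the three-phase response (suppression, escape, rebound); per-window
   frequency, metric means and net % change vs baseline are reported.
6. **Statistics.** Mean ± SEM per cell, paired Student's t,
   one-way ANOVA with Dunnett many-to-one post hoc, and asterisk
   notation (\*, \*\*, \*\*\*, \*\*\*\* at p < 0.05/0.01/0.001/0.0001).

A first-class synthetic-data module generates seeded movies and ST
maps with known ground truth (nonhomogeneous Poisson firing at
discrete sites; double-exponential kinetics with exact planted FDHM;
Gaussian spatial profiles with planted spread and velocity; EFS rate
envelopes; sensor noise, optical blur and tissue drift), so every
stage is testable without any recording.

## Worked example

```python
from caxstm import (SimulationConfig, efs_envelope, plan_events,
                    render_stmap, detect_events, StimulusProtocol,
                    make_windows, summarize_window, percent_change)

cfg = SimulationConfig(duration=17.0, seed=42,
                       rate_envelope=efs_envelope(onset=6.0,
                                                  train_duration=5.0))
truth = plan_events(cfg)          # ground-truth event list
stm = render_stmap(truth)         # position x time ΔF/F0 map
events = detect_events(stm)       # the detection chain
print(f"planted events: {len(truth)}, detected: {len(events)}")

windows = make_windows(StimulusProtocol(efs_onset=6.0), stm.duration)
summary = summarize_window(events, windows)
print(summary.table[["n", "frequency", "amplitude", "fdhm_ms",
                     "spread_um"]].round(2))
print(percent_change(summary)[["frequency"]].round(1))
```

prints

```
planted events: 20, detected: 16
         n  frequency  amplitude  fdhm_ms  spread_um
pre      4       0.80       1.14   226.29      16.50
initial  1       0.50       1.04   142.34      10.00
late     4       1.33       1.12   217.24       8.12
post     6       1.20       1.14   261.51      10.75
         frequency
initial      -37.5
late          66.7
post          50.0
```

Here 20 events were planted on a 17-s recording with firing
suppressed for 2 s at EFS onset, escaping to 1.7× basal during the
remaining train and rebounding to 2× afterwards. The detector finds
16 (closely co-active events merge into single detected complexes —
see `docs/methods.md`); window frequencies rise from 0.80 s⁻¹ at
baseline to 1.33 s⁻¹ in the final 3 s of the train and 1.20 s⁻¹
post-stimulus, i.e. +67% and +50% vs baseline, while the initial
window is suppressed.

## Command line

```bash
caxstm simulate --seed 3 --out sim/          # movie + ST map + truth
caxstm stabilize --movie sim/movie.tif --out stab/
caxstm stmap --movie stab/stabilized.tif --roi sim/rois.json --out maps/
caxstm detect --stmap maps/stmap_cell0.tif --out det/
caxstm analyze --events det/events.csv --protocol proto.json \
               --recording-span 17 --out win/
caxstm report --summaries win/window_summaries.csv --out stats/
caxstm run --config run.yaml                 # everything at once
```

Every output directory receives a manifest with the config hash and
seed; identical config + seed reproduces byte-identical event tables.

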