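# Methods

This note documents the models, parameter choices and numerical
conventions behind `caxstm`, and what the synthetic benchmarks do and
do not establish about real recordings.

## The analysis model

The unit of analysis is the spatio-temporal (ST) map of one cell:
mean fluorescence in position bins along the cell's centerline versus
time. Position bin `p` covers `[p·pitch, (p+1)·pitch)` µm (pitch =
pixel size, default 0.5 µm); frame `k` is at `t = k·Δt_frame`
(default 1/33 s, i.e. 33 fps). All event quantification happens on
the ΔF/F₀ layer of this map.

**Baseline.** F₀ per position bin is the mean of the lowest decile of
that bin's time series. This is robust as long as transients occupy a
minority of samples at each position; with pure Gaussian noise it
under-reads the true baseline by ≈1.75 noise SD, a bias of order
0.5 % here, which propagates to an equally small ΔF/F₀ offset.

**Detection chain.** Differentiate → smooth → threshold → label:

* *Differentiation* is a backward difference over the nearest whole
  number of frames to Δt = 0.5 s. The quotient uses the realised lag
  (k·Δt_frame), so a linear ramp returns its slope exactly. The first
  k columns are undefined (NaN) and never detected on.
* *Smoothing* is position-axis-only Gaussian convolution, kernel SD
  1.0 bin, truncated to a 3.3-µm box and renormalised to unit sum, so
  constants are preserved exactly. A config switch reads the SD in µm
  instead.
* *Thresholding* uses the amplitude dB convention:
  `threshold = σ_noise · 10^(dB/20)` with dB = 25 by default. σ_noise
  is 1.4826×MAD of the processed map — robust to a sparse active
  fraction. The power convention (10^(dB/10)) is available but at
  25 dB (a 316× ratio) it sits above any physiological transient's
  differentiated amplitude, which is itself evidence for the
  amplitude reading.
* *Labeling* takes connected components (8-connectivity by default)
  and discards components below 2 map pixels.

**Event footprints.** Each particle is expanded on the ΔF/F₀ layer to
the contiguous region at or above half the event's peak, flood-filled
from the particle's ΔF/F₀ maximum (the 0.5-s backward difference
remains above threshold through the fluorescence peak, so the peak
always lies inside the particle). Metrics are measured on this
footprint, not on the differentiated layer, because amplitude, FDHM
and spread are defined on ΔF/F₀.

**Metrics.**

* FDHM is measured on the time series at the event's peak position
  bin with linear interpolation between frames; a variant integrating
  over position is available. Events clipped by the map edge are
  flagged and excluded from summaries.
* Spread is the union-across-frames extent of position bins at
  ≥ half amplitude, as micrometres of cell covered; for a travelling
  event this includes the travel distance. A peak-frame-only variant
  exists.
* Velocity fits half-maximum front positions against time. Fronts are
  located per frame at half of that frame's spatial maximum, so a
  translating profile of constant shape yields exactly its
  translation speed; the leading and trailing slopes are averaged.
  Events spanning < 3 frames are flagged undefined.
* Initiation sites are the earliest-frame centroid; firing sites are
  single-linkage clusters of initiation positions with a 2-µm merge
  radius (sub-cellular granularity; configurable).

**Stimulus windows.** Events are assigned by peak time (the robustly
detected landmark; onset-based assignment is a switch) to half-open
windows pre/initial/late/post = [onset−5, onset), [onset, onset+2),
[onset+T−3, onset+T), [onset+T, onset+T+5). For 5-s trains the
initial and late windows tile the train; for longer trains the
uncovered middle is reported as `mid` and excluded from the
phase summaries. The 2-s initial window reflects the duration of the
stimulus-onset suppression of firing and is configurable.

**Statistics.** The analysis unit is the cell; animal ids are carried
for n/c bookkeeping but no mixed-model nesting is attempted — a
deliberate fidelity-over-sophistication choice, noted as a
limitation. Dunnett comparisons use multivariate-t quantiles
(scipy), with a seeded stochastic integration for unbalanced groups.
The paired t statistic is computed directly from the difference
vector so that identical vectors give (t = 0, p = 1) rather than NaN.

## The synthetic-data generator

The generator emulates an elongated ~100 µm × 8 µm cell at 0.5 µm/px
and 33 fps, with discrete firing sites (default 6, uniform random
positions) firing as a nonhomogeneous Poisson process at a basal
1 event·s⁻¹·cell⁻¹, modulated by a piecewise-constant envelope.
Per-event kinetics are drawn uniformly from amplitude 0.3–1.4 ΔF/F₀,
FDHM 120–340 ms and spread 6–19 µm — the ranges typical of
spontaneous ICC Ca²⁺ transients. Velocity defaults to 0 (these events
are localized, without regenerative propagation); non-zero planted
velocities translate the spatial profile. The EFS envelope default
(0× for 2 s, 1.7× for the rest of the train, 2.0× for 5 s after)
mirrors the measured suppression/escape/rebound ratios.

The temporal kernel is an asymmetric double exponential
`h(u) = (1 − e^(−u))·e^(−u/ρ)` with decay/rise ratio ρ = 3
(GCaMP-like: fast rise, slower decay). The canonical shape's FDHM is
3.9844 rise-constants, so the rise constant `τ_r = FDHM/3.9844` hits
the planted duration exactly; the onset→peak lag is
`τ_r·ln(1+ρ)`. Spatial profiles are Gaussians with FWHM equal to the
planted spread. Overlapping events sum linearly with a saturation
ceiling (default ΔF/F₀ = 8). Sensor noise is additive Gaussian on raw
intensity, default SD 1 % of the baseline F₀ = 100 — i.e. ΔF/F₀ noise
SD 0.01, placing the smallest default amplitude ~30 dB above noise.
Gaussian (not Poisson) noise keeps the dB threshold contract exact.

Movie rendering places the map on a ribbon with constant transverse
fluorescence, blurs with a small optical PSF (σ = 0.6 px; real
confocal images have no single-pixel step edges), applies cumulative
drift as an exact band-limited (Fourier) translation, then adds
per-pixel noise. Bleaching is deliberately not simulated.

**What passing tests do not show.** The generator has separable,
unimodal events, stationary Gaussian noise, rigid translation-only
motion and no bleaching, focus drift or neighbouring-cell crosstalk.
Benchmarks therefore validate the *algorithmic* contracts (detection
above a known SNR, metric definitions, window logic), not performance
on tissue with correlated noise or non-rigid motion.

## Known limitation: event-count saturation

With the 0.5-s differentiation window, a transient whose FDHM is
much shorter than 0.5 s produces a differentiated signal close to
ΔF/F₀ itself (the subtracted sample is pre-onset for most of the
event), so each event occupies ~0.4–0.5 s × ~1.5 spatial FWHM of the
thresholded map. Co-active transients closer than that merge into a
single detected complex and are counted once. Detection *coverage*
stays high (a merged complex overlaps each constituent event — pooled
sensitivity 0.98 on the 20-map benchmark, FDR 0), but counts
saturate: recovered rates run ≈5 % low at 0.3 events·s⁻¹, ≈15 % low
at 1.0 and ≈30 % low at 2.5 under the default geometry. This is a
property of the differentiate-then-threshold scheme itself, not of
its implementation; measured frequencies at high activity should be
read as complex rates, and comparisons between conditions remain
valid as the bias is monotone in the true rate.

## Benchmark matching rule

A planted event counts as recovered when some detection's footprint
overlaps the event's half-maximum extent within a slack of one FDHM
in time and one spread in position (a non-exclusive predicate, no
one-to-one assignment). Counting fidelity is deliberately reported
separately (rate-recovery bias above), so merging cannot hide in the
sensitivity number.

## Numerical choices and degenerate inputs

* Registration: skimage phase cross-correlation, upsample factor 20
  (0.05-px grid); zero-variance frames get shift (0, 0) with a
  warning; exposed borders are filled with the frame median and the
  margin recorded in metadata.
* Centerlines: principal axis sampled at 1-px pitch when the
  transverse-centroid sagitta is ≤ 2 px; otherwise the mask skeleton's
  longest geodesic, tangent-extended to the cell ends. Curved-cell
  arc length is recovered within ~4 %.
* Constant maps: the noise estimate is 0 with a warning and detection
  returns no events rather than dividing by zero.
* Half-open conventions everywhere: position bins `[p, p+pitch)`,
  windows `[a, b)` — an event peaking exactly on a boundary belongs
  to the later window.
* Benchmark problem sizes: 20 seeds × 60 s for detection, 20 seeds per
  planted kinetic value, 100 seeds × 17 s for the stimulus response,
  1000 replicates for the Dunnett null — sizes at which Monte-Carlo
  error is small relative to the tolerances tested.
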