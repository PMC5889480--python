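"""Seeded synthetic movies and ST maps with known ground truth.

The generator emulates an elongated intramuscular interstitial cell
(ICC-DMP-like geometry) expressing a genetically encoded Ca2+ sensor:
discrete firing sites placed along the cell fire stochastically as a
nonhomogeneous Poisson process, each event carrying its own amplitude,
duration (FDHM), spatial spread (FWHM) and propagation velocity.

Event shape model
-----------------
Each transient is separable into a temporal kinetic profile and a
spatial Gaussian:

* temporal: an asymmetric double exponential
  ``h(u) = (1 - exp(-u)) * exp(-u / rho)`` with ``u = (t - onset) / tau_r``
  and a fixed decay/rise ratio ``rho = 3`` (fast rise, slower decay,
  as for GCaMP-class sensors).  ``tau_r`` is chosen so the profile's
  full duration at half maximum equals the planted FDHM exactly
  (the shape is a pure time scaling of a canonical curve whose FDHM
  in ``u`` units is a constant, ``FDHM_CANON``).
* spatial: a Gaussian in position with FWHM equal to the planted
  spread, whose centre translates at the planted velocity from the
  event's origin.

Overlapping events sum linearly; the summed dF/F0 is clipped at a
configurable saturation ceiling.  Sensor noise is additive Gaussian on
raw intensity, so the dF/F0 noise SD is ``noise_sd / baseline_f0``.
Photobleaching is deliberately not simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .core import CellROI, MovieStack, STMap, ValidationError

__all__ = [
    "RateEnvelope",
    "efs_envelope",
    "SimulationConfig",
    "GroundTruthEvent",
    "GroundTruth",
    "plan_events",
    "render_stmap",
    "render_movie",
    "RHO",
    "FDHM_CANON",
    "U_PEAK",
]

# ---------------------------------------------------------------------------
# canonical temporal kinetic shape

RHO = 3.0  # decay / rise time-constant ratio


def _shape(u: np.ndarray | float) -> np.ndarray | float:
    """Canonical rise*decay profile, zero for u <= 0, peak < 1."""
    u = np.asarray(u, dtype=np.float64)
    out = np.where(u > 0, (1.0 - np.exp(-np.maximum(u, 0.0))) *
                   np.exp(-np.maximum(u, 0.0) / RHO), 0.0)
    return out


U_PEAK = float(np.log(1.0 + RHO))
H_PEAK = float(_shape(U_PEAK))
_U_HALF_LO = brentq(lambda u: _shape(u) - H_PEAK / 2, 1e-9, U_PEAK)
_U_HALF_HI = brentq(lambda u: _shape(u) - H_PEAK / 2, U_PEAK, 100.0)
#: FDHM of the canonical shape in units of the rise time constant.
FDHM_CANON = float(_U_HALF_HI - _U_HALF_LO)
#: profile support: point where the decay falls to 0.2% of peak.
_U_SUPPORT = brentq(lambda u: _shape(u) - 0.002 * H_PEAK, U_PEAK, 500.0)


def temporal_profile(t: np.ndarray, onset: float, fdhm_s: float,
                     amplitude: float) -> np.ndarray:
    """Evaluate the unit-peak kinetic profile scaled to ``amplitude``."""
    tau_r = fdhm_s / FDHM_CANON
    return amplitude / H_PEAK * _shape((np.asarray(t) - onset) / tau_r)


def peak_lag(fdhm_s: float) -> float:
    """Onset-to-peak delay for an event of the given FDHM (seconds)."""
    return fdhm_s / FDHM_CANON * U_PEAK


# ---------------------------------------------------------------------------
# rate envelope


@dataclass(frozen=True)
class RateEnvelope:
    """Piecewise-constant multiplier of the basal firing rate.

    ``segments`` is a sequence of ``(t_start, t_end, multiplier)``
    triples; the multiplier is 1.0 everywhere not covered.  Segments
    must be non-overlapping and multipliers non-negative.
    """

    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(sorted((float(a), float(b), float(m))
                            for a, b, m in self.segments))
        object.__setattr__(self, "segments", segs)
        for a, b, m in segs:
            if b <= a:
                raise ValidationError(f"empty envelope segment [{a}, {b})")
            if m < 0:
                raise ValidationError("envelope multiplier must be >= 0")
        for (a0, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if a1 < b0:
                raise ValidationError("envelope segments overlap")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=np.float64)
        out = np.ones_like(t)
        for a, b, m in self.segments:
            out = np.where((t >= a) & (t < b), m, out)
        return out if out.ndim else float(out)

    def pieces(self, t0: float, t1: float) -> list[tuple[float, float, float]]:
        """Constant-rate pieces tiling ``[t0, t1)``."""
        edges = sorted({t0, t1} | {x for a, b, _ in self.segments
                                   for x in (a, b) if t0 < x < t1})
        return [(a, b, float(self((a + b) / 2)))
                for a, b in zip(edges, edges[1:])]

    def integral(self, t0: float, t1: float) -> float:
        return sum((b - a) * m for a, b, m in self.pieces(t0, t1))


def efs_envelope(onset: float, train_duration: float = 5.0, *,
                 initial_s: float = 2.0, initial_mult: float = 0.0,
                 late_mult: float = 1.7, post_mult: float = 2.0,
                 post_s: float = 5.0) -> RateEnvelope:
    """Three-phase rate modulation of an EFS train.

    Firing is suppressed for ``initial_s`` seconds after stimulus
    onset, escapes to ``late_mult`` x basal for the remainder of the
    train, and rebounds to ``post_mult`` x basal for ``post_s`` seconds
    after the train ends.  Default multipliers (0x, 1.7x, 2.0x) follow
    the suppression / escape / rebound phenomenology of nerve-evoked
    responses in ICC-DMP.
    """
    if train_duration <= initial_s:
        raise ValidationError("train shorter than the initial suppression")
    return RateEnvelope((
        (onset, onset + initial_s, initial_mult),
        (onset + initial_s, onset + train_duration, late_mult),
        (onset + train_duration, onset + train_duration + post_s, post_mult),
    ))


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic recording.

    Geometry defaults describe an elongated ~100 um cell imaged at
    0.5 um/px and 33 fps; kinetic ranges span the amplitudes
    (0.3-1.4 dF/F0), durations (120-340 ms FDHM), spreads (6-19 um)
    and basal rates typical of spontaneous ICC-DMP Ca2+ transients.
    Events are localised by default (velocity 0), reflecting the
    absence of regenerative propagation in these cells.
    """

    cell_length: float = 100.0          # um
    cell_width: float = 8.0             # um
    pixel_size: float = 0.5             # um / px
    frame_interval: float = 1.0 / 33.0  # s
    duration: float = 20.0              # s
    n_sites: int = 6
    site_positions: Sequence[float] | None = None   # um
    base_rate: float = 1.0              # events / s / cell
    rate_envelope: RateEnvelope | None = None
    amp_range: tuple[float, float] = (0.3, 1.4)       # dF/F0
    fdhm_range_ms: tuple[float, float] = (120.0, 340.0)
    spread_fwhm_range: tuple[float, float] = (6.0, 19.0)  # um
    velocity_range: tuple[float, float] = (0.0, 0.0)      # um/s, signed
    noise_sd: float = 1.0               # raw intensity units
    baseline_f0: float = 100.0          # raw intensity units
    drift_per_frame: tuple[float, float] = (0.0, 0.0)     # (row, col) px
    psf_sigma_px: float = 0.6   # optical blur of rendered movie frames
    saturation_dff: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amp_range", "fdhm_range_ms", "spread_fwhm_range",
                     "velocity_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: min > max")
        if self.base_rate < 0:
            raise ValidationError("base_rate must be >= 0")
        if self.duration <= 0 or self.cell_length <= 0:
            raise ValidationError("duration and cell_length must be > 0")
        if self.baseline_f0 <= 0:
            raise ValidationError("baseline_f0 must be > 0")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValidationError("pixel_size and frame_interval must be > 0")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.site_positions is not None:
            pos = np.asarray(self.site_positions, dtype=float)
            if pos.size == 0 or pos.min() < 0 or pos.max() > self.cell_length:
                raise ValidationError("site_positions must lie on the cell")

    @property
    def n_position_bins(self) -> int:
        return int(np.ceil(self.cell_length / self.pixel_size - 1e-9))

    @property
    def n_frames(self) -> int:
        return int(np.ceil(self.duration / self.frame_interval - 1e-9))

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruthEvent:
    """The planted analogue of one measured Ca2+ transient."""

    site_id: int
    onset_time: float   # s
    peak_time: float    # s
    amplitude: float    # dF/F0
    fdhm: float         # ms
    spread_fwhm: float  # um
    velocity: float     # um/s, signed
    origin_position: float  # um

    def __post_init__(self) -> None:
        if not (self.onset_time < self.peak_time):
            raise ValidationError("onset must precede peak")
        if self.amplitude <= 0 or self.fdhm <= 0 or self.spread_fwhm <= 0:
            raise ValidationError("amplitude, fdhm, spread must be > 0")


@dataclass
class GroundTruth:
    """Planted event list plus the configuration that produced it."""

    events: list[GroundTruthEvent]
    config: SimulationConfig
    site_positions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        onsets = [e.onset_time for e in self.events]
        if onsets != sorted(onsets):
            raise ValidationError("events must be sorted by onset time")
        if onsets and (min(onsets) < 0 or
                       max(onsets) >= self.config.duration):
            raise ValidationError("onsets must lie in [0, duration)")

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# event planning


def plan_events(config: SimulationConfig, seed: int | None = None) -> GroundTruth:
    """Draw the ground-truth event list for one recording.

    Whole-cell firing is a nonhomogeneous Poisson process with rate
    ``base_rate * envelope(t)``; each event is assigned to a firing
    site uniformly at random and its kinetic parameters are drawn
    uniformly from the configured ranges.  Reproducible given
    (config, seed); ``seed=None`` uses ``config.seed``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), 0xCA])
    env = config.rate_envelope or RateEnvelope()

    if config.site_positions is not None:
        sites = np.asarray(config.site_positions, dtype=float)
    else:
        sites = np.sort(rng.uniform(0.0, config.cell_length, config.n_sites))

    times: list[float] = []
    for a, b, mult in env.pieces(0.0, config.duration):
        lam = config.base_rate * mult * (b - a)
        n = rng.poisson(lam) if lam > 0 else 0
        times.extend(rng.uniform(a, b, n))
    times = np.sort(np.asarray(times, dtype=float))

    n = times.size
    site_ids = rng.integers(0, sites.size, n)
    amps = rng.uniform(*config.amp_range, n)
    fdhms = rng.uniform(*config.fdhm_range_ms, n)
    spreads = rng.uniform(*config.spread_fwhm_range, n)
    vels = rng.uniform(*config.velocity_range, n)

    events = [
        GroundTruthEvent(
            site_id=int(site_ids[i]),
            onset_time=float(times[i]),
            peak_time=float(times[i] + peak_lag(fdhms[i] / 1000.0)),
            amplitude=float(amps[i]),
            fdhm=float(fdhms[i]),
            spread_fwhm=float(spreads[i]),
            velocity=float(vels[i]),
            origin_position=float(sites[site_ids[i]]),
        )
        for i in range(n)
    ]
    return GroundTruth(events=events, config=config, site_positions=sites)


# ---------------------------------------------------------------------------
# rendering


def _clean_dff(truth: GroundTruth) -> np.ndarray:
    """Noise-free dF/F0 ST map of all planted events (position x frame)."""
    cfg = truth.config
    n_pos, n_t = cfg.n_position_bins, cfg.n_frames
    x = (np.arange(n_pos) + 0.5) * cfg.pixel_size
    t = np.arange(n_t) * cfg.frame_interval
    out = np.zeros((n_pos, n_t))

    for ev in truth.events:
        fdhm_s = ev.fdhm / 1000.0
        tau_r = fdhm_s / FDHM_CANON
        t_end = ev.onset_time + tau_r * _U_SUPPORT
        k0 = max(0, int(np.floor(ev.onset_time / cfg.frame_interval)))
        k1 = min(n_t, int(np.ceil(t_end / cfg.frame_interval)) + 1)
        if k1 <= k0:
            warnings.warn(f"event at t={ev.onset_time:.3f}s lies outside the "
                          "map and was clipped", stacklevel=2)
            continue
        tt = t[k0:k1]
        centre = ev.origin_position + ev.velocity * (tt - ev.onset_time)
        sigma_x = ev.spread_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        xmin = centre.min() - 4.0 * sigma_x
        xmax = centre.max() + 4.0 * sigma_x
        if xmax < 0 or xmin > cfg.cell_length or t_end > cfg.duration:
            warnings.warn(f"event at t={ev.onset_time:.3f}s extends beyond "
                          "the map and was clipped", stacklevel=2)
        p0 = max(0, int(np.floor(xmin / cfg.pixel_size)))
        p1 = min(n_pos, int(np.ceil(xmax / cfg.pixel_size)) + 1)
        if p1 <= p0:
            continue
        temporal = temporal_profile(tt, ev.onset_time, fdhm_s, ev.amplitude)
        spatial = np.exp(-((x[p0:p1, None] - centre[None, :]) ** 2)
                         / (2.0 * sigma_x ** 2))
        out[p0:p1, k0:k1] += spatial * temporal[None, :]

    np.clip(out, None, cfg.saturation_dff, out=out)
    return out


def render_stmap(truth: GroundTruth) -> STMap:
    """Render the ground truth directly onto a position x time map.

    Raw fluorescence is ``F0 * (1 + dff_clean)`` plus additive Gaussian
    noise of SD ``noise_sd``; the dF/F0 layer is re-derived from the
    noisy raw layer using the true baseline, so its noise SD is
    ``noise_sd / baseline_f0``.
    """
    cfg = truth.config
    clean = _clean_dff(truth)
    rng = np.random.default_rng([int(cfg.seed), 0x57])
    raw = cfg.baseline_f0 * (1.0 + clean)
    if cfg.noise_sd > 0:
        raw = raw + rng.normal(0.0, cfg.noise_sd, clean.shape)
    dff = raw / cfg.baseline_f0 - 1.0
    return STMap(
        raw_F=raw, dff=dff,
        position_pitch=cfg.pixel_size, frame_interval=cfg.frame_interval,
        provenance={"source": "synthetic", "seed": cfg.seed,
                    "n_events": len(truth)},
    )


def render_movie(truth: GroundTruth,
                 background: float = 10.0,
                 margin_px: int | None = None) -> tuple[MovieStack, CellROI]:
    """Render the ground truth as a drifting movie plus its cell ROI.

    The cell is a horizontal ribbon of ``cell_width`` with fluorescence
    constant across the transverse axis, blurred by a small Gaussian
    optical PSF (``psf_sigma_px``; confocal images have no single-pixel
    step edges); per-frame cumulative drift ``k * drift_per_frame`` is
    applied as an exact band-limited (Fourier) translation before
    sensor noise is added, so drift is a pure rigid displacement.  The
    returned ROI marks the undrifted ribbon.
    """
    cfg = truth.config
    clean = _clean_dff(truth)  # (pos, frame)
    n_pos, n_t = clean.shape
    width_px = max(1, int(round(cfg.cell_width / cfg.pixel_size)))

    drift = np.asarray(cfg.drift_per_frame, dtype=float)
    cum = np.arange(n_t)[:, None] * drift[None, :]
    max_shift = np.abs(cum).max(axis=0)
    if margin_px is None:
        # auto-size the field to keep the drifting cell inside
        margin_r = 10 + int(np.ceil(max_shift[0]))
        margin_c = 10 + int(np.ceil(max_shift[1]))
    else:
        margin_r = margin_c = int(margin_px)
        if max_shift.max() > margin_px - 2:
            raise ValidationError(
                "drift would move the cell outside the field")

    H = width_px + 2 * margin_r
    W = n_pos + 2 * margin_c
    r0, c0 = margin_r, margin_c

    rng = np.random.default_rng([int(cfg.seed), 0x3F])
    frames = np.empty((n_t, H, W))
    for k in range(n_t):
        frame = np.full((H, W), background)
        frame[r0:r0 + width_px, c0:c0 + n_pos] = \
            cfg.baseline_f0 * (1.0 + clean[:, k])[None, :]
        if cfg.psf_sigma_px > 0:
            frame = ndimage.gaussian_filter(frame, cfg.psf_sigma_px)
        if cum[k, 0] != 0.0 or cum[k, 1] != 0.0:
            frame = np.fft.ifft2(ndimage.fourier_shift(
                np.fft.fft2(frame), cum[k])).real
        frames[k] = frame
    if cfg.noise_sd > 0:
        frames += rng.normal(0.0, cfg.noise_sd, frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    mask = np.zeros((H, W), dtype=bool)
    mask[r0:r0 + width_px, c0:c0 + n_pos] = True
    roi = CellROI(cell_id="sim0", animal_id="sim", condition="synthetic",
                  mask=mask)
    movie = MovieStack(frames, cfg.frame_interval, cfg.pixel_size,
                       metadata={"source": "synthetic", "seed": cfg.seed})
    return movie, roi
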