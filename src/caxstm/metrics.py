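"""Per-event and per-cell Ca2+ transient metrics.

Definitions (all measured on the dF/F0 ST-map layer):

amplitude
    Maximum dF/F0 over the event footprint.
FDHM (ms)
    Full duration at half-maximum amplitude of the dF/F0 time series
    at the event's peak position bin, with linear interpolation
    between frames.  Events clipped at the map edge (no half-max
    crossing on one side) are flagged and return NaN.
spatial spread (um)
    Extent of the set of position bins the event occupies at or above
    half its amplitude, over the whole event (micrometres of cell the
    event covers).
velocity (um/s)
    Slope of a least-squares fit of the half-maximum front position
    against time.  Fronts are located per frame at half of that
    frame's spatial maximum, so a translating profile of constant
    shape yields its translation speed; leading and trailing fronts
    move together and their mean slope is reported, signed along the
    position axis.  Events spanning fewer than 3 frames are flagged.
initiation site (um)
    Centroid position of the event's pixels in its earliest frame.
"""

from __future__ import annotations

import numpy as np

from .core import CaEvent, FiringSite, STMap, ValidationError

__all__ = ["amplitude", "fdhm", "spatial_spread", "velocity",
           "initiation_site", "cluster_sites", "frequency",
           "measure_event"]


def amplitude(pixels: np.ndarray, dff: np.ndarray) -> float:
    """Maximum dF/F0 over the event footprint."""
    if pixels.size == 0:
        raise ValidationError("empty footprint")
    return float(dff[pixels[:, 0], pixels[:, 1]].max())


def _half_crossing(trace: np.ndarray, start: int, half: float,
                   direction: int) -> float | None:
    """Fractional frame index where ``trace`` first drops below
    ``half`` walking from ``start`` in ``direction``; None if clipped."""
    i = start
    while 0 <= i + direction < trace.size:
        j = i + direction
        if not np.isfinite(trace[j]):
            return None
        if trace[j] < half:
            # linear interpolation between frames i and j
            frac = (trace[i] - half) / (trace[i] - trace[j])
            return i + direction * frac
        i = j
    return None


def fdhm(pixels: np.ndarray, dff: np.ndarray, frame_interval: float
         ) -> float:
    """Full duration at half-maximum amplitude, in milliseconds.

    NaN if the temporal profile does not cross half-max on both sides
    within the map (clipped event).
    """
    vals = dff[pixels[:, 0], pixels[:, 1]]
    peak = int(np.argmax(vals))
    pb, pf = int(pixels[peak, 0]), int(pixels[peak, 1])
    amp = float(vals[peak])
    trace = dff[pb]
    left = _half_crossing(trace, pf, amp / 2.0, -1)
    right = _half_crossing(trace, pf, amp / 2.0, +1)
    if left is None or right is None:
        return float("nan")
    return (right - left) * frame_interval * 1000.0


def spatial_spread(pixels: np.ndarray, position_pitch: float) -> float:
    """Micrometres of cell occupied at >= half amplitude (union over
    frames); a single-bin event spans one pitch."""
    if pixels.size == 0:
        raise ValidationError("empty footprint")
    span = int(pixels[:, 0].max() - pixels[:, 0].min()) + 1
    return span * position_pitch


def velocity(pixels: np.ndarray, dff: np.ndarray, position_pitch: float,
             frame_interval: float) -> float:
    """Propagation velocity from half-max front positions, um/s.

    NaN (undefined) for events spanning fewer than 3 frames.
    """
    frames = np.unique(pixels[:, 1])
    if frames.size < 3:
        return float("nan")
    n_pos = dff.shape[0]
    t_list, lead, trail = [], [], []
    for f in frames:
        bins = np.sort(pixels[pixels[:, 1] == f, 0])
        col = dff[:, f]
        m = float(col[bins].max())
        if m <= 0:
            continue
        half = m / 2.0

        def edge(b_edge: int, direction: int) -> float:
            i = b_edge
            while 0 <= i + direction < n_pos:
                j = i + direction
                if not np.isfinite(col[j]) or col[j] < half:
                    frac = (col[i] - half) / (col[i] - col[j]) \
                        if np.isfinite(col[j]) and col[i] != col[j] else 0.0
                    return i + direction * frac
                i = j
            return float(i)

        t_list.append(f * frame_interval)
        lead.append(edge(int(bins[-1]), +1))
        trail.append(edge(int(bins[0]), -1))
    if len(t_list) < 3:
        return float("nan")
    t = np.asarray(t_list)
    slope_lead = np.polyfit(t, np.asarray(lead), 1)[0]
    slope_trail = np.polyfit(t, np.asarray(trail), 1)[0]
    return float(0.5 * (slope_lead + slope_trail) * position_pitch)


def initiation_site(pixels: np.ndarray, position_pitch: float) -> float:
    """Centroid position (um) of the event's earliest-frame pixels."""
    if pixels.size == 0:
        raise ValidationError("empty footprint")
    f0 = pixels[:, 1].min()
    bins = pixels[pixels[:, 1] == f0, 0]
    return float((bins.mean() + 0.5) * position_pitch)


def cluster_sites(events: list[CaEvent],
                  merge_radius: float = 2.0) -> list[FiringSite]:
    """Single-linkage clustering of initiation positions.

    Two events belong to one firing site iff their origins are
    chained by gaps of at most ``merge_radius`` micrometres.
    """
    if merge_radius <= 0:
        raise ValidationError("merge_radius must be > 0")
    if not events:
        return []
    order = np.argsort([e.origin_um for e in events])
    sites: list[FiringSite] = []
    members: list[int] = [int(order[0])]
    for idx in order[1:]:
        prev = events[members[-1]].origin_um
        if events[idx].origin_um - prev <= merge_radius:
            members.append(int(idx))
        else:
            sites.append(_make_site(events, members))
            members = [int(idx)]
    sites.append(_make_site(events, members))
    return sites


def _make_site(events: list[CaEvent], members: list[int]) -> FiringSite:
    pos = float(np.mean([events[i].origin_um for i in members]))
    return FiringSite(position_um=pos,
                      event_ids=tuple(events[i].id for i in members))


def frequency(n_events: int, window_duration: float,
              n_cells: int = 1) -> float:
    """Events fired per cell per second."""
    if window_duration <= 0:
        raise ValidationError("window_duration must be > 0")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    return n_events / (window_duration * n_cells)


def measure_event(footprint: np.ndarray, peak_px: tuple[int, int],
                  amp: float, stm: STMap, event_id: int,
                  cell_id: str) -> CaEvent:
    """Instantiate a CaEvent with all metrics measured on ``stm``."""
    dt, pitch = stm.frame_interval, stm.position_pitch
    flags: list[str] = []
    f_ms = fdhm(footprint, stm.dff, dt)
    if not np.isfinite(f_ms):
        flags.append("fdhm_clipped")
    v = velocity(footprint, stm.dff, pitch, dt)
    if not np.isfinite(v):
        flags.append("velocity_undefined")
    fmin, fmax = footprint[:, 1].min(), footprint[:, 1].max()
    return CaEvent(
        id=event_id,
        cell_id=cell_id,
        onset_time=float(fmin * dt),
        peak_time=float(peak_px[1] * dt),
        amplitude=float(amp),
        fdhm_ms=float(f_ms),
        spread_um=spatial_spread(footprint, pitch),
        velocity_um_s=float(v),
        origin_um=initiation_site(footprint, pitch),
        pixels=footprint,
        end_time=float((fmax + 1) * dt),
        flags=tuple(flags),
    )
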