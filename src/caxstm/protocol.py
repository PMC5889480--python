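"""EFS stimulus protocols and three-phase window analysis.

Electrical field stimulation of enteric nerves evokes a three-phase
Ca2+ response in ICC-DMP: suppression for ~2 s after stimulus onset,
escape from inhibition during the remaining train, and rebound
excitation after the train ends.  Quantification uses four fixed
half-open windows around a train of duration ``T`` starting at
``onset``::

    pre     [onset - 5, onset)        baseline
    initial [onset, onset + 2)        suppression
    late    [onset + T - 3, onset + T)  escape ("final 3 s of EFS")
    post    [onset + T, onset + T + 5)  rebound

For 5-s trains the initial and late windows tile the train exactly;
for longer trains the uncovered middle is reported as ``mid`` but kept
out of the phase summaries.  Events are assigned to windows by their
peak time (config switch for onset-based assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CaEvent, ValidationError
from . import metrics as _metrics

__all__ = ["StimulusProtocol", "AnalysisWindows", "WindowSummary",
           "make_windows", "summarize_window", "percent_change",
           "SUMMARY_QUANTITIES"]

SUMMARY_QUANTITIES = ("frequency", "amplitude", "fdhm_ms", "spread_um",
                      "abs_velocity", "n_sites")


@dataclass
class StimulusProtocol:
    """One EFS train: onset, duration and pulse parameters."""

    efs_onset: float            # s
    train_duration: float = 5.0  # s
    pulse_frequency: float = 10.0  # Hz
    pulse_width_ms: float = 0.5
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.train_duration <= 0:
            raise ValidationError("train_duration must be > 0")
        if self.efs_onset < 0:
            raise ValidationError("efs_onset must be >= 0")


@dataclass
class AnalysisWindows:
    """Half-open quantification windows [start, end) in seconds."""

    pre: tuple[float, float]
    initial: tuple[float, float]
    late: tuple[float, float]
    post: tuple[float, float]
    mid: tuple[float, float] | None = None

    def named(self) -> dict[str, tuple[float, float]]:
        out = {"pre": self.pre, "initial": self.initial,
               "late": self.late, "post": self.post}
        if self.mid is not None:
            out["mid"] = self.mid
        return out

    def window_of(self, t: float) -> str | None:
        """Window containing time ``t`` (half-open; boundaries belong
        to the later window), or None."""
        for name in ("pre", "initial", "mid", "late", "post"):
            w = getattr(self, name) if name != "mid" else self.mid
            if w is not None and w[0] <= t < w[1]:
                return name
        return None


def make_windows(protocol: StimulusProtocol, recording_span: float,
                 pre_s: float = 5.0, initial_s: float = 2.0,
                 late_s: float = 3.0, post_s: float = 5.0
                 ) -> AnalysisWindows:
    """Derive the pre / initial / late / post windows for a protocol.

    Raises (naming the offending window) when the recording does not
    cover a window or the train is shorter than the late window.
    """
    on, train = protocol.efs_onset, protocol.train_duration
    if train < late_s:
        raise ValidationError(
            f"late window ({late_s} s) longer than the train ({train} s)")
    if train < initial_s:
        raise ValidationError(
            f"initial window ({initial_s} s) longer than the train")
    if on - pre_s < 0:
        raise ValidationError("recording does not cover the pre window")
    if on + train + post_s > recording_span + 1e-9:
        raise ValidationError("recording does not cover the post window")
    mid = None
    if train > initial_s + late_s:
        mid = (on + initial_s, on + train - late_s)
    return AnalysisWindows(
        pre=(on - pre_s, on),
        initial=(on, on + initial_s),
        late=(on + train - late_s, on + train),
        post=(on + train, on + train + post_s),
        mid=mid,
    )


@dataclass
class WindowSummary:
    """Per-cell, per-window event statistics.

    ``frequency`` is events per second in the window; kinetic
    quantities are means over the window's events (NaN when the
    window is empty, with the window listed in ``empty_windows``).
    """

    cell_id: str
    table: pd.DataFrame           # index window, columns quantities + n
    empty_windows: tuple[str, ...] = ()
    unassigned_event_ids: tuple[int, ...] = ()

    def value(self, window: str, quantity: str) -> float:
        return float(self.table.loc[window, quantity])


def summarize_window(events: list[CaEvent], windows: AnalysisWindows,
                     cell_id: str = "cell0", merge_radius: float = 2.0,
                     assign_by: str = "peak") -> WindowSummary:
    """Assign events to windows and compute the six phase summaries.

    Events are binned by peak time (``assign_by='onset'`` switches to
    onset time); events inside the analysis span but in no summary
    window (possible only for trains longer than 5 s, via ``mid``)
    are reported separately and excluded from the phase summaries.
    """
    if assign_by not in ("peak", "onset"):
        raise ValidationError("assign_by must be 'peak' or 'onset'")
    named = windows.named()
    rows = {}
    empty: list[str] = []
    assigned: set[int] = set()
    for name, (a, b) in named.items():
        sel = []
        for ev in events:
            t = ev.peak_time if assign_by == "peak" else ev.onset_time
            if a <= t < b:
                sel.append(ev)
                assigned.add(ev.id)
        n = len(sel)
        row = {"n": n, "frequency": _metrics.frequency(n, b - a)}
        if n:
            row["amplitude"] = float(np.mean([e.amplitude for e in sel]))
            row["fdhm_ms"] = float(np.nanmean([e.fdhm_ms for e in sel]))
            row["spread_um"] = float(np.mean([e.spread_um for e in sel]))
            row["abs_velocity"] = float(np.nanmean(
                [abs(e.velocity_um_s) for e in sel]))
            row["n_sites"] = float(len(
                _metrics.cluster_sites(sel, merge_radius)))
        else:
            empty.append(name)
            for q in ("amplitude", "fdhm_ms", "spread_um", "abs_velocity",
                      "n_sites"):
                row[q] = np.nan
        rows[name] = row
    order = [w for w in ("pre", "initial", "mid", "late", "post")
             if w in rows]
    table = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    span = (min(a for a, _ in named.values()),
            max(b for _, b in named.values()))
    unassigned = tuple(
        ev.id for ev in events
        if ev.id not in assigned and span[0] <=
        (ev.peak_time if assign_by == "peak" else ev.onset_time) < span[1])
    return WindowSummary(cell_id=cell_id, table=table,
                         empty_windows=tuple(empty),
                         unassigned_event_ids=unassigned)


def percent_change(summary: WindowSummary, baseline_window: str = "pre"
                   ) -> pd.DataFrame:
    """Net percentage change of each quantity relative to the baseline
    window: ``100 * (value - baseline) / baseline``.

    NaN where the baseline is zero or undefined (flagged windows).
    """
    base = summary.table.loc[baseline_window]
    out = {}
    for window in summary.table.index:
        if window == baseline_window:
            continue
        row = {}
        for q in SUMMARY_QUANTITIES:
            b, v = base[q], summary.table.loc[window, q]
            row[q] = 100.0 * (v - b) / b \
                if np.isfinite(b) and b > 0 and np.isfinite(v) else np.nan
        out[window] = row
    return pd.DataFrame.from_dict(out, orient="index")
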