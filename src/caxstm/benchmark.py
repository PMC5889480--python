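"""Detection benchmarking against simulator ground truth.

A planted event counts as recovered when some detected event overlaps
it within per-event tolerances: the planted event's half-maximum
extent (FDHM around the peak in time, spread around the origin in
position) must overlap the detection's footprint, with a slack of one
planted FDHM in time and one planted spread in position.  The
predicate is evaluated independently per pair (no one-to-one
assignment): closely spaced transients that merge into one detected
complex still credit each planted event they cover, while a detection
covering no planted event is a false discovery.  Sensitivity
therefore measures signal recovery; counting fidelity under event
merging is quantified separately by rate-recovery bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CaEvent
from .synthetic import GroundTruth

__all__ = ["match_events", "detection_scores", "MatchResult"]


@dataclass
class MatchResult:
    truth_matched: np.ndarray    # bool per planted event
    detected_matched: np.ndarray  # bool per detected event

    @property
    def sensitivity(self) -> float:
        return float(self.truth_matched.mean()) \
            if self.truth_matched.size else float("nan")

    @property
    def fdr(self) -> float:
        return float(1.0 - self.detected_matched.mean()) \
            if self.detected_matched.size else 0.0


def match_events(truth: GroundTruth, detected: list[CaEvent],
                 position_pitch: float) -> MatchResult:
    """Match detected events to planted ground truth (see module doc)."""
    n_t, n_d = len(truth.events), len(detected)
    tm = np.zeros(n_t, dtype=bool)
    dm = np.zeros(n_d, dtype=bool)
    if n_t == 0 or n_d == 0:
        return MatchResult(tm, dm)

    det_t0 = np.array([d.onset_time for d in detected])
    det_t1 = np.array([d.end_time for d in detected])
    det_x0 = np.array([d.position_extent[0] * position_pitch
                       for d in detected])
    det_x1 = np.array([(d.position_extent[1] + 1) * position_pitch
                       for d in detected])

    for i, ev in enumerate(truth.events):
        fdhm_s = ev.fdhm / 1000.0
        t_lo = ev.peak_time - fdhm_s / 2.0
        t_hi = ev.peak_time + fdhm_s / 2.0
        x_lo = ev.origin_position - ev.spread_fwhm / 2.0
        x_hi = ev.origin_position + ev.spread_fwhm / 2.0
        ok = ((t_hi + fdhm_s >= det_t0) & (t_lo - fdhm_s <= det_t1) &
              (x_hi + ev.spread_fwhm >= det_x0) &
              (x_lo - ev.spread_fwhm <= det_x1))
        if ok.any():
            tm[i] = True
            dm |= ok
    return MatchResult(tm, dm)


def detection_scores(truth: GroundTruth, detected: list[CaEvent],
                     position_pitch: float) -> dict[str, float]:
    """Sensitivity and false-discovery rate for one recording."""
    m = match_events(truth, detected, position_pitch)
    return {"sensitivity": m.sensitivity, "fdr": m.fdr,
            "n_truth": float(len(truth.events)),
            "n_detected": float(len(detected))}
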