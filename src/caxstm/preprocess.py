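"""Motion stabilisation and dF/F0 normalisation.

Tissue motion is corrected by rigid translation: each frame is
registered to a single reference frame by phase cross-correlation
(with optional subpixel refinement by local upsampling), then shifted
back.  Residual motion in nicardipine-treated preparations is small,
so translation-only registration suffices.

Baseline fluorescence F0 is the mean of the lowest decile of each
spatial bin's time series — robust as long as transients occupy a
minority of samples — and dF/F0 = (F - F0) / F0.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import MovieStack, ShiftTrack, ValidationError

__all__ = ["estimate_shifts", "apply_shifts", "stabilize",
           "compute_f0", "to_dff"]


def estimate_shifts(movie: MovieStack, reference: int = 0,
                    upsample_factor: int = 20) -> ShiftTrack:
    """Estimate per-frame (row, col) displacement relative to a reference.

    Returns the displacement of each frame's content; the reference
    frame's displacement is exactly (0, 0).  Frames with zero variance
    cannot be registered and are assigned (0, 0) with a warning.
    """
    if not (0 <= reference < movie.n_frames):
        raise ValidationError(f"reference frame {reference} out of range")
    ref = movie.data[reference]
    shifts = np.zeros((movie.n_frames, 2))
    for k in range(movie.n_frames):
        if k == reference:
            continue
        frame = movie.data[k]
        if frame.std() == 0 or ref.std() == 0:
            warnings.warn(f"frame {k} has zero variance; shift set to (0,0)",
                          stacklevel=2)
            continue
        reg, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor)
        # phase correlation returns the shift registering `frame` onto
        # the reference, i.e. the negated displacement
        shifts[k] = -reg
    return ShiftTrack(shifts=shifts, reference=reference)


def apply_shifts(movie: MovieStack, shifts: ShiftTrack) -> MovieStack:
    """Translate each frame by the negated estimated displacement.

    Linear interpolation for subpixel shifts; border pixels exposed by
    the translation are filled with the frame median and the maximal
    fill margin is recorded in the metadata.
    """
    if len(shifts) != movie.n_frames:
        raise ValidationError("shift count does not match frame count")
    out = movie.data.copy()
    for k in range(movie.n_frames):
        s = shifts.shifts[k]
        if s[0] == 0.0 and s[1] == 0.0:
            continue
        fill = float(np.median(movie.data[k]))
        out[k] = ndimage.shift(movie.data[k], -s, order=1,
                               mode="constant", cval=fill)
    np.clip(out, 0.0, None, out=out)
    meta = dict(movie.metadata)
    meta["stabilized"] = True
    meta["border_fill_margin_px"] = float(np.ceil(np.abs(shifts.shifts).max()))
    return MovieStack(out, movie.frame_interval, movie.pixel_size, meta)


def stabilize(movie: MovieStack, reference: int = 0,
              upsample_factor: int = 20) -> tuple[MovieStack, ShiftTrack]:
    """Estimate and correct rigid drift in one call."""
    shifts = estimate_shifts(movie, reference, upsample_factor)
    return apply_shifts(movie, shifts), shifts


def compute_f0(trace: np.ndarray, quantile: float = 0.10) -> float:
    """Baseline fluorescence: mean of the lowest ``quantile`` of samples.

    Insensitive to transients occupying a minority of the trace.
    Raises if the trace has no positive values or the baseline is not
    positive (normalisation would be undefined).
    """
    trace = np.asarray(trace, dtype=np.float64).ravel()
    if trace.size == 0:
        raise ValidationError("empty trace")
    if not np.any(trace > 0):
        raise ValidationError("trace has no positive values; cannot "
                              "compute F0")
    k = max(1, int(round(quantile * trace.size)))
    f0 = float(np.mean(np.sort(trace)[:k]))
    if f0 <= 0:
        raise ValidationError("baseline F0 is not positive")
    return f0


def to_dff(F: np.ndarray | float, F0: float) -> np.ndarray | float:
    """dF/F0 = (F - F0) / F0 with F0 > 0."""
    if F0 <= 0:
        raise ValidationError("F0 must be > 0")
    return (np.asarray(F, dtype=np.float64) - F0) / F0
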