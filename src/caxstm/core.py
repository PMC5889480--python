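"""Core data containers shared across the pipeline.

Conventions
-----------
* Movies are ``(frame, row, col)`` arrays; frame ``k`` is at time
  ``k * frame_interval`` seconds (first frame at t = 0).
* ST maps are ``(position bin, frame)`` arrays.  Position bin ``p``
  covers the half-open interval ``[p * pitch, (p + 1) * pitch)`` in
  micrometres from one end of the cell; bin centres sit at
  ``(p + 0.5) * pitch``.
* Amplitudes are dimensionless dF/F0 once normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class MovieStack:
    """A raw fluorescence recording.

    Parameters
    ----------
    data
        ``(frame, row, col)`` intensity array, finite and non-negative.
    frame_interval
        Seconds per frame.
    pixel_size
        Micrometres per pixel (isotropic).
    metadata
        Free-form key/value provenance.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValidationError("movie must be 3-D with at least 2 frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValidationError("frame_interval and pixel_size must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("movie intensities must be finite")
        if self.data.min() < 0:
            raise ValidationError("movie intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ShiftTrack:
    """Per-frame rigid displacement relative to a reference frame.

    ``shifts[k]`` is the (row, col) displacement, in pixels, of frame
    ``k``'s content relative to the reference frame; stabilisation
    translates each frame by the negated displacement.
    """

    shifts: np.ndarray
    reference: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValidationError("shifts must be an (n_frames, 2) array")
        if not np.allclose(self.shifts[self.reference], 0.0):
            raise ValidationError("reference frame shift must be (0, 0)")

    def __len__(self) -> int:
        return self.shifts.shape[0]


@dataclass
class CellROI:
    """A whole-cell region of interest.

    Either ``vertices`` (polygon, (row, col) pixel coordinates) or a
    boolean ``mask`` must be supplied; the mask is rasterised lazily
    from the polygon when absent.
    """

    cell_id: str = "cell0"
    animal_id: str = "animal0"
    condition: str = "control"
    vertices: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.vertices is None and self.mask is None:
            raise ValidationError("ROI needs polygon vertices or a mask")
        if self.vertices is not None:
            self.vertices = np.asarray(self.vertices, dtype=np.float64)
            if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
                raise ValidationError("ROI polygon needs >= 3 vertices")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValidationError("ROI mask is empty")

    def mask_for(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this ROI on a frame of the given shape."""
        if self.mask is not None:
            if self.mask.shape != frame_shape:
                raise ValidationError(
                    f"ROI mask shape {self.mask.shape} != frame {frame_shape}"
                )
            return self.mask
        from skimage.draw import polygon

        rr, cc = polygon(self.vertices[:, 0], self.vertices[:, 1], frame_shape)
        if rr.size == 0:
            raise ValidationError("ROI polygon rasterises to an empty mask")
        out = np.zeros(frame_shape, dtype=bool)
        out[rr, cc] = True
        return out


@dataclass
class STMap:
    """Spatio-temporal map of one cell: position along the cell x time.

    ``raw_F`` holds mean fluorescence per position bin and frame;
    ``dff`` the baseline-normalised dF/F0 layer of the same shape.
    """

    raw_F: np.ndarray
    dff: np.ndarray
    position_pitch: float
    frame_interval: float
    centerline: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_F = np.asarray(self.raw_F, dtype=np.float64)
        self.dff = np.asarray(self.dff, dtype=np.float64)
        if self.raw_F.shape != self.dff.shape:
            raise ValidationError("raw_F and dff must share a shape")
        if self.raw_F.ndim != 2:
            raise ValidationError("ST map layers must be 2-D (position, frame)")
        if self.position_pitch <= 0 or self.frame_interval <= 0:
            raise ValidationError("position_pitch and frame_interval must be > 0")

    @property
    def n_positions(self) -> int:
        return self.raw_F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw_F.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def length(self) -> float:
        return self.n_positions * self.position_pitch

    def positions(self) -> np.ndarray:
        """Bin-centre positions in micrometres."""
        return (np.arange(self.n_positions) + 0.5) * self.position_pitch

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class Particle:
    """A connected above-threshold component on the processed ST map."""

    pixels: np.ndarray  # (k, 2) int array of (position bin, frame)
    id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValidationError("particle pixels must be (k, 2)")

    @property
    def area(self) -> int:
        return self.pixels.shape[0]


@dataclass
class CaEvent:
    """One detected Ca2+ transient with its derived metrics.

    ``pixels`` is the event footprint on the dF/F0 map: the connected
    region at or above half the event's peak amplitude.  Metrics that
    could not be measured (clipped FDHM, too-brief velocity fits) are
    NaN and the reason is recorded in ``flags``.
    """

    id: int
    cell_id: str
    onset_time: float
    peak_time: float
    amplitude: float
    fdhm_ms: float
    spread_um: float
    velocity_um_s: float
    origin_um: float
    pixels: np.ndarray
    end_time: float = np.nan
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp)
        if self.pixels.size == 0:
            raise ValidationError("event footprint is empty")
        if self.amplitude <= 0:
            raise ValidationError("event amplitude must be > 0")
        if self.onset_time > self.peak_time + 1e-12:
            raise ValidationError("event onset must not follow its peak")

    @property
    def position_extent(self) -> tuple[int, int]:
        """(min, max) position bin of the footprint."""
        return int(self.pixels[:, 0].min()), int(self.pixels[:, 0].max())

    @property
    def frame_extent(self) -> tuple[int, int]:
        """(min, max) frame index of the footprint."""
        return int(self.pixels[:, 1].min()), int(self.pixels[:, 1].max())


@dataclass
class FiringSite:
    """A recurrent initiation locus along the cell."""

    position_um: float
    event_ids: tuple[int, ...]

    @property
    def n_events(self) -> int:
        return len(self.event_ids)
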