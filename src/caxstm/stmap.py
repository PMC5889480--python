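"""Whole-cell ROI -> spatio-temporal (position x time) map construction.

The cell is parameterised by a centerline: for near-linear cells the
principal axis of the ROI mask, sampled at one-pixel pitch; for
curved cells (transverse-centroid sagitta beyond a threshold) the
ordered skeleton of the mask, extended to the mask boundary at both
ends.  Every ROI
pixel is assigned to its nearest centerline point, and the ST map row
``p`` is the mean fluorescence over the pixels assigned to point ``p``
at each frame.  dF/F0 is computed per position bin from its own
time series.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .core import CellROI, MovieStack, STMap, ValidationError
from .preprocess import compute_f0, to_dff

__all__ = ["extract_centerline", "build_stmap"]


def _principal_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                 np.ndarray]:
    """Centroid, unit axis and eigenvalues of the coordinate cloud."""
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    # deterministic orientation: dominant component points positive
    if axis[int(np.argmax(np.abs(axis)))] < 0:
        axis = -axis
    return centroid, axis, np.sort(evals)[::-1]


def _skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Ordered (row, col) path along the skeleton of ``mask``.

    The longest geodesic between skeleton endpoints, found by a
    double breadth-first search, extended at both ends along the local
    tangent until the mask boundary so the path spans the full cell.
    """
    skel = skeletonize(mask)
    pts = np.argwhere(skel)
    if pts.shape[0] < 2:
        raise ValidationError("ROI too thin to skeletonize")
    index = {tuple(p): i for i, p in enumerate(pts)}
    nbrs: list[list[int]] = [[] for _ in range(len(pts))]
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int) -> tuple[int, dict[int, int]]:
        parent = {start: -1}
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if v not in parent:
                        parent[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, parent

    far, _ = bfs(0)
    end, parent = bfs(far)
    path = [end]
    while parent[path[-1]] != -1:
        path.append(parent[path[-1]])
    path_pts = pts[np.asarray(path[::-1])].astype(float)

    # extend both ends along the local tangent to the mask boundary
    def extend(tail: np.ndarray, ahead: np.ndarray) -> list[np.ndarray]:
        d = tail - ahead
        n = np.hypot(*d)
        if n == 0:
            return []
        d = d / n
        out = []
        p = tail.copy()
        for _ in range(mask.shape[0] + mask.shape[1]):
            p = p + d
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]
                    and mask[r, c]):
                break
            out.append(p.copy())
        return out

    k = min(5, len(path_pts) - 1)
    head_ext = extend(path_pts[0], path_pts[k])[::-1]
    tail_ext = extend(path_pts[-1], path_pts[-1 - k])
    return np.vstack([head_ext + [p for p in path_pts] + tail_ext]) \
        if (head_ext or tail_ext) else path_pts


def extract_centerline(roi: CellROI, pixel_size: float,
                       frame_shape: tuple[int, int] | None = None,
                       curvature_threshold_px: float = 2.0
                       ) -> tuple[np.ndarray, float]:
    """Ordered centerline points (row, col) and the position pitch (um).

    Near-linear masks use the principal axis sampled at one-pixel
    steps; masks whose transverse-centroid drift along the axis (the
    sagitta) exceeds ``curvature_threshold_px`` fall back to
    skeletonization.
    """
    if frame_shape is None:
        if roi.mask is None:
            v = roi.vertices
            frame_shape = (int(np.ceil(v[:, 0].max())) + 2,
                           int(np.ceil(v[:, 1].max())) + 2)
        else:
            frame_shape = roi.mask.shape
    mask = roi.mask_for(frame_shape)
    coords = np.argwhere(mask).astype(float)
    if coords.shape[0] < 3:
        raise ValidationError("ROI mask has fewer than 3 pixels")

    centroid, axis, evals = _principal_axis(coords)
    if evals[0] <= 0:
        raise ValidationError("degenerate ROI mask")

    # curvature measure: drift of the transverse centroid along the
    # principal axis (the sagitta); insensitive to cell width
    proj = (coords - centroid) @ axis
    perp = (coords - centroid) @ np.array([-axis[1], axis[0]])
    bins = np.clip(((proj - proj.min()) // 5.0).astype(int), 0, None)
    centres = np.array([perp[bins == b].mean() for b in range(bins.max() + 1)
                        if np.any(bins == b)])
    sagitta = centres.max() - centres.min() if centres.size else 0.0

    if sagitta <= curvature_threshold_px:
        s = np.arange(proj.min(), proj.max() + 1e-9, 1.0)
        pts = centroid[None, :] + s[:, None] * axis[None, :]
    else:
        pts = _skeleton_path(mask)
        # deterministic orientation along the principal axis
        if (pts[-1] - pts[0]) @ axis < 0:
            pts = pts[::-1]

    return pts, float(pixel_size)


def centerline_length(centerline: np.ndarray, pixel_size: float) -> float:
    """Arc length of the centerline in micrometres."""
    steps = np.diff(centerline, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum() * pixel_size)


def build_stmap(movie: MovieStack, roi: CellROI,
                curvature_threshold_px: float = 2.0) -> STMap:
    """Average a stabilised movie over the ROI into a position x time map.

    ``raw_F[p, t]`` is the mean intensity over ROI pixels nearest to
    centerline point ``p`` at frame ``t``; the dF/F0 layer is computed
    per bin (lowest-decile baseline).  Position bins left empty by the
    nearest-point assignment are filled by neighbour interpolation
    with a warning.
    """
    frame_shape = movie.data.shape[1:]
    centerline, pitch_px = extract_centerline(
        roi, movie.pixel_size, frame_shape, curvature_threshold_px)
    mask = roi.mask_for(frame_shape)
    pix = np.argwhere(mask)

    tree = cKDTree(centerline)
    _, bin_idx = tree.query(pix.astype(float))
    n_bins = centerline.shape[0]

    raw = np.full((n_bins, movie.n_frames), np.nan)
    flat = movie.data[:, pix[:, 0], pix[:, 1]]  # (frames, n_pix)
    counts = np.bincount(bin_idx, minlength=n_bins)
    sums = np.zeros((movie.n_frames, n_bins))
    np.add.at(sums.T, bin_idx, flat.T)
    nonempty = counts > 0
    raw[nonempty] = (sums[:, nonempty] / counts[nonempty]).T

    if not nonempty.all():
        warnings.warn(f"{(~nonempty).sum()} empty position bins filled by "
                      "neighbour interpolation", stacklevel=2)
        idx = np.arange(n_bins)
        for t in range(movie.n_frames):
            col = raw[:, t]
            good = np.isfinite(col)
            raw[:, t] = np.interp(idx, idx[good], col[good])

    dff = np.empty_like(raw)
    for p in range(n_bins):
        f0 = compute_f0(raw[p])
        dff[p] = to_dff(raw[p], f0)

    return STMap(
        raw_F=raw, dff=dff,
        position_pitch=movie.pixel_size,
        frame_interval=movie.frame_interval,
        centerline=centerline,
        provenance={"cell_id": roi.cell_id, "animal_id": roi.animal_id,
                    "condition": roi.condition},
    )
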