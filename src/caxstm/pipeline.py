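"""End-to-end composition: movie -> stabilised ST maps -> events ->
window summaries -> group statistics, with provenance."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as cio
from .core import ValidationError
from .detect import detect_events
from .preprocess import stabilize
from .protocol import make_windows, percent_change, summarize_window
from .stmap import build_stmap


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except ValidationError as e:
                raise StageError(f"[{name}] {e}") from e
        return wrapped
    return deco


def run_pipeline(config: cio.RunConfig) -> dict[str, object]:
    """Run the full analysis described by a RunConfig.

    Writes stabilised ST maps (TIFF), the event table (CSV + JSON),
    per-cell window summaries and percent changes (CSV) and a run
    manifest into ``config.out_dir``.  Returns the in-memory objects
    keyed by stage.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    movie = _stage("read_movie")(cio.read_movie)(
        config.movie_path, config.pixel_size, config.frame_interval)
    rois = _stage("read_roi")(cio.read_roi)(config.roi_path)
    protocol = None
    if config.protocol_path is not None:
        protocol = _stage("read_protocol")(cio.read_protocol)(
            config.protocol_path)

    if config.stabilize:
        movie, shifts = _stage("stabilize")(stabilize)(
            movie, config.reference_frame)
    else:
        shifts = None

    results: dict[str, object] = {"movie": movie, "shifts": shifts,
                                  "rois": rois, "protocol": protocol}
    all_events = []
    summaries = []
    pc_rows = []
    for roi in rois:
        stm = _stage("build_stmap")(build_stmap)(movie, roi)
        cio.write_stmap(stm, out / f"stmap_{roi.cell_id}.tif")
        events = _stage("detect")(detect_events)(
            stm, config.detection, cell_id=roi.cell_id)
        all_events.extend(events)
        if protocol is not None:
            windows = _stage("windows")(make_windows)(
                protocol, stm.duration)
            summary = summarize_window(events, windows, roi.cell_id,
                                       config.merge_radius_um)
            summaries.append(summary)
            pc = percent_change(summary)
            pc.insert(0, "cell_id", roi.cell_id)
            pc_rows.append(pc)
        results[f"stmap_{roi.cell_id}"] = stm

    cio.write_events(all_events, out / "events.csv", out / "events.json")
    results["events"] = all_events

    if summaries:
        tab = pd.concat([s.table.assign(cell_id=s.cell_id) for s in summaries])
        tab.index.name = "window"
        tab.to_csv(out / "window_summaries.csv")
        pd.concat(pc_rows).rename_axis("window") \
            .to_csv(out / "percent_change.csv")
        results["summaries"] = summaries

    cio.write_manifest(out, config, config.seed,
                       extra={"n_cells": len(rois),
                              "n_events": len(all_events)})
    return results
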