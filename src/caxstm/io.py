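"""File formats, run configuration and provenance.

Formats
-------
* Movies and ST maps: 32-bit float TIFF; acquisition metadata
  (um/px, s/frame) is stored as JSON in the TIFF description and can
  be overridden from the run configuration (with a warning on
  conflict).
* ROIs: a JSON list of polygons with cell / animal / condition labels
  (vertices in 0-based (row, col) pixel coordinates); a plain-text
  importer accepts rectangular ROIs as ``cell_id r0 c0 r1 c1`` lines.
* Stimulus protocols: JSON with ``onset_s, train_s, pulse_hz,
  pulse_ms, condition``.
* Events and summaries: CSV (full float precision, round-trip safe)
  plus an events JSON carrying the pixel footprints.
* Every output directory receives a manifest recording the config
  hash, seed and package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import CaEvent, CellROI, MovieStack, STMap, ValidationError
from .detect import DetectionParams
from .protocol import StimulusProtocol
from .synthetic import GroundTruth, GroundTruthEvent, RateEnvelope, \
    SimulationConfig

__all__ = [
    "read_movie", "write_movie", "read_stmap", "write_stmap",
    "read_roi", "write_roi", "read_rect_rois",
    "read_protocol", "write_protocol",
    "write_events", "read_events",
    "write_ground_truth", "read_ground_truth",
    "RunConfig", "load_run_config", "config_hash", "write_manifest",
    "load_simulation_config", "save_simulation_config",
]

EVENT_COLUMNS = ["id", "cell_id", "onset_time", "peak_time", "amplitude",
                 "fdhm_ms", "spread_um", "velocity_um_s", "origin_um",
                 "end_time", "flags"]


# ---------------------------------------------------------------------------
# TIFF


def write_movie(movie: MovieStack, path: str | Path) -> None:
    meta = {"pixel_size_um": movie.pixel_size,
            "frame_interval_s": movie.frame_interval,
            **{k: v for k, v in movie.metadata.items()
               if isinstance(v, (str, int, float, bool))}}
    tifffile.imwrite(path, movie.data.astype(np.float32),
                     description=json.dumps(meta))


def _read_tiff_meta(path: str | Path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        if not isinstance(meta, dict):
            meta = {}
    except (json.JSONDecodeError, TypeError):
        meta = {}
    return np.asarray(data, dtype=np.float64), meta


def read_movie(path: str | Path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> MovieStack:
    """Load a TIFF stack; explicit geometry overrides file metadata
    (warning on conflict)."""
    data, meta = _read_tiff_meta(path)
    file_px = meta.get("pixel_size_um")
    file_dt = meta.get("frame_interval_s")
    px = _resolve(pixel_size, file_px, "pixel_size", path)
    dt = _resolve(frame_interval, file_dt, "frame_interval", path)
    if px is None or dt is None:
        raise ValidationError(
            f"{path}: pixel_size / frame_interval neither in file metadata "
            "nor supplied")
    return MovieStack(data, dt, px, metadata=meta)


def _resolve(override, from_file, name, path):
    if override is not None and from_file is not None and \
            not np.isclose(override, from_file):
        warnings.warn(f"{path}: config {name}={override} overrides file "
                      f"metadata {from_file}", stacklevel=3)
    return override if override is not None else from_file


def write_stmap(stm: STMap, path: str | Path) -> None:
    meta = {"position_pitch_um": stm.position_pitch,
            "frame_interval_s": stm.frame_interval,
            "layers": ["raw_F", "dff"],
            "provenance": {k: v for k, v in stm.provenance.items()
                           if isinstance(v, (str, int, float, bool))}}
    stack = np.stack([stm.raw_F, stm.dff]).astype(np.float32)
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_stmap(path: str | Path) -> STMap:
    data, meta = _read_tiff_meta(path)
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValidationError(f"{path}: expected a 2-layer ST-map TIFF")
    return STMap(raw_F=data[0], dff=data[1],
                 position_pitch=meta["position_pitch_um"],
                 frame_interval=meta["frame_interval_s"],
                 provenance=meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# ROI / protocol JSON


def write_roi(rois: list[CellROI], path: str | Path) -> None:
    recs = []
    for roi in rois:
        if roi.vertices is None:
            raise ValidationError(
                "only polygon ROIs can be written as JSON; mask ROIs have "
                "no compact representation")
        recs.append({"cell_id": roi.cell_id, "animal_id": roi.animal_id,
                     "condition": roi.condition,
                     "vertices": np.asarray(roi.vertices).tolist()})
    Path(path).write_text(json.dumps(recs, indent=1))


def read_roi(path: str | Path) -> list[CellROI]:
    try:
        recs = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"{path}: malformed ROI JSON: {e}") from e
    out = []
    for i, r in enumerate(recs):
        try:
            out.append(CellROI(cell_id=r["cell_id"],
                               animal_id=r.get("animal_id", "animal0"),
                               condition=r.get("condition", "control"),
                               vertices=np.asarray(r["vertices"], float)))
        except (KeyError, TypeError) as e:
            raise ValidationError(
                f"{path}: ROI record {i} missing field: {e}") from e
    return out


def read_rect_rois(path: str | Path) -> list[CellROI]:
    """Rectangular text ROIs: whitespace-separated
    ``cell_id r0 c0 r1 c1`` per line (# comments allowed)."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValidationError(
                f"{path}:{ln}: expected 'cell_id r0 c0 r1 c1'")
        cid, r0, c0, r1, c1 = parts[0], *map(float, parts[1:])
        out.append(CellROI(cell_id=cid, vertices=np.array(
            [[r0, c0], [r0, c1], [r1, c1], [r1, c0]])))
    return out


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "onset_s": protocol.efs_onset, "train_s": protocol.train_duration,
        "pulse_hz": protocol.pulse_frequency,
        "pulse_ms": protocol.pulse_width_ms,
        "condition": protocol.condition}, indent=1))


def read_protocol(path: str | Path) -> StimulusProtocol:
    try:
        d = json.loads(Path(path).read_text())
        return StimulusProtocol(
            efs_onset=d["onset_s"], train_duration=d["train_s"],
            pulse_frequency=d.get("pulse_hz", 10.0),
            pulse_width_ms=d.get("pulse_ms", 0.5),
            condition=d.get("condition", "control"))
    except (json.JSONDecodeError, KeyError, TypeError) as e:
        raise ValidationError(f"{path}: malformed protocol JSON: {e}") from e


# ---------------------------------------------------------------------------
# events


def events_frame(events: list[CaEvent]) -> pd.DataFrame:
    rows = [{**{c: getattr(e, c) for c in EVENT_COLUMNS if c != "flags"},
             "flags": ";".join(e.flags)} for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events: list[CaEvent], csv_path: str | Path,
                 json_path: str | Path | None = None) -> None:
    """Event table as CSV (all metric columns at full float precision);
    optionally a JSON sidecar carrying the pixel footprints."""
    events_frame(events).to_csv(csv_path, index=False,
                                float_format="%.17g")
    if json_path is not None:
        recs = [{**{c: getattr(e, c) for c in EVENT_COLUMNS if c != "flags"},
                 "flags": list(e.flags),
                 "pixels": e.pixels.tolist()} for e in events]
        Path(json_path).write_text(json.dumps(recs))


def read_events(csv_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{csv_path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# ground truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "config": _config_dict(truth.config),
        "site_positions": np.asarray(truth.site_positions).tolist(),
        "events": [dataclasses.asdict(e) for e in truth.events]}))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    cfg = _config_from_dict(d["config"])
    events = [GroundTruthEvent(**e) for e in d["events"]]
    return GroundTruth(events=events, config=cfg,
                       site_positions=np.asarray(d["site_positions"]))


def _config_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    env = d.pop("rate_envelope")
    d["rate_envelope"] = list(env["segments"]) if env else None
    return d


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    segs = d.pop("rate_envelope", None)
    env = RateEnvelope(tuple(tuple(s) for s in segs)) if segs else None
    for key in ("amp_range", "fdhm_range_ms", "spread_fwhm_range",
                "velocity_range", "drift_per_frame"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("site_positions") is not None:
        d["site_positions"] = list(d["site_positions"])
    return SimulationConfig(rate_envelope=env, **d)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh) or {})


def save_simulation_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# run configuration and provenance


@dataclass
class RunConfig:
    """Everything one pipeline run needs, resolvable from YAML."""

    movie_path: str
    roi_path: str
    out_dir: str
    protocol_path: str | None = None
    pixel_size: float | None = None
    frame_interval: float | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    merge_radius_um: float = 2.0
    stabilize: bool = True
    reference_frame: int = 0
    seed: int = 0
    condition: str = "control"

    def validate_paths(self) -> None:
        for name in ("movie_path", "roi_path", "protocol_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name}: no such file: {p}")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    det = d.pop("detection", None)
    cfg = RunConfig(**d)
    if det:
        cfg.detection = DetectionParams(**det)
    return cfg


def config_hash(obj: Any) -> str:
    """Stable sha256 over a canonical JSON rendering of a config."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(out_dir: str | Path, config: Any, seed: int,
                   extra: dict | None = None) -> Path:
    from . import __version__

    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps({
        "config_hash": config_hash(config),
        "seed": seed,
        "versions": {"caxstm": __version__, "numpy": np.__version__},
        **(extra or {})}, indent=1))
    return path
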