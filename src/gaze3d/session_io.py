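"""Serialization of sessions, feature tracks and fitted models.

Formats are deliberately diff-able and language-neutral: JSON for sessions,
models and ground truth, CSV for tabular feature tracks, YAML for scenario
and pipeline configuration.  Every file carries ``schema_version`` and
declares its length unit; anything but mm is rejected on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .convergence_model import ConvergenceModel, EyeConvergenceLaw
from .errors import SchemaError
from .stereo_reconstruction import EyeFeatureSet

__all__ = [
    "SessionRecord",
    "write_session",
    "read_session",
    "write_model",
    "read_model",
    "write_feature_tracks",
    "read_feature_tracks",
    "write_detections",
    "load_scenario_yaml",
]

SCHEMA_VERSION = 1

_TRACK_COLUMNS = [
    "frame_id", "placement", "fixation",
    "pupil_left_x", "pupil_left_y", "pupil_left_z",
    "pupil_right_x", "pupil_right_y", "pupil_right_z",
    "size_left", "size_right",
    "corner_left_x", "corner_left_y", "corner_left_z",
    "corner_right_x", "corner_right_y", "corner_right_z",
]


@dataclass
class SessionRecord:
    """Serializable calibration session: rig constants + capture records."""

    captures: list                           # EyeFeatureSet records
    board_spacing: float = 150.0
    board_distances: tuple = ()
    units: str = "mm"
    schema_version: int = SCHEMA_VERSION
    provenance: dict = field(default_factory=dict)

    def placements(self):
        """Group captures into per-placement 4-fixation lists."""
        groups: dict = {}
        for f in self.captures:
            groups.setdefault(f.placement, []).append(f)
        out = []
        for j in sorted(groups):
            feats = sorted(groups[j], key=lambda f: (f.fixation or 0))
            out.append(feats)
        return out


def _features_to_dict(f: EyeFeatureSet) -> dict:
    return {
        "placement": f.placement, "fixation": f.fixation,
        "left": {"pupil": list(map(float, f.pupil_left)), "size": float(f.size_left)},
        "right": {"pupil": list(map(float, f.pupil_right)), "size": float(f.size_right)},
        "corners": {"left": list(map(float, f.corner_left)),
                    "right": list(map(float, f.corner_right))},
    }


def _features_from_dict(d: dict) -> EyeFeatureSet:
    try:
        return EyeFeatureSet(
            pupil_left=d["left"]["pupil"], pupil_right=d["right"]["pupil"],
            size_left=d["left"]["size"], size_right=d["right"]["size"],
            corner_left=d["corners"]["left"], corner_right=d["corners"]["right"],
            fixation=d.get("fixation"), placement=d.get("placement"))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed capture record: {exc}") from exc


def write_session(path, record: SessionRecord):
    payload = {
        "schema_version": record.schema_version,
        "units": record.units,
        "board": {"spacing": record.board_spacing,
                  "distances": list(record.board_distances)},
        "provenance": record.provenance,
        "captures": [_features_to_dict(f) for f in record.captures],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _check_header(payload: dict, path):
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{path}: schema_version {version!r} != {SCHEMA_VERSION}")
    units = payload.get("units")
    if units != "mm":
        raise SchemaError(f"{path}: units {units!r}; this package requires mm")


def read_session(path) -> SessionRecord:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    _check_header(payload, path)
    board = payload.get("board", {})
    return SessionRecord(
        captures=[_features_from_dict(d) for d in payload.get("captures", [])],
        board_spacing=float(board.get("spacing", 150.0)),
        board_distances=tuple(board.get("distances", ())),
        units=payload["units"], schema_version=payload["schema_version"],
        provenance=payload.get("provenance", {}))


def write_model(path, model: ConvergenceModel, provenance: dict | None = None):
    payload = {
        "schema_version": SCHEMA_VERSION,
        "units": "mm",
        "eyes": {
            side: {
                "gamma": list(map(float, law.gamma)),
                "alpha": list(map(float, law.alpha)),
                "beta": list(map(float, law.beta)),
                "s_range": list(map(float, law.s_range)),
            }
            for side, law in (("left", model.left), ("right", model.right))
        },
        "reference": {"v0": list(map(float, model.v0)),
                      "origin": list(map(float, model.origin0))},
        "extrapolation_margin": model.extrapolation_margin,
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path) -> ConvergenceModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    _check_header(payload, path)
    laws = {}
    try:
        for side in ("left", "right"):
            d = payload["eyes"][side]
            laws[side] = EyeConvergenceLaw(
                gamma=np.asarray(d["gamma"], dtype=float),
                alpha=np.asarray(d["alpha"], dtype=float),
                beta=np.asarray(d["beta"], dtype=float),
                s_range=tuple(d["s_range"]))
        ref = payload["reference"]
        return ConvergenceModel(
            left=laws["left"], right=laws["right"],
            v0=ref["v0"], origin0=ref["origin"],
            extrapolation_margin=float(payload.get("extrapolation_margin", 0.10)))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed model: {exc}") from exc


def write_feature_tracks(path, features, frame_ids=None):
    """3D feature tracks as CSV (one row per fixation, mm)."""
    rows = []
    for k, f in enumerate(features):
        fid = frame_ids[k] if frame_ids is not None else k
        rows.append([fid, f.placement, f.fixation,
                     *f.pupil_left, *f.pupil_right,
                     f.size_left, f.size_right,
                     *f.corner_left, *f.corner_right])
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(path, index=False)


def read_feature_tracks(path):
    """Read a 3D feature-track CSV; errors name the offending row."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = []
    numeric = _TRACK_COLUMNS[3:]
    for idx, row in df.iterrows():
        vals = row[numeric]
        if vals.isna().any():
            raise SchemaError(f"{path}: row {idx + 1} has missing values")
        def opt(v):
            return None if pd.isna(v) else int(v)
        out.append(EyeFeatureSet(
            pupil_left=[row.pupil_left_x, row.pupil_left_y, row.pupil_left_z],
            pupil_right=[row.pupil_right_x, row.pupil_right_y, row.pupil_right_z],
            size_left=row.size_left, size_right=row.size_right,
            corner_left=[row.corner_left_x, row.corner_left_y, row.corner_left_z],
            corner_right=[row.corner_right_x, row.corner_right_y, row.corner_right_z],
            fixation=opt(row.fixation), placement=opt(row.placement)))
    return out


def write_detections(path, detections, frame_ids=None):
    """Per-camera 2D detections (pupil ellipse + corner) as CSV."""
    rows = []
    for k, det in enumerate(detections):
        fid = frame_ids[k] if frame_ids is not None else k
        e = det.ellipse
        rows.append([fid, det.camera_id, e.x0, e.y0, e.a, e.b, e.alpha,
                     det.corner.x, det.corner.y])
    cols = ["frame_id", "camera_id", "ellipse_x0", "ellipse_y0",
            "ellipse_a", "ellipse_b", "ellipse_alpha", "corner_x", "corner_y"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def load_scenario_yaml(path) -> dict:
    """Scenario keyword arguments from a YAML file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: scenario YAML must be a mapping")
    return data
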