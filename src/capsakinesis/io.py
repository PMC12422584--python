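"""Shared I/O: the track CSV dialect, YAML configs, and run manifests.

Track files are plain CSV with columns ``cell_id, frame, t_seconds, x_um,
y_um`` — one row per detection, missing detections encoded as absent rows.
Configs are single YAML files with per-module sections; unknown keys are
rejected and defaults are filled before hashing, so the config hash is
independent of key order and of which defaults were spelled out. Every
output directory receives exactly one manifest recording the command, the
config hash, the seeds and the package version — enough to regenerate the
artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import FilterPolicy
from .dose_response import ResponseCurve
from .sim import MotilityParams, SimConfig
from .synth import DoseGenConfig, TrackGenConfig
from .tracks import TRACK_COLUMNS, TrackSet

__all__ = ["read_tracks", "write_tracks", "load_config", "config_hash",
           "RunManifest", "write_manifest", "TrackFormatError"]


class TrackFormatError(ValueError):
    """Malformed track file; the message names the offending rows."""


def read_tracks(path) -> TrackSet:
    """Read a track CSV; round-trips losslessly with :func:`write_tracks`.

    Rows may appear in any order (sorting normalises them). Duplicated
    (cell_id, frame) pairs are rejected with the 1-based line numbers of
    both rows; non-finite positions are rejected naming the cell.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    # 1-based file line numbers: +2 for the header row and 0-based index
    lines = df.index.to_numpy() + 2
    dup = df.duplicated(subset=["cell_id", "frame"], keep=False)
    if dup.any():
        pairs = {}
        for ln, cid, fr in zip(lines[dup], df.loc[dup, "cell_id"],
                               df.loc[dup, "frame"]):
            pairs.setdefault((cid, fr), []).append(int(ln))
        detail = "; ".join(
            f"cell_id={cid!r} frame={fr} at lines {lns}"
            for (cid, fr), lns in sorted(pairs.items(), key=str))
        raise TrackFormatError(f"{path}: duplicated (cell_id, frame) rows: {detail}")
    bad = ~np.isfinite(df[["x_um", "y_um", "t_seconds"]]).all(axis=1)
    if bad.any():
        first = df.loc[bad].iloc[0]
        ln = int(lines[bad.to_numpy()][0])
        raise TrackFormatError(
            f"{path}: non-finite values for cell_id={first['cell_id']!r} "
            f"at line {ln}")
    try:
        return TrackSet.from_dataframe(df)
    except ValueError as exc:
        raise TrackFormatError(f"{path}: {exc}") from exc


def write_tracks(tracks: TrackSet, path) -> None:
    tracks.to_dataframe().to_csv(path, index=False)


_SECTION_TYPES = {
    "tracks": TrackGenConfig,
    "dose": DoseGenConfig,
    "sim": SimConfig,
    "policy": FilterPolicy,
    "response": ResponseCurve,
    "motility": MotilityParams,
}

_NESTED = {"response": ResponseCurve, "motility": MotilityParams}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"{context}: unknown keys {unknown}; "
                         f"allowed: {sorted(names)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            value = _build(_NESTED[key], value, f"{context}.{key}")
        elif isinstance(value, list) and key in ("seeds", "arena"):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{context}: {exc}") from exc


def load_config(path) -> dict:
    """Load and validate a YAML config with per-module sections.

    Recognised sections: ``tracks``, ``dose``, ``sim``, ``policy``,
    ``response``, ``motility``, plus a free-form ``fluor`` mapping. Unknown
    sections or keys raise with the offending name; defaults are filled by
    the section dataclasses.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    out = {}
    for section, data in raw.items():
        if section == "fluor":
            if not isinstance(data, dict):
                raise ValueError(f"{path}:fluor must be a mapping")
            out[section] = data
            continue
        cls = _SECTION_TYPES.get(section)
        if cls is None:
            raise ValueError(f"{path}: unknown section {section!r}; "
                             f"allowed: {sorted(_SECTION_TYPES) + ['fluor']}")
        out[section] = _build(cls, data, f"{path}:{section}")
    return out


def _canonical(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _canonical(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=str)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Deterministic digest of a config mapping or dataclass.

    Canonicalises to sorted-key JSON first, so serialisations that differ
    only in key order (or in spelling out defaults) hash identically.
    """
    payload = json.dumps(_canonical(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every result artifact."""

    command: str
    config_hash: str
    seeds: list
    package_version: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


def write_manifest(out_dir, command: str, config, seeds) -> RunManifest:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command=command, config_hash=config_hash(config),
                           seeds=list(seeds), package_version=__version__)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    return manifest
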