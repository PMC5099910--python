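"""File I/O: observation CSVs, parameter and range YAML, result JSON.

On-disk time convention is always days post-conception (``time_dpc``);
embryonic stage labels such as ``E17.5`` are accepted on input and
converted.  Trajectory exports add a derived postnatal-day column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .calibration import BootstrapResult, FitResult, ObservationSet, SearchRanges
from .dde import Trajectory
from .parameters import ModelSpec

__all__ = [
    "read_observations",
    "write_observations",
    "read_spec",
    "write_spec",
    "read_ranges",
    "write_ranges",
    "write_trajectory",
    "write_fit",
    "write_bootstrap",
    "parse_time_label",
]

PathLike = Union[str, Path]


def parse_time_label(value) -> float:
    """Convert a time entry to days post-conception.

    Accepts plain numbers (already dpc) and embryonic stage labels like
    ``E17.5``.
    """
    if isinstance(value, str):
        text = value.strip()
        if text and text[0] in "Ee":
            return float(text[1:])
        return float(text)
    return float(value)


def read_observations(path: PathLike) -> ObservationSet:
    """Read and validate a tidy observation CSV.

    Required columns: time_dpc, population, replicate, count_cells.
    Errors name the offending row.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ObservationSet.COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frame["time_dpc"] = frame["time_dpc"].map(parse_time_label)
    return ObservationSet(frame)


def write_observations(obs: ObservationSet, path: PathLike) -> None:
    # %.17g round-trips IEEE doubles exactly: write(read(x)) == x
    obs.frame.to_csv(path, index=False, float_format="%.17g")


def write_spec(spec: ModelSpec, path: PathLike) -> None:
    flat = spec.to_flat_dict()
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))


def read_spec(path: PathLike) -> ModelSpec:
    data = yaml.safe_load(Path(path).read_text())
    return ModelSpec.from_flat_dict(data)


def write_ranges(ranges: SearchRanges, path: PathLike) -> None:
    payload = {name: [float(lo), float(hi)] for name, (lo, hi) in ranges.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_ranges(path: PathLike) -> SearchRanges:
    data = yaml.safe_load(Path(path).read_text())
    ranges = SearchRanges({name: (float(lo), float(hi)) for name, (lo, hi) in data.items()})
    ranges.validate()
    return ranges


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_trajectory(traj: Trajectory, path: PathLike, metadata: dict | None = None) -> None:
    """Tidy trajectory CSV plus a JSON sidecar with provenance metadata."""
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    spec_flat = traj.spec.to_flat_dict()
    meta = {
        "spec": spec_flat,
        "spec_hash": config_hash(spec_flat),
        "influx_mode_postnatal": traj.influx_mode_postnatal.value,
        "t0": traj.t0,
        "birth_time": traj.birth_time,
        "t_end": traj.t_end,
        **(metadata or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_fit(result: FitResult, path: PathLike, metadata: dict | None = None) -> None:
    payload = result.to_dict()
    payload.update(metadata or {})
    payload["config_hash"] = config_hash(payload)
    Path(path).write_text(json.dumps(payload, indent=2))


def write_bootstrap(result: BootstrapResult, path: PathLike, metadata: dict | None = None) -> None:
    payload = result.to_dict()
    payload.update(metadata or {})
    payload["config_hash"] = config_hash(payload)
    Path(path).write_text(json.dumps(payload, indent=2))
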