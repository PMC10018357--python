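"""Tabular and image I/O for traces, gel lanes, survival data and results.

Traces travel as one CSV per dataset (``trace_id, frame, donor, acceptor``)
with a JSON sidecar holding the frame interval and, for simulated data, the
generating parameters.  Movies are multi-page TIFF.  Results serialise to
JSON with NumPy types coerced to plain Python.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .models import GelLane, KineticModel, MovieStack, RawTrace

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_gel_lane_csv",
    "read_gel_lane_csv",
    "write_json",
    "read_json",
    "load_config",
]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(data: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def write_traces_csv(
    traces: list[RawTrace], path: str | Path, sidecar: bool = True
) -> None:
    """One row per frame: ``trace_id, frame, donor, acceptor``."""
    frames = []
    for i, t in enumerate(traces):
        tid = t.trace_id or f"trace-{i:05d}"
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tid,
                    "frame": np.arange(len(t)),
                    "donor": t.donor,
                    "acceptor": t.acceptor,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["trace_id", "frame", "donor", "acceptor"]
    )
    path = Path(path)
    df.to_csv(path, index=False)
    if sidecar:
        meta: dict[str, Any] = {
            "frame_interval": traces[0].frame_interval if traces else 0.1,
            "n_traces": len(traces),
        }
        models = {
            id(t.truth.model): t.truth.model
            for t in traces
            if t.truth is not None and t.truth.model is not None
        }
        if len(models) == 1:
            meta["model"] = _jsonable(next(iter(models.values())))
        write_json(meta, path.with_suffix(".json"))


def read_traces_csv(path: str | Path) -> list[RawTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    frame_interval = 0.1
    if sidecar.exists():
        frame_interval = float(read_json(sidecar).get("frame_interval", 0.1))
    traces = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        traces.append(
            RawTrace(
                donor=g["donor"].to_numpy(float),
                acceptor=g["acceptor"].to_numpy(float),
                frame_interval=frame_interval,
                trace_id=str(tid),
            )
        )
    return traces


def write_movie_tiff(stack: MovieStack, path: str | Path) -> None:
    """Channels interleaved along the page axis: (frame, channel)."""
    n, c, h, w = stack.frames.shape
    tifffile.imwrite(str(path), stack.frames.reshape(n * c, h, w).astype(np.float32))


def read_movie_tiff(
    path: str | Path, psf_sigma: float, frame_interval: float = 0.1
) -> MovieStack:
    data = tifffile.imread(str(path)).astype(float)
    if data.ndim != 3 or data.shape[0] % 2:
        raise ValueError("expected an even-page single-plane TIFF stack")
    n2, h, w = data.shape
    return MovieStack(
        frames=data.reshape(n2 // 2, 2, h, w),
        spot_truth=[],
        psf_sigma=psf_sigma,
        frame_interval=frame_interval,
    )


def write_gel_lane_csv(lane: GelLane, path: str | Path) -> None:
    pd.DataFrame({"position": lane.positions, "density": lane.densities}).to_csv(
        path, index=False
    )


def read_gel_lane_csv(
    path: str | Path, lesion_position: int | None = None
) -> GelLane:
    df = pd.read_csv(path)
    return GelLane(
        positions=df["position"].to_numpy(int),
        densities=df["density"].to_numpy(float),
        lesion_position=lesion_position,
    )


def load_config(path: str | Path) -> dict[str, Any]:
    """YAML run configuration; returns a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg


def kinetic_model_from_dict(params: dict[str, Any]) -> KineticModel:
    fields = {f.name for f in dataclasses.fields(KineticModel)}
    unknown = set(params) - fields
    if unknown:
        raise ValueError(f"unknown kinetic-model parameters: {sorted(unknown)}")
    return KineticModel(**params)
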