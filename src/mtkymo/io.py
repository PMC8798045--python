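"""Readers and writers for the project's file formats.

All on-disk coordinates are physical units (s, nm, um); pixel conversions
happen only inside image-facing operations.  CSVs are comma-separated UTF-8
with a required header; kymographs are multi-page TIFFs (one channel per
page) with calibration and channel names in a JSON sidecar; phase
annotations are JSON.  Per-figure-style Excel count sheets (one row per
condition) are supported through openpyxl.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import (
    BindingEvent,
    EndTrajectory,
    Kymograph,
    NucleationDataset,
    PhaseAnnotation,
)

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_counts",
    "write_counts",
    "read_counts_excel",
    "write_counts_excel",
    "read_annotation",
    "write_annotation",
    "read_kymograph",
    "write_kymograph",
]

TRACE_COLUMNS = ["time_s", "position_nm"]
EVENT_COLUMNS = ["position_um", "t_on_s", "t_off_s", "censored", "condition"]
COUNT_COLUMNS = ["x_uM", "seeds_total", "seeds_nucleated"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def read_trace(path: str | Path) -> EndTrajectory:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, f"trace {path}")
    meta = _read_sidecar(path)
    return EndTrajectory(
        times=df["time_s"].to_numpy(float),
        positions=df["position_nm"].to_numpy(float),
        pixel_size=meta.get("pixel_size", 160.0),
        frame_interval=meta.get("frame_interval", 5.0),
        truth_phases=[tuple(p) for p in meta["truth_phases"]]
        if "truth_phases" in meta
        else None,
        truth_vertices=np.asarray(meta["truth_vertices"])
        if "truth_vertices" in meta
        else None,
    )


def write_trace(trajectory: EndTrajectory, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trajectory.times, "position_nm": trajectory.positions}
    ).to_csv(path, index=False)
    meta = {
        "pixel_size": trajectory.pixel_size,
        "frame_interval": trajectory.frame_interval,
    }
    if trajectory.truth_phases is not None:
        meta["truth_phases"] = [list(p) for p in trajectory.truth_phases]
    if trajectory.truth_vertices is not None:
        meta["truth_vertices"] = trajectory.truth_vertices.tolist()
    _write_sidecar(path, meta)


def read_events(path: str | Path) -> list[BindingEvent]:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, f"events {path}")
    return [
        BindingEvent(
            position_um=float(r.position_um),
            t_on=float(r.t_on_s),
            t_off=float(r.t_off_s),
            censored=bool(r.censored),
            condition=str(r.condition),
        )
        for r in df.itertuples()
    ]


def write_events(events: list[BindingEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "position_um": e.position_um,
                "t_on_s": e.t_on,
                "t_off_s": e.t_off,
                "censored": e.censored,
                "condition": e.condition,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    ).to_csv(path, index=False)


def read_counts(path: str | Path) -> NucleationDataset:
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, f"counts {path}")
    return NucleationDataset(
        x_uM=df["x_uM"].to_numpy(float),
        seeds_total=df["seeds_total"].to_numpy(int),
        seeds_nucleated=df["seeds_nucleated"].to_numpy(int),
    )


def write_counts(dataset: NucleationDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_uM": dataset.x_uM,
            "seeds_total": dataset.seeds_total,
            "seeds_nucleated": dataset.seeds_nucleated,
        }
    ).to_csv(path, index=False)


def read_counts_excel(path: str | Path, sheet: int | str = 0) -> NucleationDataset:
    """Read a per-condition counts sheet (columns x_uM/seeds_total/seeds_nucleated)."""
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    _require_columns(df, COUNT_COLUMNS, f"excel counts {path}")
    return NucleationDataset(
        x_uM=df["x_uM"].to_numpy(float),
        seeds_total=df["seeds_total"].to_numpy(int),
        seeds_nucleated=df["seeds_nucleated"].to_numpy(int),
    )


def write_counts_excel(dataset: NucleationDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_uM": dataset.x_uM,
            "seeds_total": dataset.seeds_total,
            "seeds_nucleated": dataset.seeds_nucleated,
        }
    ).to_excel(path, index=False, engine="openpyxl")


def write_annotation(ann: PhaseAnnotation, path: str | Path) -> None:
    payload = {
        "vertices": ann.vertices.tolist(),
        "labels": list(ann.labels),
        "observation_time": ann.observation_time,
        "n_marks": ann.n_marks,
        "rate_ok": list(map(bool, ann.rate_ok)) if ann.rate_ok is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotation(path: str | Path) -> PhaseAnnotation:
    payload = json.loads(Path(path).read_text())
    for key in ("vertices", "labels", "observation_time"):
        if key not in payload:
            raise ValueError(f"annotation {path}: missing field {key!r}")
    return PhaseAnnotation(
        vertices=np.asarray(payload["vertices"], dtype=float),
        labels=list(payload["labels"]),
        observation_time=float(payload["observation_time"]),
        n_marks=payload.get("n_marks"),
        rate_ok=payload.get("rate_ok"),
    )


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Multi-page TIFF (one page per channel) with a JSON calibration sidecar."""
    path = Path(path)
    names = sorted(kymo.channels)
    stack = np.stack([kymo.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack)
    _write_sidecar(
        path,
        {
            "channels": names,
            "pixel_size": kymo.pixel_size,
            "frame_interval": kymo.frame_interval,
        },
    )


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = _read_sidecar(path)
    if "channels" not in meta:
        raise ValueError(f"kymograph {path}: sidecar missing 'channels'")
    if stack.ndim == 2:
        stack = stack[None]
    names = meta["channels"]
    if len(names) != stack.shape[0]:
        raise ValueError(f"kymograph {path}: {len(names)} names for {stack.shape[0]} pages")
    return Kymograph(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size=meta.get("pixel_size", 160.0),
        frame_interval=meta.get("frame_interval", 5.0),
    )


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def _write_sidecar(path: str | Path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: str | Path) -> dict:
    sp = _sidecar_path(path)
    if sp.exists():
        return json.loads(sp.read_text())
    return {}
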