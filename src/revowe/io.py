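"""Run-record persistence: HDF5 (primary) and JSON-lines (fallback).

HDF5 layout: ``/positions`` and ``/weights`` datasets (bit-exact int64 /
float64), with the config, resampling records, warp events and extras
stored as JSON attributes/datasets -- the records are small relative to
the trajectory arrays.  Files ending in ``.jsonl`` use a line-oriented
plain-text layout with the same content.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import Operation, ResamplingRecord, WarpEvent
from .driver import RunRecord

__all__ = ["save_record", "load_record"]


def _record_to_dict(rec: ResamplingRecord) -> dict:
    return {
        "cycle_index": rec.cycle_index,
        "operations": [
            {
                "kind": op.kind,
                "sources": list(op.sources),
                "targets": list(op.targets),
                "kept": op.kept,
            }
            for op in rec.operations
        ],
        "weights_before": None
        if rec.weights_before is None
        else list(map(float, rec.weights_before)),
        "weights_after": None
        if rec.weights_after is None
        else list(map(float, rec.weights_after)),
        "info": _jsonable(rec.info),
    }


def _record_from_dict(d: dict) -> ResamplingRecord:
    return ResamplingRecord(
        cycle_index=int(d["cycle_index"]),
        operations=[
            Operation(
                kind=op["kind"],
                sources=tuple(op["sources"]),
                targets=tuple(op["targets"]),
                kept=op["kept"],
            )
            for op in d["operations"]
        ],
        weights_before=None
        if d["weights_before"] is None
        else np.asarray(d["weights_before"], dtype=float),
        weights_after=None
        if d["weights_after"] is None
        else np.asarray(d["weights_after"], dtype=float),
        info=d.get("info", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_record(record: RunRecord, path) -> None:
    """Write a run record; format chosen by extension (.h5/.hdf5 or .jsonl)."""
    path = Path(path)
    if path.suffix == ".jsonl":
        _save_jsonl(record, path)
        return
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(record.config)
        f.create_dataset("positions", data=record.positions)
        f.create_dataset("weights", data=record.weights)
        f.create_dataset(
            "resampling",
            data=json.dumps([_record_to_dict(r) for r in record.resampling]),
        )
        f.create_dataset(
            "warps",
            data=json.dumps(
                [
                    {
                        "cycle_index": e.cycle_index,
                        "walker_index": e.walker_index,
                        "warped_weight": float(e.warped_weight),
                    }
                    for e in record.warps
                ]
            ),
        )
        f.create_dataset("extras", data=json.dumps(_jsonable(record.extras)))


def load_record(path) -> RunRecord:
    """Read a run record written by :func:`save_record`."""
    path = Path(path)
    if path.suffix == ".jsonl":
        return _load_jsonl(path)
    with h5py.File(path, "r") as f:
        config = json.loads(f.attrs["config"])
        positions = f["positions"][()]
        weights = f["weights"][()]
        resampling = [
            _record_from_dict(d) for d in json.loads(f["resampling"][()].decode())
        ]
        warps = [
            WarpEvent(d["cycle_index"], d["walker_index"], d["warped_weight"])
            for d in json.loads(f["warps"][()].decode())
        ]
        extras = json.loads(f["extras"][()].decode())
    return RunRecord(
        config=config,
        positions=positions,
        weights=weights,
        resampling=resampling,
        warps=warps,
        extras=extras,
    )


def _save_jsonl(record: RunRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(json.dumps({"config": record.config}) + "\n")
        fh.write(
            json.dumps(
                {
                    "positions": record.positions.tolist(),
                    "weights": record.weights.tolist(),
                }
            )
            + "\n"
        )
        fh.write(
            json.dumps({"resampling": [_record_to_dict(r) for r in record.resampling]})
            + "\n"
        )
        fh.write(
            json.dumps(
                {
                    "warps": [
                        {
                            "cycle_index": e.cycle_index,
                            "walker_index": e.walker_index,
                            "warped_weight": float(e.warped_weight),
                        }
                        for e in record.warps
                    ]
                }
            )
            + "\n"
        )
        fh.write(json.dumps({"extras": _jsonable(record.extras)}) + "\n")


def _load_jsonl(path: Path) -> RunRecord:
    with open(path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    data = {}
    for line in lines:
        data.update(line)
    return RunRecord(
        config=data["config"],
        positions=np.asarray(data["positions"], dtype=np.int64),
        weights=np.asarray(data["weights"], dtype=np.float64),
        resampling=[_record_from_dict(d) for d in data["resampling"]],
        warps=[
            WarpEvent(d["cycle_index"], d["walker_index"], d["warped_weight"])
            for d in data["warps"]
        ],
        extras=data.get("extras", {}),
    )
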