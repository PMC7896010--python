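"""File formats for stimulus events, sampled traces and measurement tables.

Event files: plain text, one event time in seconds per line (UTF-8, LF);
the file name encodes the nerve, ``events_<nerve_id>.txt``.

Trace files: either single-column text (one sample per line, millivolts,
extension ``.txt``) or little-endian 32-bit float binary (``.f32``); each
trace has a JSON sidecar ``<name>.json`` with at least ``sample_rate_hz``,
``units`` ("mV"), ``channel`` and ``t0_s``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np

from renshaw.synthetic import (
    AntidromicConfig,
    IPSPKernel,
    NonlinearityConfig,
    Recording,
    RecordingConfig,
    StimulusTrain,
    TrainConfig,
)

__all__ = [
    "write_event_file",
    "read_event_file",
    "write_trace",
    "read_trace",
    "write_recording",
    "read_recording",
    "config_to_dict",
    "recording_config_from_dict",
]


def write_event_file(path: str | Path, train: StimulusTrain) -> Path:
    path = Path(path)
    path.write_text("".join(f"{t:.9f}\n" for t in train.times), encoding="utf-8")
    return path


def read_event_file(
    path: str | Path, nerve_id: str | None = None, config: TrainConfig | None = None
) -> StimulusTrain:
    path = Path(path)
    times = np.array(
        [float(line) for line in path.read_text(encoding="utf-8").split() if line],
        dtype=float,
    )
    if nerve_id is None:
        stem = path.stem
        nerve_id = stem[len("events_"):] if stem.startswith("events_") else stem
    if config is None:
        duration = float(times[-1]) + 1e-9 if times.size else 0.0
        config = TrainConfig(duration=duration)
    return StimulusTrain(nerve_id, times, config)


def write_trace(
    path: str | Path,
    trace: np.ndarray,
    sample_rate: float,
    channel: str = "intracellular",
    t0_s: float = 0.0,
    fmt: str = "f32",
) -> Path:
    path = Path(path)
    if fmt == "f32":
        np.asarray(trace, dtype="<f4").tofile(path)
    elif fmt == "text":
        np.savetxt(path, np.asarray(trace, dtype=float), fmt="%.6f")
    else:
        raise ValueError("fmt must be 'f32' or 'text'")
    sidecar = {
        "sample_rate_hz": sample_rate,
        "units": "mV",
        "channel": channel,
        "t0_s": t0_s,
        "n_samples": int(len(trace)),
        "format": fmt,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8"
    )
    return path


def read_trace(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text("utf-8"))
    if sidecar.get("format", "f32") == "f32":
        trace = np.fromfile(path, dtype="<f4").astype(float)
    else:
        trace = np.loadtxt(path, dtype=float)
    return trace, sidecar


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_to_dict(config: Any) -> dict:
    """Ground-truth serialization of any configuration dataclass."""
    return _as_jsonable(config)


def recording_config_from_dict(d: dict) -> RecordingConfig:
    d = dict(d)
    kernels = {k: IPSPKernel(**v) for k, v in d.pop("kernels", {}).items()}
    nl = d.pop("nonlinearity", None)
    anti = d.pop("antidromic", None)
    return RecordingConfig(
        kernels=kernels,
        nonlinearity=NonlinearityConfig(**nl) if nl else NonlinearityConfig(),
        antidromic=AntidromicConfig(**anti) if anti else None,
        **d,
    )


def write_recording(out_dir: str | Path, recording: Recording, fmt: str = "f32") -> Path:
    """Write trains, both traces, sidecars and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tr in recording.trains:
        write_event_file(out / f"events_{tr.nerve_id}.txt", tr)
    ext = "f32" if fmt == "f32" else "txt"
    for channel in ("intracellular", "extracellular"):
        write_trace(
            out / f"{channel}.{ext}",
            getattr(recording, channel),
            recording.sample_rate,
            channel=channel,
            fmt=fmt,
        )
    truth = {
        "config": config_to_dict(recording.truth),
        "meta": _as_jsonable(recording.meta),
        "train_configs": {
            tr.nerve_id: config_to_dict(tr.config) for tr in recording.trains
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1), "utf-8")
    return out


def read_recording(in_dir: str | Path) -> Recording:
    """Read a recording directory written by :func:`write_recording`."""
    d = Path(in_dir)
    truth = json.loads((d / "ground_truth.json").read_text("utf-8"))
    config = recording_config_from_dict(truth["config"])
    trains = []
    for ev in sorted(d.glob("events_*.txt")):
        nerve = ev.stem[len("events_"):]
        tc = truth["train_configs"].get(nerve)
        trains.append(
            read_event_file(ev, nerve, TrainConfig(**tc) if tc else None)
        )
    intra = extra = None
    for ext in ("f32", "txt"):
        if (d / f"intracellular.{ext}").exists():
            intra, _ = read_trace(d / f"intracellular.{ext}")
            extra, _ = read_trace(d / f"extracellular.{ext}")
            break
    if intra is None:
        raise FileNotFoundError(f"no trace files in {d}")
    return Recording(
        intracellular=intra,
        extracellular=extra,
        sample_rate=config.sample_rate,
        trains=tuple(trains),
        truth=config,
        meta=truth.get("meta", {}),
    )
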