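"""CSV/JSON readers and writers for recordings, annotations and results.

Dialect is pinned: UTF-8, header row, ``.`` decimal, time in seconds
from recording start, half-open intervals ``[start, end)``. A recording
directory contains::

    channels.csv     time_s, flow_lps, spo2_pct, etco2_mmhg, n2_marker
    beats.csv        beat_time_s, ectopic_flag
    annotations.csv  start_s, end_s
    meta.json        sample_rate, subject, visit
    truth.json       (optional) generator ground truth

Floats are written with ``repr`` (shortest round-trip) precision, so a
write -> read cycle reproduces values exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .recording import SignalRecording
from .synth import GroundTruth

def _fmt_float(value) -> str:
    """Shortest round-trip decimal representation."""
    return repr(float(value))


__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "write_result_json",
]


def write_recording(
    recording: SignalRecording, out_dir: str | Path, truth: Optional[GroundTruth] = None
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channels = pd.DataFrame(
        {
            "time_s": recording.time,
            "flow_lps": recording.flow,
            "spo2_pct": recording.spo2,
        }
    )
    if recording.etco2 is not None:
        channels["etco2_mmhg"] = recording.etco2
    if recording.marker is not None:
        channels["n2_marker"] = recording.marker
    channels.to_csv(out / "channels.csv", index=False, float_format=_fmt_float)
    flags = (
        recording.beat_ectopic_flags
        if recording.beat_ectopic_flags is not None
        else np.zeros(len(recording.beat_times), dtype=bool)
    )
    pd.DataFrame(
        {"beat_time_s": recording.beat_times, "ectopic_flag": flags.astype(int)}
    ).to_csv(out / "beats.csv", index=False, float_format=_fmt_float)
    if recording.n2_intervals is not None:
        pd.DataFrame(
            recording.n2_intervals, columns=["start_s", "end_s"]
        ).to_csv(out / "annotations.csv", index=False, float_format=_fmt_float)
    meta = {
        "sample_rate": recording.sample_rate,
        "subject": recording.subject_id,
        "visit": recording.visit,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
    if truth is not None:
        write_ground_truth(truth, out / "truth.json")
    return out


def read_recording(in_dir: str | Path) -> SignalRecording:
    src = Path(in_dir)
    if not (src / "channels.csv").exists():
        raise ValidationError(f"no channels.csv in {src}")
    channels = pd.read_csv(src / "channels.csv", float_precision="round_trip")
    meta = json.loads((src / "meta.json").read_text(encoding="utf-8"))
    beats = pd.read_csv(src / "beats.csv", float_precision="round_trip")
    n2 = None
    if (src / "annotations.csv").exists():
        ann = pd.read_csv(src / "annotations.csv", float_precision="round_trip")
        n2 = ann[["start_s", "end_s"]].to_numpy()
    return SignalRecording(
        sample_rate=float(meta["sample_rate"]),
        flow=channels["flow_lps"].to_numpy(),
        spo2=channels["spo2_pct"].to_numpy(),
        etco2=(
            channels["etco2_mmhg"].to_numpy() if "etco2_mmhg" in channels else None
        ),
        marker=(
            channels["n2_marker"].to_numpy() if "n2_marker" in channels else None
        ),
        beat_times=beats["beat_time_s"].to_numpy(),
        beat_ectopic_flags=beats["ectopic_flag"].to_numpy().astype(bool),
        n2_intervals=n2,
        subject_id=str(meta.get("subject", "")),
        visit=str(meta.get("visit", "")),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict()), encoding="utf-8")


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result_json(result, path: str | Path) -> None:
    """Serialize a result object (dataclass/dict/DataFrame mix) to JSON."""
    Path(path).write_text(
        json.dumps(_jsonable(result), indent=1, sort_keys=True), encoding="utf-8"
    )
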