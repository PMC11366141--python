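"""Delimited-text readers and writers for recordings, logs and tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AccelRecording, ExclusionEpisode

RECORDING_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g"]
EXCLUSION_COLUMNS = ["start_s", "end_s", "reason"]


def write_recording(rec: AccelRecording, path) -> None:
    df = pd.DataFrame(
        {
            "t_s": rec.t,
            "ax_g": rec.xyz[:, 0],
            "ay_g": rec.xyz[:, 1],
            "az_g": rec.xyz[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(path, leg_id: str = "", patient_id: str = "") -> AccelRecording:
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recording file {path} lacks columns {missing}")
    t = df["t_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"recording file {path} has fewer than two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    if not leg_id:
        leg_id = Path(path).stem
    return AccelRecording(
        t=t,
        xyz=df[["ax_g", "ay_g", "az_g"]].to_numpy(float),
        sample_rate_hz=rate,
        leg_id=leg_id,
        patient_id=patient_id,
    )


def write_exclusions(episodes: list[ExclusionEpisode], path) -> None:
    pd.DataFrame(
        [{"start_s": e.start_s, "end_s": e.end_s, "reason": e.reason} for e in episodes],
        columns=EXCLUSION_COLUMNS,
    ).to_csv(path, index=False)


def read_exclusions(path) -> list[ExclusionEpisode]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    return [
        ExclusionEpisode(float(r.start_s), float(r.end_s), str(r.reason))
        for r in df.itertuples()
    ]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
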