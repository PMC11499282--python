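"""File-boundary I/O: accelerometry CSV, truth sidecars, config YAML.

Accelerometry CSV dialect: columns ``timestamp`` (ISO-8601, millisecond
precision), ``x``, ``y``, ``z`` in g. Truth sidecars are JSON with
intervals in seconds from recording start (half-open).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import AccelRecording, FreeLivingTruth


def write_accel_csv(recording: AccelRecording, path) -> None:
    ts = recording.start_time + pd.to_timedelta(recording.times_s, unit="s")
    df = pd.DataFrame(
        {
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3],
            "x": recording.data[:, 0],
            "y": recording.data[:, 1],
            "z": recording.data[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_accel_csv(path, site: str = "lumbar", subject_id: str = "") -> AccelRecording:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    t = (df["timestamp"] - df["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    if len(t) < 2:
        raise ValueError("need at least two samples")
    # span-based rate estimate: robust to per-sample timestamp truncation
    fs = (len(t) - 1) / (t[-1] - t[0])
    data = df[["x", "y", "z"]].to_numpy(dtype=float)
    return AccelRecording(
        data=data, fs_hz=float(round(fs, 3)), start_time=df["timestamp"].iloc[0],
        site=site, subject_id=subject_id,
    )


def write_truth_json(truth: FreeLivingTruth, path) -> None:
    payload = {
        "bout_intervals": [list(iv) for iv in truth.bout_intervals],
        "nonwear_intervals": [list(iv) for iv in truth.nonwear_intervals],
        "epoch_len_s": truth.epoch_len_s,
        "intensity_labels": {
            str(float(k)): v for k, v in truth.intensity_labels.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> FreeLivingTruth:
    payload = json.loads(Path(path).read_text())
    labels = pd.Series(
        list(payload["intensity_labels"].values()),
        index=[float(k) for k in payload["intensity_labels"]],
    )
    return FreeLivingTruth(
        bout_intervals=[tuple(iv) for iv in payload["bout_intervals"]],
        nonwear_intervals=[tuple(iv) for iv in payload["nonwear_intervals"]],
        intensity_labels=labels,
        epoch_len_s=payload["epoch_len_s"],
    )


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config_yaml(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
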