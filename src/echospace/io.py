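"""Reading and writing the pipeline's columnar text formats.

All session inputs and outputs are plain CSV/JSON: motion-capture marker
frames, scene objects, vocalization times, spike event times, LFP sample
streams, echo tables, and the ground-truth sidecar of synthetic sessions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .echo_model import SceneObject
from .lfp import LFPChannel

MARKER_COLUMNS = ["t", "Px", "Py", "Pz", "Qx", "Qy", "Qz", "Rx", "Ry", "Rz"]


def read_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing marker columns {missing}")
    return df[MARKER_COLUMNS]


def write_markers(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_scene(path) -> List[SceneObject]:
    """Scene objects from JSON: list of {id, center, shape, radius, length, axis}."""
    data = json.loads(Path(path).read_text())
    objs = []
    for d in data:
        objs.append(SceneObject(
            id=str(d["id"]), center=np.asarray(d["center"], float),
            shape=d.get("shape", "point"), radius=float(d.get("radius", 0.0)),
            length=float(d.get("length", 0.0)),
            axis=np.asarray(d["axis"], float) if d.get("axis") else None))
    return objs


def write_scene(scene: List[SceneObject], path) -> None:
    data = []
    for o in scene:
        d = dict(id=o.id, center=o.center.tolist(), shape=o.shape)
        if o.shape == "cylinder":
            d.update(radius=o.radius, length=o.length, axis=o.axis.tolist())
        data.append(d)
    Path(path).write_text(json.dumps(data, indent=1))


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "t_emit" not in df.columns:
        raise ValueError(f"{path}: calls CSV needs a t_emit column")
    return df


def read_spikes(path) -> Dict[str, np.ndarray]:
    """Spike CSV with columns unit_id[, channel], t -> {unit: sorted times}."""
    df = pd.read_csv(path)
    return {uid: np.sort(g["t"].to_numpy(float))
            for uid, g in df.groupby("unit_id")}


def write_spikes(spikes: Dict[str, np.ndarray], path) -> None:
    rows = [pd.DataFrame(dict(unit_id=uid, t=t)) for uid, t in spikes.items()]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_lfp(path) -> LFPChannel:
    """LFP CSV with header columns channel_id, fs, t0 and a 'sample' column."""
    df = pd.read_csv(path)
    return LFPChannel(channel_id=str(df["channel_id"].iloc[0]),
                      fs=float(df["fs"].iloc[0]),
                      t0=float(df.get("t0", pd.Series([0.0])).iloc[0]),
                      samples=df["sample"].to_numpy(float))


def write_lfp(ch: LFPChannel, path) -> None:
    pd.DataFrame(dict(channel_id=ch.channel_id, fs=ch.fs, t0=ch.t0,
                      sample=ch.samples)).to_csv(path, index=False)


def write_session(session, outdir) -> None:
    """Write a synthetic session's inputs + ground truth to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_markers(session.markers, out / "markers.csv")
    session.poses.to_csv(out / "poses.csv", index=False)
    write_scene(session.scene, out / "scene.json")
    session.calls.to_csv(out / "calls.csv", index=False)
    session.echoes.to_csv(out / "echoes.csv", index=False)
    write_spikes(session.spikes, out / "spikes.csv")
    for uid, ch in session.lfp.items():
        write_lfp(ch, out / f"lfp_{uid}.csv")
    session.truth.to_json(out / "ground_truth.json")
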