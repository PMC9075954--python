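"""Plain-text serialization for trial tables, time series and results.

Everything round-trips through CSV / whitespace matrices / JSON sidecars
so that artifacts remain diffable and platform-neutral.  All indices in
files are 0-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from wmdecode.simulate import ROITimeSeries

__all__ = [
    "save_trial_table",
    "load_trial_table",
    "save_timeseries",
    "load_timeseries",
    "dataframe_hash",
]


def save_trial_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def load_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_timeseries(ts: ROITimeSeries, directory, stem: str, seed=None) -> Path:
    """Write one matrix file per run plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    runs = []
    for code in ts.run_codes():
        sl = ts.run_slice(code)
        fname = f"{stem}_run{int(code):03d}.txt"
        np.savetxt(directory / fname, ts.data[:, sl], fmt="%.6e")
        sess, run = ts.run_keys.get(code, (None, None))
        runs.append({"code": int(code), "file": fname, "session": sess, "run": run})
    sidecar = {
        "tr_s": ts.tr_s,
        "state": ts.state,
        "seed": seed,
        "runs": runs,
        "ground_truth_hash": _gt_hash(ts.ground_truth),
    }
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return directory / f"{stem}.json"


def load_timeseries(sidecar_path) -> ROITimeSeries:
    sidecar_path = Path(sidecar_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    blocks, ids, keys = [], [], {}
    for entry in meta["runs"]:
        block = np.loadtxt(sidecar_path.parent / entry["file"], ndmin=2)
        blocks.append(block)
        ids.append(np.full(block.shape[1], entry["code"]))
        keys[entry["code"]] = (entry["session"], entry["run"])
    return ROITimeSeries(
        data=np.concatenate(blocks, axis=1),
        tr_s=meta["tr_s"],
        run_ids=np.concatenate(ids),
        state=meta["state"],
        run_keys=keys,
    )


def _gt_hash(gt) -> str | None:
    if gt is None:
        return None
    h = hashlib.sha256()
    for arr in (gt.preferred_angle_deg, gt.kappa, gt.action_weight):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(repr(sorted(gt.spatial_gain.items())).encode())
    return h.hexdigest()[:16]


def dataframe_hash(df: pd.DataFrame) -> str:
    """Stable content hash of a DataFrame (used for determinism checks)."""
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]
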