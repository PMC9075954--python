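"""Run-wise normalization, temporal filtering, epoching and trial patterns.

The chain mirrors a standard event-related fMRI preparation: per-run
high-pass filtering (discrete-cosine drift basis, 1/40 Hz cutoff), per-run
voxelwise z-scoring, epoching on TR-rounded trial onsets, averaging a
task-specific delay-period window, and mean-centering each trial's pattern
across voxels so that multivariate decoders cannot exploit global
activation differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from wmdecode.simulate import ROITimeSeries

__all__ = [
    "TrialPattern",
    "WINDOWS_TR",
    "zscore_runs",
    "highpass_filter",
    "epoch_trials",
    "average_window",
    "mean_center_trials",
]

#: Inclusive TR windows averaged to one pattern per trial, per task.
#: Main task: TRs 10-16 (8-12.8 s, mid/late delay); mapping: TRs 6-12
#: (4.8-9.6 s); localizers: TRs 4-7 (3.2-5.6 s, stimulus-evoked peak).
WINDOWS_TR = {
    "main": (10, 16),
    "mapping": (6, 12),
    "spatial_localizer": (4, 7),
    "button_localizer": (4, 7),
}


@dataclass
class TrialPattern:
    """Trial x voxel activation matrix with aligned per-trial labels."""

    data: np.ndarray  # (n_trials, n_voxels)
    labels: pd.DataFrame  # one row per trial
    centered: bool = False
    timepoint_tr: int | None = None
    window_tr: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must align 1:1 with pattern rows")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "TrialPattern":
        mask = np.asarray(mask)
        return dc_replace(
            self, data=self.data[mask], labels=self.labels.iloc[mask].reset_index(drop=True)
        )


def zscore_runs(ts: ROITimeSeries) -> ROITimeSeries:
    """Z-score each voxel's signal within each run (sample sd, ddof=1).

    Raises on any zero-variance voxel/run pair rather than emitting NaNs.
    """
    if ts.state not in ("raw", "filtered"):
        raise ValueError(f"expected raw or filtered input, got state={ts.state!r}")
    out = np.empty_like(ts.data)
    for code in ts.run_codes():
        sl = ts.run_slice(code)
        block = ts.data[:, sl]
        sd = block.std(axis=1, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"zero-variance voxel(s) {dead.tolist()} in run {ts.run_keys.get(code, code)}"
            )
        out[:, sl] = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
    return ROITimeSeries(
        data=out,
        tr_s=ts.tr_s,
        run_ids=ts.run_ids.copy(),
        state="zscored",
        run_keys=dict(ts.run_keys),
        ground_truth=ts.ground_truth,
    )


def _dct_drift_basis(n: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """DCT-II columns with frequency below ``cutoff_hz`` (excluding DC)."""
    t = np.arange(n)
    ks = []
    k = 1
    while k / (2.0 * n * tr_s) < cutoff_hz:
        ks.append(k)
        k += 1
    cols = [np.cos(np.pi * kk * (2 * t + 1) / (2.0 * n)) for kk in ks]
    if not cols:
        return np.empty((n, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def highpass_filter(ts: ROITimeSeries, cutoff_hz: float = 1.0 / 40.0) -> ROITimeSeries:
    """Remove slow drifts by projecting out a per-run low-frequency DCT basis.

    All cosine components with frequency below ``cutoff_hz`` (plus the
    per-run mean) are regressed out of each voxel's run time course.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    if ts.state != "raw":
        raise ValueError(f"expected raw input, got state={ts.state!r}")
    out = np.empty_like(ts.data)
    for code in ts.run_codes():
        sl = ts.run_slice(code)
        block = ts.data[:, sl]
        n = block.shape[1]
        basis = _dct_drift_basis(n, ts.tr_s, cutoff_hz)
        demeaned = block - block.mean(axis=1, keepdims=True)
        if basis.shape[1]:
            coefs = demeaned @ basis  # orthonormal basis: projection
            demeaned = demeaned - coefs @ basis.T
        out[:, sl] = demeaned + block.mean(axis=1, keepdims=True)
    return ROITimeSeries(
        data=out,
        tr_s=ts.tr_s,
        run_ids=ts.run_ids.copy(),
        state="filtered",
        run_keys=dict(ts.run_keys),
        ground_truth=ts.ground_truth,
    )


def _onset_tr(onset_s: float, tr_s: float) -> int:
    # round-half-away-from-zero; onsets are non-negative
    return int(np.floor(onset_s / tr_s + 0.5))


def epoch_trials(
    ts: ROITimeSeries,
    trial_table: pd.DataFrame,
    n_trs: int,
    pad: bool = False,
) -> np.ndarray:
    """Epoch a z-scored time series into a (trial, TR, voxel) tensor.

    Trial ``t`` starts at TR ``round(onset_s / tr_s)`` within its own run
    (pure indexing, no interpolation).  Trials whose window extends past
    the end of their run raise an error unless ``pad=True``, in which case
    they are zero-padded and a warning is issued.
    """
    if ts.state != "zscored":
        raise ValueError(f"expected z-scored input, got state={ts.state!r}")
    if n_trs <= 0:
        raise ValueError("n_trs must be positive")
    key_to_code = {key: code for code, key in ts.run_keys.items()}
    tensor = np.zeros((len(trial_table), n_trs, ts.n_voxels))
    n_truncated = 0
    for i, (_, row) in enumerate(trial_table.iterrows()):
        key = (int(row["session"]), int(row["run"]))
        if key not in key_to_code:
            raise KeyError(f"run {key} not present in the time series")
        sl = ts.run_slice(key_to_code[key])
        run_len = sl.stop - sl.start
        start = _onset_tr(float(row["onset_s"]), ts.tr_s)
        if start >= run_len:
            raise ValueError(f"trial onset {row['onset_s']} s lies beyond the end of run {key}")
        stop = start + n_trs
        if stop > run_len:
            if not pad:
                raise ValueError(
                    f"trial window [{start}, {stop}) TRs exceeds run {key} length {run_len}; "
                    "pass pad=True to zero-pad"
                )
            n_truncated += 1
            avail = run_len - start
            tensor[i, :avail, :] = ts.data[:, sl][:, start:run_len].T
        else:
            tensor[i] = ts.data[:, sl][:, start:stop].T
    if n_truncated:
        warnings.warn(f"{n_truncated} trial(s) zero-padded past run end", stacklevel=2)
    return tensor


def average_window(
    tensor: np.ndarray,
    task: str | tuple,
    trial_table: pd.DataFrame | None = None,
) -> TrialPattern:
    """Average an inclusive TR window of an epoch tensor into trial patterns.

    ``task`` is either a task name keyed in :data:`WINDOWS_TR` or an
    explicit inclusive ``(first_tr, last_tr)`` tuple.
    """
    window = WINDOWS_TR[task] if isinstance(task, str) else tuple(task)
    lo, hi = window
    if not 0 <= lo <= hi < tensor.shape[1]:
        raise ValueError(f"window {window} outside epoch of {tensor.shape[1]} TRs")
    data = tensor[:, lo : hi + 1, :].mean(axis=1)
    labels = (
        trial_table.reset_index(drop=True)
        if trial_table is not None
        else pd.DataFrame(index=range(data.shape[0]))
    )
    return TrialPattern(data=data, labels=labels, centered=False, window_tr=window)


def mean_center_trials(pattern: TrialPattern) -> TrialPattern:
    """Subtract each trial's mean across voxels (idempotent)."""
    if pattern.data.shape[1] == 1:
        warnings.warn("single-voxel pattern: centering zeroes it and decoding is degenerate")
    data = pattern.data - pattern.data.mean(axis=1, keepdims=True)
    return dc_replace(pattern, data=data, centered=True)
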