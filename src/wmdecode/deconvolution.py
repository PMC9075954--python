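"""FIR (finite-impulse-response) deconvolution of condition-wise HRFs.

A GLM with one 0/1 onset regressor per condition plus temporally shifted
copies (one per post-onset lag) and a constant per run estimates an
unconstrained HRF for every voxel and condition from the continuous
z-scored time series.  ROI-mean time courses summarize the voxelwise
estimates; group curves aggregate them across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wmdecode.simulate import ROITimeSeries

__all__ = [
    "FIRDesign",
    "HRFEstimate",
    "DEFAULT_N_LAGS",
    "build_fir_design",
    "fit_fir",
    "split_contra_ipsi",
    "group_hrf_summary",
]

#: Default FIR window: 35 lags of 0.8 s = 0-27.2 s, spanning the 18.5 s
#: trial plus the hemodynamic tail.
DEFAULT_N_LAGS = 35


@dataclass
class FIRDesign:
    """TR x regressor FIR design matrix with per-column metadata."""

    matrix: np.ndarray  # (T, n_conditions * n_lags + n_runs)
    regressor_meta: list  # ("fir", condition, lag) or ("constant", run_key)
    n_lags: int
    conditions: list

    def fir_column(self, condition: str, lag: int) -> int:
        return self.regressor_meta.index(("fir", condition, lag))


@dataclass
class HRFEstimate:
    """Estimated FIR betas: condition x lag x voxel, with ROI means."""

    betas: np.ndarray  # (n_conditions, n_lags, n_voxels)
    roi_mean: np.ndarray  # (n_conditions, n_lags)
    conditions: list
    tr_s: float

    def tidy(self, participant=None, roi=None) -> pd.DataFrame:
        rows = []
        for ci, cond in enumerate(self.conditions):
            for lag in range(self.betas.shape[1]):
                rows.append(
                    {
                        "participant": participant,
                        "roi": roi,
                        "condition": cond,
                        "lag_s": lag * self.tr_s,
                        "beta": self.roi_mean[ci, lag],
                    }
                )
        return pd.DataFrame(rows)


def build_fir_design(
    trial_table: pd.DataFrame,
    ts: ROITimeSeries,
    n_lags: int = DEFAULT_N_LAGS,
    conditions: list | None = None,
    condition_col: str = "condition",
) -> FIRDesign:
    """Build the 0/1 FIR design for a trial table on a time-series grid.

    For each condition, column ``lag`` carries a 1 at TR ``onset_tr + lag``
    for every trial of that condition (an indicator, not a count); events
    shifted past the end of their run are truncated.  One constant
    indicator column is appended per run.
    """
    if n_lags <= 0:
        raise ValueError("n_lags must be positive")
    if conditions is None:
        conditions = list(dict.fromkeys(trial_table[condition_col]))
    T = ts.data.shape[1]
    key_to_code = {key: code for code, key in ts.run_keys.items()}

    n_fir = len(conditions) * n_lags
    X = np.zeros((T, n_fir + len(ts.run_keys)))
    meta = [("fir", c, lag) for c in conditions for lag in range(n_lags)]

    for _, row in trial_table.iterrows():
        cond = row[condition_col]
        if cond not in conditions:
            continue
        ci = conditions.index(cond)
        key = (int(row["session"]), int(row["run"]))
        sl = ts.run_slice(key_to_code[key])
        onset_tr = int(np.floor(float(row["onset_s"]) / ts.tr_s + 0.5))
        for lag in range(n_lags):
            t = sl.start + onset_tr + lag
            if t < sl.stop:
                X[t, ci * n_lags + lag] = 1.0

    for j, code in enumerate(ts.run_codes()):
        sl = ts.run_slice(code)
        X[sl, n_fir + j] = 1.0
        meta.append(("constant", ts.run_keys.get(code, code)))
    return FIRDesign(matrix=X, regressor_meta=meta, n_lags=n_lags, conditions=list(conditions))


def fit_fir(ts: ROITimeSeries, design: FIRDesign) -> HRFEstimate:
    """Ordinary least squares fit of the FIR design, voxel by voxel.

    Requires z-scored input and a full-rank design; betas are reshaped to
    condition x lag x voxel and averaged over voxels into ``roi_mean``.
    """
    if ts.state != "zscored":
        raise ValueError(f"expected z-scored input, got state={ts.state!r}")
    X = design.matrix
    if X.shape[0] != ts.data.shape[1]:
        raise ValueError("design rows must equal the number of TRs")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [design.regressor_meta[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise np.linalg.LinAlgError(
            f"rank-deficient FIR design (rank {rank} < {X.shape[1]}); suspect columns: {bad}"
        )
    betas, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    n_cond, n_lags = len(design.conditions), design.n_lags
    fir = betas[: n_cond * n_lags].reshape(n_cond, n_lags, -1)
    return HRFEstimate(
        betas=fir, roi_mean=fir.mean(axis=2), conditions=design.conditions, tr_s=ts.tr_s
    )


def split_contra_ipsi(trial_table: pd.DataFrame, hemisphere_per_voxel) -> dict:
    """Relabel trials by laterality of the correct press, per hemisphere.

    For each hemisphere present among the voxels, returns a copy of the
    trial table whose ``condition`` column is replaced by
    ``"<condition>_contra"`` / ``"<condition>_ipsi>"`` according to whether
    the correct finger is contralateral to that hemisphere (left hemisphere
    <-> right finger).  Fitting a 4-condition FIR per hemisphere group and
    averaging the relabeled estimates over all voxels yields
    contralateral/ipsilateral HRFs.
    """
    hemis = np.unique(np.asarray(hemisphere_per_voxel))
    out = {}
    for hemi in hemis:
        contra_finger = "right" if hemi == "left" else "left"
        table = trial_table.copy()
        lat = np.where(table["correct_finger"] == contra_finger, "contra", "ipsi")
        table["condition"] = table["condition"].astype(str) + "_" + lat
        out[str(hemi)] = table
    return out


def group_hrf_summary(estimates: list[HRFEstimate]) -> pd.DataFrame:
    """Across-participant mean and SEM (sd/sqrt(N)) of ROI-mean HRFs."""
    if not estimates:
        raise ValueError("no estimates supplied")
    conds = estimates[0].conditions
    stack = np.stack([e.roi_mean for e in estimates])  # (N, cond, lag)
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0]) if stack.shape[0] > 1 else np.full(mean.shape, np.nan)
    rows = []
    for ci, cond in enumerate(conds):
        for lag in range(mean.shape[1]):
            rows.append(
                {
                    "condition": cond,
                    "lag_s": lag * estimates[0].tr_s,
                    "beta_mean": mean[ci, lag],
                    "beta_sem": sem[ci, lag],
                    "n": stack.shape[0],
                }
            )
    return pd.DataFrame(rows)
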