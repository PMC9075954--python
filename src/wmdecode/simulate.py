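"""Synthetic BOLD simulation with a parameterized voxel-level ground truth.

Each simulated voxel carries a von Mises spatial tuning curve (preferred
angle and concentration ``kappa``), condition-dependent multiplicative
gains on that tuning, and a signed *action weight* expressing a preference
for button presses made with the finger contralateral to the voxel's
hemisphere.  Trial tables from :mod:`wmdecode.design` are turned into
neural boxcar time courses, convolved with a double-gamma hemodynamic
response, and corrupted with voxelwise AR(1) Gaussian noise.

The built-in profiles emulate the qualitative information content of
cortical regions in a delayed spatial working-memory experiment:

``visual_like``
    Angular tuning with a larger gain when no response can be pre-planned
    (uninformative condition) than when it can (informative); no action
    signal.  Emulates retinotopic visual cortex.
``parietal_like``
    Same structure with weaker gains; emulates intraparietal regions.
``sensorimotor_like``
    No spatial tuning; a lateralized action signal carried by a fraction
    of voxels, active during the delay only when the upcoming press is
    known (informative condition), and during the actual response window
    in both conditions.  Emulates S1/M1/premotor cortex.
``null``
    No information-bearing parameters at all; used for chance calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from wmdecode.design import MAIN_EVENTS_S, RUN_DURATION_S

__all__ = [
    "HRFParams",
    "GroundTruth",
    "ROITimeSeries",
    "SimSpec",
    "PROFILES",
    "make_ground_truth",
    "double_gamma_hrf",
    "event_amplitudes",
    "simulate_session",
    "concat_sessions",
]

TR_S = 0.8


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (seconds), SPM-like defaults."""

    peak_delay: float = 6.0
    peak_disp: float = 1.0
    undershoot_delay: float = 16.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0  # peak-to-undershoot amplitude ratio


@dataclass
class GroundTruth:
    """Per-voxel generative parameters for one simulated ROI."""

    n_voxels: int
    preferred_angle_deg: np.ndarray  # (V,), degrees in [0, 360)
    kappa: np.ndarray  # (V,), von Mises concentration >= 0
    spatial_gain: dict  # {"informative": g_i, "uninformative": g_u}
    encoding_gain: float  # shared gain before the preview disk
    action_weight: np.ndarray  # (V,), signed; + prefers contralateral press
    hemisphere: np.ndarray  # (V,) of {"left", "right"}
    orientation_gain: float = 0.0  # response to the preview-disk boundary
    baseline_amp: float = 1.0
    noise_sd: float = 1.0
    ar1_phi: float = 0.3
    hrf_params: HRFParams = field(default_factory=HRFParams)
    info_onset_s: float = MAIN_EVENTS_S["preview"][0]  # 3.5
    info_offset_s: float = MAIN_EVENTS_S["response"][0]  # 16.5
    profile: str = "custom"

    def __post_init__(self):
        self.preferred_angle_deg = np.asarray(self.preferred_angle_deg, float)
        self.kappa = np.asarray(self.kappa, float)
        self.action_weight = np.asarray(self.action_weight, float)
        self.hemisphere = np.asarray(self.hemisphere)
        for arr in (self.preferred_angle_deg, self.kappa, self.action_weight, self.hemisphere):
            if arr.shape != (self.n_voxels,):
                raise ValueError("per-voxel arrays must have length n_voxels")
        if not np.all(np.isfinite(self.kappa)) or np.any(self.kappa < 0):
            raise ValueError("kappa must be finite and non-negative")
        if any(g < 0 for g in self.spatial_gain.values()):
            raise ValueError("spatial gains must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if not 0 <= self.info_onset_s < self.info_offset_s <= 18.5:
            raise ValueError("information window must lie within the 18.5 s trial")


@dataclass
class ROITimeSeries:
    """Voxel x TR matrix spanning one or more runs.

    ``data`` concatenates runs along the time axis; ``run_ids`` labels every
    column with an integer run code (``run_keys`` maps codes back to
    ``(session, run)`` pairs).  ``state`` tracks provenance through the
    preprocessing chain: ``raw`` -> ``filtered`` -> ``zscored``.
    """

    data: np.ndarray  # (V, T)
    tr_s: float
    run_ids: np.ndarray  # (T,)
    state: str = "raw"
    run_keys: dict = field(default_factory=dict)  # run code -> (session, run)
    ground_truth: GroundTruth | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.run_ids = np.asarray(self.run_ids)
        if self.data.ndim != 2 or self.run_ids.shape != (self.data.shape[1],):
            raise ValueError("data must be (voxels, TRs) with one run id per TR")
        if np.isnan(self.data).any():
            raise ValueError("time series contains NaNs")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    def run_codes(self) -> np.ndarray:
        codes, idx = np.unique(self.run_ids, return_index=True)
        return codes[np.argsort(idx)]  # preserve temporal order

    def run_slice(self, code) -> slice:
        where = np.flatnonzero(self.run_ids == code)
        return slice(where[0], where[-1] + 1)


@dataclass(frozen=True)
class SimSpec:
    """Simulation noise/sampling parameters; ``None`` defers to ground truth."""

    noise_sd: float | None = None
    ar1_phi: float | None = None
    tr_s: float = TR_S
    hrf_duration_s: float = 32.0


# Default generative parameters per ROI profile.  Gains were chosen once so
# that the downstream decoders land in the qualitative accuracy regime the
# profiles are meant to emulate (strong but imperfect spatial decoding in
# visual-like voxels, chance elsewhere) at the default noise level.
PROFILES = {
    "visual_like": dict(kappa=4.0, g_uninf=0.07, g_inf=0.03, action=0.0, orient=0.25),
    "parietal_like": dict(kappa=4.0, g_uninf=0.03, g_inf=0.012, action=0.0, orient=0.1),
    "sensorimotor_like": dict(kappa=0.0, g_uninf=0.0, g_inf=0.0, action=0.04, orient=0.0),
    "null": dict(kappa=0.0, g_uninf=0.0, g_inf=0.0, action=0.0, orient=0.0),
}

_ACTION_FRACTION = 0.6  # fraction of sensorimotor voxels carrying the signal


def make_ground_truth(profile: str, n_voxels: int, seed: int, **overrides) -> GroundTruth:
    """Draw a :class:`GroundTruth` for one ROI.

    Parameters
    ----------
    profile : {"visual_like", "parietal_like", "sensorimotor_like", "null"}
        Which qualitative information profile to emulate.
    n_voxels : int
        Number of simulated voxels; hemispheres are split half/half.
    seed : int
        Seed for preferred angles, action-weight draws and hemisphere
        assignment.
    **overrides
        Any :class:`GroundTruth` field (e.g. ``noise_sd``, ``spatial_gain``)
        to override the profile default.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    if seed is None:
        raise ValueError("a seed is required")
    params = PROFILES[profile]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    preferred = rng.uniform(0.0, 360.0, n_voxels)
    kappa = np.full(n_voxels, params["kappa"])
    hemisphere = np.where(np.arange(n_voxels) % 2 == 0, "left", "right")

    action = np.zeros(n_voxels)
    if params["action"] != 0.0:
        active = rng.random(n_voxels) < _ACTION_FRACTION
        draws = rng.normal(params["action"], 0.25 * params["action"], n_voxels)
        draws[draws == 0] = params["action"]
        signs = rng.choice([-1.0, 1.0], n_voxels)
        action = np.where(active, signs * np.abs(draws), 0.0)

    fields = dict(
        n_voxels=n_voxels,
        preferred_angle_deg=preferred,
        kappa=kappa,
        spatial_gain={"uninformative": params["g_uninf"], "informative": params["g_inf"]},
        encoding_gain=params["g_uninf"],
        action_weight=action,
        hemisphere=hemisphere,
        orientation_gain=params["orient"],
        profile=profile,
    )
    fields.update(overrides)
    return GroundTruth(**fields)


def double_gamma_hrf(
    hrf_params: HRFParams | None = None,
    tr_s: float = TR_S,
    duration_s: float = 32.0,
) -> np.ndarray:
    """Sample a peak-normalized double-gamma HRF kernel at ``tr_s``.

    The kernel is the difference of two gamma densities (response peak
    minus a delayed undershoot scaled by ``1/ratio``), normalized so its
    maximum is 1.  Default parameters peak near 5 s.
    """
    p = hrf_params or HRFParams()
    if min(p.peak_delay, p.peak_disp, p.undershoot_delay, p.undershoot_disp, p.ratio) <= 0:
        raise ValueError("HRF parameters must all be positive")
    t = np.arange(0.0, duration_s, tr_s)
    peak = sp_stats.gamma.pdf(t, a=p.peak_delay / p.peak_disp, scale=p.peak_disp)
    under = sp_stats.gamma.pdf(t, a=p.undershoot_delay / p.undershoot_disp, scale=p.undershoot_disp)
    kernel = peak - under / p.ratio
    m = kernel.max()
    if m <= 0:
        raise ValueError("degenerate HRF parameters: kernel has no positive peak")
    return kernel / m


def _tuning(gt: GroundTruth, angle_deg: float) -> np.ndarray:
    """Von Mises tuning profile, 1 at the preferred angle."""
    delta = np.deg2rad(angle_deg - gt.preferred_angle_deg)
    return np.exp(gt.kappa * (np.cos(delta) - 1.0))


def _orientation_tuning(gt: GroundTruth, orientation_deg: float) -> np.ndarray:
    """180-deg-periodic tuning used for disk-boundary orientation."""
    delta = 2.0 * np.deg2rad(orientation_deg - gt.preferred_angle_deg)
    return np.exp(gt.kappa * (np.cos(delta) - 1.0))


def _action_side(gt: GroundTruth, finger: str) -> np.ndarray:
    """+1 where ``finger`` is contralateral to the voxel's hemisphere."""
    contra = np.where(gt.hemisphere == "left", "right", "left")
    return np.where(contra == finger, 1.0, -1.0)


def event_amplitudes(trial_row, gt: GroundTruth, condition: str) -> np.ndarray:
    """Per-voxel neural amplitude during the delay-period window.

    ``baseline + g_condition * exp(kappa * (cos(angle - pref) - 1))`` plus,
    on informative trials only, ``action_weight * side`` where ``side`` is
    +1 for the contralateral and -1 for the ipsilateral correct finger.
    """
    amp = np.full(gt.n_voxels, float(gt.baseline_amp))
    gain = gt.spatial_gain.get(condition, 0.0)
    angle = trial_row["target_angle_deg"]
    if np.isfinite(angle) and gain != 0.0:
        amp = amp + gain * _tuning(gt, float(angle))
    finger = trial_row.get("correct_finger", "none")
    if condition == "informative" and finger in ("left", "right"):
        amp = amp + gt.action_weight * _action_side(gt, finger)
    return amp


def _trial_events(trial_row, gt: GroundTruth):
    """(start_s, end_s, amplitude) neural events for one trial, times
    relative to trial onset.  Overlapping events sum."""
    task = trial_row["task"]
    base = float(gt.baseline_amp)
    V = gt.n_voxels
    events = []
    if task == "main":
        condition = trial_row["condition"]
        angle = float(trial_row["target_angle_deg"])
        finger = trial_row["correct_finger"]
        # Visual drive + memory encoding, shared between conditions until
        # the preview disk reveals (or fails to reveal) the response map.
        enc = np.full(V, base) + gt.encoding_gain * _tuning(gt, angle)
        events.append((0.0, gt.info_onset_s, enc))
        events.append((gt.info_onset_s, gt.info_offset_s, event_amplitudes(trial_row, gt, condition)))
        # Preview disk: a physical stimulus whose boundary orientation
        # drives orientation-tuned voxels identically in both conditions.
        preview = trial_row.get("preview_rotation_deg", np.nan)
        if gt.orientation_gain != 0.0 and np.isfinite(preview):
            orient = float(preview) % 180.0
            amp = gt.orientation_gain * _orientation_tuning(gt, orient)
            events.append((MAIN_EVENTS_S["preview"][0], MAIN_EVENTS_S["preview"][1], amp))
        # Response window: disk onscreen and the press actually executed.
        resp = np.full(V, base)
        if finger in ("left", "right"):
            resp = resp + gt.action_weight * _action_side(gt, finger)
        events.append((MAIN_EVENTS_S["response"][0], MAIN_EVENTS_S["response"][1], resp))
    elif task == "mapping":
        angle = float(trial_row["target_angle_deg"])
        amp = np.full(V, base) + gt.encoding_gain * _tuning(gt, angle)
        events.append((0.0, 12.5, amp))  # target + delay
    elif task == "spatial_localizer":
        angle = float(trial_row["target_angle_deg"])
        amp = np.full(V, base) + gt.encoding_gain * _tuning(gt, angle)
        events.append((0.0, 3.0, amp))
    elif task == "button_localizer":
        finger = trial_row["correct_finger"]
        amp = np.full(V, base)
        if finger in ("left", "right"):
            amp = amp + gt.action_weight * _action_side(gt, finger)
        events.append((0.0, 1.0, amp))
    else:
        raise ValueError(f"unknown task {task!r}")
    return events


def _ar1_noise(rng, shape, sd, phi):
    """Stationary AR(1) Gaussian noise with marginal standard deviation sd."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, shape)
    eps[:, 0] = rng.normal(0.0, sd, shape[0])  # stationary start
    return sp_signal.lfilter([1.0], [1.0, -phi], eps, axis=1)


def simulate_session(
    trial_table,
    gt: GroundTruth,
    sim_spec: SimSpec | None = None,
    seed: int | None = None,
) -> ROITimeSeries:
    """Simulate raw voxel x TR time series for every run in a trial table.

    Per run, neural boxcars (see :func:`event_amplitudes`) are placed at the
    within-trial event windows, convolved with the double-gamma HRF, and
    summed with AR(1) Gaussian noise.  Overlapping events add linearly.

    Returns an :class:`ROITimeSeries` in state ``raw``; the result is
    deterministic under (table, ground truth, seed).
    """
    if seed is None:
        raise ValueError("a seed is required")
    spec = sim_spec or SimSpec()
    noise_sd = spec.noise_sd if spec.noise_sd is not None else gt.noise_sd
    phi = spec.ar1_phi if spec.ar1_phi is not None else gt.ar1_phi
    tr = spec.tr_s
    kernel = double_gamma_hrf(gt.hrf_params, tr, spec.hrf_duration_s)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))

    task = trial_table["task"].iloc[0]
    duration = RUN_DURATION_S[task]
    n_tr = int(np.ceil(duration / tr))
    t_mid = (np.arange(n_tr) + 0.5) * tr

    blocks, run_ids, run_keys = [], [], {}
    groups = list(trial_table.groupby(["session", "run"], sort=True))
    for code, ((sess, run), run_table) in enumerate(groups):
        neural = np.zeros((gt.n_voxels, n_tr))
        for _, row in run_table.iterrows():
            onset = float(row["onset_s"])
            for start, end, amp in _trial_events(row, gt):
                if np.asarray(amp).shape != (gt.n_voxels,):
                    raise ValueError("amplitude vector does not match voxel count")
                mask = (t_mid >= onset + start) & (t_mid < onset + end)
                neural[:, mask] += amp[:, None]
        bold = sp_signal.fftconvolve(neural, kernel[None, :], mode="full", axes=1)[:, :n_tr]
        if noise_sd > 0:
            bold = bold + _ar1_noise(rng, (gt.n_voxels, n_tr), noise_sd, phi)
        blocks.append(bold)
        run_ids.append(np.full(n_tr, code))
        run_keys[code] = (int(sess), int(run))

    return ROITimeSeries(
        data=np.concatenate(blocks, axis=1),
        tr_s=tr,
        run_ids=np.concatenate(run_ids),
        state="raw",
        run_keys=run_keys,
        ground_truth=gt,
    )


def concat_sessions(*series: ROITimeSeries) -> ROITimeSeries:
    """Concatenate per-session time series along time, re-coding runs."""
    if not series:
        raise ValueError("nothing to concatenate")
    v = series[0].n_voxels
    state = series[0].state
    if any(s.n_voxels != v or s.state != state or s.tr_s != series[0].tr_s for s in series):
        raise ValueError("all series must share voxel count, state and TR")
    data, ids, keys = [], [], {}
    offset = 0
    for s in series:
        codes = s.run_codes()
        remap = {c: offset + i for i, c in enumerate(codes)}
        data.append(s.data)
        ids.append(np.vectorize(remap.get)(s.run_ids))
        keys.update({remap[c]: s.run_keys.get(c, (None, None)) for c in codes})
        offset += len(codes)
    return ROITimeSeries(
        data=np.concatenate(data, axis=1),
        tr_s=series[0].tr_s,
        run_ids=np.concatenate(ids),
        state=state,
        run_keys=keys,
        ground_truth=series[0].ground_truth,
    )
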