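"""Trial-design generators for the four scanner tasks.

All four generators return a tidy :class:`pandas.DataFrame` ("trial table")
with one row per trial and a shared column set (see :data:`TRIAL_COLUMNS`).
Angles are in degrees on ``[0, 360)`` (0 deg at the positive x-axis,
counter-clockwise); times are in seconds from the start of the run.

Tasks
-----
``main``
    Delayed spatial working-memory task.  A target dot appears on an
    invisible ring, is remembered across a 16 s delay, and the participant
    reports which half of a two-toned "response disk" contained it.  On
    *informative* trials a preview disk shown early in the delay already
    matches the final response disk, so the button press can be planned in
    advance; on *uninformative* trials the preview orientation is random.
``mapping``
    Spatial working-memory mapping task used as independent decoder
    training data: 200 target angles tiling the circle at 1.8 deg spacing.
``spatial_localizer``
    Flickering checkerboard wedges at 24 polar angles, used to train
    sensory-driven spatial decoders.
``button_localizer``
    Cued left/right index-finger button presses, used to train
    action decoders and to tag sensorimotor voxels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "RUN_DURATION_S",
    "MAIN_EVENTS_S",
    "generate_main_task_design",
    "generate_mapping_design",
    "generate_spatial_localizer_design",
    "generate_button_localizer_design",
]

#: Column order of every trial table.
TRIAL_COLUMNS = [
    "task",
    "participant",
    "session",
    "run",
    "trial",
    "onset_s",
    "condition",
    "target_angle_deg",
    "preview_rotation_deg",
    "response_rotation_deg",
    "boundary_orientation_deg",
    "correct_finger",
    "luminance_map",
    "hard_trial",
    "iti_s",
]

#: Fixed total run duration per task (final fixation pads to this length).
RUN_DURATION_S = {
    "main": 466.0,
    "mapping": 406.0,
    "spatial_localizer": 313.0,
    "button_localizer": 319.0,
}

#: Within-trial event times for the main task, seconds relative to target
#: onset: pre-cue, target, condition color cue, preview disk, response disk.
MAIN_EVENTS_S = {
    "cue": (-0.75, 0.0),
    "target": (0.0, 0.5),
    "color_cue": (1.5, 3.5),
    "preview": (3.5, 4.5),
    "response": (16.5, 18.5),
}

# Trial "blocks" (pre-cue through last task event, excluding ITI).
_MAIN_BLOCK_S = 0.75 + 18.5
_MAPPING_BLOCK_S = 0.75 + 0.5 + 12.0 + 3.0


def _require_seed(seed) -> int:
    if seed is None:
        raise ValueError("a seed is required; designs must be reproducible")
    return int(seed)


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def _draw_itis(rng, n, lo, hi, budget_s, grid=0.1, max_tries=1000):
    """Draw ``n`` jittered ITIs on a ``grid``-spaced [lo, hi] lattice whose
    sum leaves non-negative final-fixation padding within ``budget_s``."""
    choices = np.round(np.arange(lo, hi + grid / 2, grid), 10)
    for _ in range(max_tries):
        itis = rng.choice(choices, size=n)
        if itis.sum() <= budget_s:
            return itis
    raise RuntimeError("could not draw ITIs within the run-duration budget")


def _finger_for_trial(target, rotation, luminance_map):
    """Correct index finger given the disk geometry and luminance mapping.

    The light half of the disk covers polar angles in ``(rotation,
    rotation + 180)``; the target sits on the light side iff
    ``sin(target - rotation) > 0``.  The 1.8 deg offset between the target
    and rotation lattices guarantees the sine never vanishes.
    """
    on_light = np.sin(np.deg2rad(target - rotation)) > 0
    light_finger = "left" if luminance_map == "lightleft" else "right"
    dark_finger = "right" if light_finger == "left" else "left"
    return light_finger if on_light else dark_finger


def _counterbalanced_pairs(rng):
    """Target angle / response rotation pairs for one condition.

    100 target angles on a 3.6 deg lattice and 100 disk rotations on the
    same lattice shifted by 1.8 deg, each used exactly once, paired so the
    10x10 matrix of (36 deg target bin) x (36 deg rotation bin)
    combinations is filled exactly once per cell.
    """
    targets = np.arange(100) * 3.6
    rotations = 1.8 + np.arange(100) * 3.6
    cell_target = np.empty((10, 10))
    cell_rotation = np.empty((10, 10))
    for tb in range(10):
        cell_target[tb, :] = rng.permutation(targets[tb * 10 : (tb + 1) * 10])
    for bb in range(10):
        cell_rotation[:, bb] = rng.permutation(rotations[bb * 10 : (bb + 1) * 10])
    return cell_target.ravel(), cell_rotation.ravel()


def generate_main_task_design(participant: int, session: int, seed: int) -> pd.DataFrame:
    """Generate one session (10 runs x 20 trials) of the main WM task.

    Counterbalancing operates at the session level: 100 trials per
    condition, each condition using 100 unique target angles (3.6 deg
    minimum spacing) and 100 unique response-disk rotations (offset
    1.8 deg from the target lattice), with every combination of target
    36-deg bin and rotation 36-deg bin occurring exactly once per
    condition.  Informative previews equal the response rotation;
    uninformative previews are an independent shuffle of the same 100
    rotations.  Trials are shuffled across the session and split evenly
    into 10 runs of 466 s.

    Parameters
    ----------
    participant, session : int
        Participant index and session index (1 or 2).  The
        luminance-to-finger mapping flips between the two sessions.
    seed : int
        Mandatory seed; identical arguments give identical tables.
    """
    seed = _require_seed(seed)
    if session not in (1, 2):
        raise ValueError(f"session must be 1 or 2, got {session!r}")
    rng = _rng(seed, int(participant), int(session), 0)

    luminance_map = "lightleft" if (int(participant) + session) % 2 == 0 else "lightright"

    rows = []
    for condition in ("informative", "uninformative"):
        targets, rotations = _counterbalanced_pairs(rng)
        if condition == "informative":
            previews = rotations.copy()
        else:
            previews = rng.permutation(rotations)
        for t, r, pv in zip(targets, rotations, previews):
            rows.append(
                {
                    "condition": condition,
                    "target_angle_deg": t,
                    "preview_rotation_deg": pv,
                    "response_rotation_deg": r,
                }
            )
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    records = []
    for run in range(1, 11):
        run_rows = rows[(run - 1) * 20 : run * 20]
        budget = RUN_DURATION_S["main"] - 20 * _MAIN_BLOCK_S
        itis = _draw_itis(rng, 19, 1.0, 5.0, budget)
        onset = 0.75
        for trial, row in enumerate(run_rows, start=1):
            target = row["target_angle_deg"]
            rotation = row["response_rotation_deg"]
            hard = int(target // 36) == int(rotation // 36)
            records.append(
                {
                    "task": "main",
                    "participant": int(participant),
                    "session": session,
                    "run": run,
                    "trial": trial,
                    "onset_s": round(onset, 10),
                    "condition": row["condition"],
                    "target_angle_deg": target,
                    "preview_rotation_deg": row["preview_rotation_deg"],
                    "response_rotation_deg": rotation,
                    "boundary_orientation_deg": rotation % 180.0,
                    "correct_finger": _finger_for_trial(target, rotation, luminance_map),
                    "luminance_map": luminance_map,
                    "hard_trial": bool(hard),
                    "iti_s": float(itis[trial - 1]) if trial < 20 else np.nan,
                }
            )
            if trial < 20:
                onset = onset + 18.5 + itis[trial - 1] + 0.75
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


def _binned_sequence_per_run(rng, values, n_bins, n_runs):
    """Assign ``values`` (lattice over the circle) to runs so each run
    samples each of ``n_bins`` equal bins exactly once."""
    per_bin = len(values) // n_bins
    assert per_bin == n_runs
    assignment = np.empty((n_runs, n_bins))
    for b in range(n_bins):
        assignment[:, b] = rng.permutation(values[b * per_bin : (b + 1) * per_bin])
    return assignment  # rows: runs, columns: one value per bin


def generate_mapping_design(participant: int, seed: int) -> pd.DataFrame:
    """Generate the 10-run spatial WM mapping task for one participant.

    200 target angles uniformly tile the circle at 1.8 deg spacing; the
    200 positions are split into 20 bins of 10 and each run samples each
    bin once.  Probe-dot start angles follow the identical scheme but are
    drawn independently of the targets.  Runs last 406 s.
    """
    seed = _require_seed(seed)
    rng = _rng(seed, int(participant), 0, 1)

    angles = np.arange(200) * 1.8
    target_by_run = _binned_sequence_per_run(rng, angles, 20, 10)
    probe_by_run = _binned_sequence_per_run(rng, angles, 20, 10)

    records = []
    for run in range(1, 11):
        targets = rng.permutation(target_by_run[run - 1])
        probes = rng.permutation(probe_by_run[run - 1])
        budget = RUN_DURATION_S["mapping"] - 20 * _MAPPING_BLOCK_S
        itis = _draw_itis(rng, 19, 1.0, 5.0, budget)
        onset = 0.75
        for trial in range(1, 21):
            records.append(
                {
                    "task": "mapping",
                    "participant": int(participant),
                    "session": 1,
                    "run": run,
                    "trial": trial,
                    "onset_s": round(onset, 10),
                    "condition": "none",
                    "target_angle_deg": targets[trial - 1],
                    "preview_rotation_deg": probes[trial - 1],
                    "response_rotation_deg": np.nan,
                    "boundary_orientation_deg": np.nan,
                    "correct_finger": "none",
                    "luminance_map": "none",
                    "hard_trial": False,
                    "iti_s": float(itis[trial - 1]) if trial < 20 else np.nan,
                }
            )
            if trial < 20:
                onset = onset + (_MAPPING_BLOCK_S - 0.75) + itis[trial - 1] + 0.75
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


def _localizer_run_sequence(rng, centers, reps, max_tries=200):
    """Random wedge order with no two consecutive wedges in one quadrant."""
    for _ in range(max_tries):
        counts = {c: reps for c in centers}
        seq = []
        ok = True
        while counts:
            prev_q = int(seq[-1] // 90) if seq else None
            allowed = [c for c in counts if int(c // 90) != prev_q]
            if not allowed:
                ok = False
                break
            c = allowed[rng.integers(len(allowed))]
            seq.append(c)
            counts[c] -= 1
            if counts[c] == 0:
                del counts[c]
        if ok:
            return np.asarray(seq)
    raise RuntimeError("failed to build a quadrant-constrained wedge sequence")


def generate_spatial_localizer_design(n_runs: int, seed: int) -> pd.DataFrame:
    """Generate the checkerboard-wedge spatial localizer.

    24 wedge centers at ``7.5 + k * 15`` degrees (offset 7.5 deg from the
    cardinal axes), 4 presentations per center per run (96 trials of 3 s,
    no ITI), with consecutive wedges never in the same quadrant.  Runs
    last 313 s; the residual after the final wedge is fixation.
    """
    seed = _require_seed(seed)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = _rng(seed, 0, 0, 2)
    centers = 7.5 + np.arange(24) * 15.0

    records = []
    for run in range(1, n_runs + 1):
        seq = _localizer_run_sequence(rng, centers, reps=4)
        for trial, center in enumerate(seq, start=1):
            records.append(
                {
                    "task": "spatial_localizer",
                    "participant": 0,
                    "session": 1,
                    "run": run,
                    "trial": trial,
                    "onset_s": 3.0 * (trial - 1),
                    "condition": "none",
                    "target_angle_deg": center,
                    "preview_rotation_deg": np.nan,
                    "response_rotation_deg": np.nan,
                    "boundary_orientation_deg": np.nan,
                    "correct_finger": "none",
                    "luminance_map": "none",
                    "hard_trial": False,
                    "iti_s": 0.0,
                }
            )
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


def generate_button_localizer_design(n_runs: int = 6, seed: int = None) -> pd.DataFrame:
    """Generate the sensorimotor (button-press) localizer.

    Each 319 s run holds 60 one-second color-change trials (30 per index
    finger, randomly interleaved) separated by 2-6 s jittered ITIs; the
    cue-color-to-finger mapping is inverted on alternating runs.
    """
    seed = _require_seed(seed)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = _rng(seed, 0, 0, 3)

    records = []
    for run in range(1, n_runs + 1):
        fingers = rng.permutation(["left"] * 30 + ["right"] * 30)
        # reserve >= 8 s final fixation so post-trial epochs stay in-run
        budget = RUN_DURATION_S["button_localizer"] - 60 * 1.0 - 8.0
        itis = _draw_itis(rng, 59, 2.0, 6.0, budget)
        mapping = "lightleft" if run % 2 == 1 else "lightright"
        onset = 0.0
        for trial in range(1, 61):
            records.append(
                {
                    "task": "button_localizer",
                    "participant": 0,
                    "session": 1,
                    "run": run,
                    "trial": trial,
                    "onset_s": round(onset, 10),
                    "condition": "none",
                    "target_angle_deg": np.nan,
                    "preview_rotation_deg": np.nan,
                    "response_rotation_deg": np.nan,
                    "boundary_orientation_deg": np.nan,
                    "correct_finger": fingers[trial - 1],
                    "luminance_map": mapping,
                    "hard_trial": False,
                    "iti_s": float(itis[trial - 1]) if trial < 60 else np.nan,
                }
            )
            if trial < 60:
                onset = onset + 1.0 + itis[trial - 1]
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)
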