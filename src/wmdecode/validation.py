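"""Calibration studies run against the simulator's known ground truth.

Three self-contained study designs back the package's empirical claims:

* :func:`null_chance_replicates` — the full spatial decoding pipeline on
  information-free (null-profile) simulations, establishing the empirical
  chance level of the four-pair binary decoding scheme;
* :func:`type1_calibration` — rejection rates of the two group
  permutation tests on null data, checking their false-positive control;
* :func:`replicate_pattern_checks` — repeated simulated experiments at
  the default ground-truth profiles, checking that the qualitative
  dissociation (spatial code in visual-like ROIs weakened when the
  response is pre-plannable; action code in sensorimotor-like ROIs only
  then) is recovered reliably.
"""

from __future__ import annotations

import numpy as np

from wmdecode import decoding, preprocess, simulate, stats
from wmdecode.design import generate_main_task_design, generate_mapping_design
from wmdecode.pipeline import (
    EPOCH_TRS,
    ExperimentConfig,
    qualitative_pattern_check,
    run_experiment,
)

__all__ = [
    "null_chance_replicates",
    "type1_calibration",
    "replicate_pattern_checks",
]


def _window_pattern(ts_z, table, task):
    tensor = preprocess.epoch_trials(ts_z, table, EPOCH_TRS[task])
    tp = preprocess.average_window(tensor, task, table)
    return preprocess.mean_center_trials(tp)


def null_chance_replicates(
    n_replicates: int = 200,
    seed: int = 0,
    n_voxels: int = 24,
) -> np.ndarray:
    """Spatial decoding accuracy on information-free simulations.

    Each replicate simulates one participant's mapping session (decoder
    training data) and one main-task session under a null ground truth
    (all gains and action weights zero, AR(1) noise only), runs the full
    preprocessing + four-pair decoding pipeline, and records the session
    accuracy over all 200 test trials.  Returns the per-replicate
    accuracies; their mean estimates the decoding scheme's chance level.
    """
    ss = np.random.SeedSequence([int(seed), 101])
    child = ss.generate_state(3 * n_replicates) % (2**31)
    accs = np.empty(n_replicates)
    d_map = generate_mapping_design(1, seed=7)
    d_main = generate_main_task_design(1, 1, seed=7)
    for r in range(n_replicates):
        gt = simulate.make_ground_truth("null", n_voxels, seed=int(child[3 * r]))
        ts_map = preprocess.zscore_runs(
            simulate.simulate_session(d_map, gt, seed=int(child[3 * r + 1]))
        )
        ts_main = preprocess.zscore_runs(
            simulate.simulate_session(d_main, gt, seed=int(child[3 * r + 2]))
        )
        train = _window_pattern(ts_map, d_map, "mapping")
        test = _window_pattern(ts_main, d_main, "main")
        accs[r] = decoding.spatial_decode(train, test).accuracy
    return accs


def _null_decode_problem(rng, n_voxels=10, n_train=8, n_test=25, n_pairs=4):
    """One participant's signal-free four-pair decoding problem.

    Mirrors the real pipeline's structure (accuracy = mean over four
    binary pair classifiers) so that the group statistics see the same
    accuracy granularity as in actual use; a single coarse-grained
    classifier would produce tied condition scores and make the
    calibration spuriously conservative.
    """
    sets = []
    for k in range(n_pairs):
        sets.append(
            decoding.PairSet(
                train_a=rng.normal(size=(n_train, n_voxels)),
                train_b=rng.normal(size=(n_train, n_voxels)),
                test=rng.normal(size=(n_test, n_voxels)),
                test_is_b=rng.random(n_test) < 0.5,
                pair=(k, k + n_pairs),
            )
        )
    return sets


def type1_calibration(
    n_experiments: int = 200,
    n_participants: int = 6,
    n_iter: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """False-positive rates of the group permutation tests on null data.

    Each simulated experiment draws signal-free decoding problems for
    ``n_participants`` participants, scores the real (unshuffled) decoder,
    and runs both :func:`wmdecode.stats.perm_above_chance` (with genuine
    label-shuffling nulls) and :func:`wmdecode.stats.perm_condition_diff`
    (on two independent null condition scores).  Returns the fraction of
    experiments rejecting at ``alpha`` for each test.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    reject_above = 0
    reject_diff = 0
    for _ in range(n_experiments):
        sets = [_null_decode_problem(rng) for _ in range(n_participants)]
        real = np.array([decoding.pair_sets_accuracy(ps)[0] for ps in sets])

        def null_fn(rng_, _sets=sets):
            return [
                decoding.pair_sets_accuracy(ps, rng=rng_, shuffle_train=True)[0]
                for ps in _sets
            ]

        out = stats.perm_above_chance(
            real, null_fn, n_iter=n_iter, seed=int(rng.integers(2**31))
        )
        reject_above += out.p_value <= alpha

        sets2 = [_null_decode_problem(rng) for _ in range(n_participants)]
        other = np.array([decoding.pair_sets_accuracy(ps)[0] for ps in sets2])
        out2 = stats.perm_condition_diff(
            real, other, n_iter=n_iter, seed=int(rng.integers(2**31))
        )
        reject_diff += out2.p_value <= alpha
    return {
        "above_chance": reject_above / n_experiments,
        "condition_diff": reject_diff / n_experiments,
        "alpha": alpha,
        "n_experiments": n_experiments,
    }


def _check_config(master_seed: int, n_voxels: int = 24, n_iter: int = 200) -> ExperimentConfig:
    return ExperimentConfig(
        n_participants=6,
        rois={
            "V1_like": {"profile": "visual_like", "n_voxels": n_voxels},
            "S1M1_like": {"profile": "sensorimotor_like", "n_voxels": n_voxels},
        },
        analyses={
            "behavioral": False,
            "univariate": False,
            "spatial": True,
            "action": True,
            "disk": False,
        },
        n_iter=n_iter,
        n_iter_signflip=1000,
        master_seed=master_seed,
    )


def replicate_pattern_checks(
    n_replicates: int = 50,
    seed: int = 0,
    n_voxels: int = 50,
    n_iter: int = 200,
) -> list[dict]:
    """Run ``n_replicates`` simulated experiments and pattern checks.

    Each replicate runs a six-participant experiment with one visual-like
    and one sensorimotor-like ROI at the default generative gains, then
    applies :func:`wmdecode.pipeline.qualitative_pattern_check`.  Returns
    the list of reports.
    """
    seeds = np.random.SeedSequence([int(seed), 303]).generate_state(n_replicates) % (2**31)
    reports = []
    for r in range(n_replicates):
        bundle = run_experiment(_check_config(int(seeds[r]), n_voxels, n_iter))
        reports.append(qualitative_pattern_check(bundle))
    return reports
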