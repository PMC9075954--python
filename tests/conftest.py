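import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wmdecode import design, preprocess, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def main_design():
    return design.generate_main_task_design(participant=1, session=1, seed=7)


@pytest.fixture(scope="session")
def main_design_s2():
    return design.generate_main_task_design(participant=1, session=2, seed=7)


@pytest.fixture(scope="session")
def mapping_design():
    return design.generate_mapping_design(participant=1, seed=3)


@pytest.fixture(scope="session")
def visual_gt():
    return simulate.make_ground_truth("visual_like", 40, seed=5)


@pytest.fixture(scope="session")
def null_gt():
    return simulate.make_ground_truth("null", 40, seed=5)


@pytest.fixture(scope="session")
def zscored_main(main_design, visual_gt):
    ts = simulate.simulate_session(main_design, visual_gt, seed=21)
    return preprocess.zscore_runs(ts)


def single_run_timeseries(data, tr_s=0.8, state="raw"):
    """Wrap a (voxels, TRs) array as a one-run ROITimeSeries."""
    data = np.atleast_2d(np.asarray(data, float))
    return simulate.ROITimeSeries(
        data=data,
        tr_s=tr_s,
        run_ids=np.zeros(data.shape[1], int),
        state=state,
        run_keys={0: (1, 1)},
    )


def toy_trial_table(onsets_s, task="main", session=1, run=1, **cols):
    n = len(onsets_s)
    base = {
        "task": [task] * n,
        "participant": [1] * n,
        "session": [session] * n,
        "run": [run] * n,
        "trial": list(range(1, n + 1)),
        "onset_s": list(onsets_s),
        "condition": cols.pop("condition", ["informative"] * n),
        "target_angle_deg": cols.pop("target_angle_deg", [0.0] * n),
        "preview_rotation_deg": cols.pop("preview_rotation_deg", [np.nan] * n),
        "response_rotation_deg": cols.pop("response_rotation_deg", [np.nan] * n),
        "boundary_orientation_deg": [np.nan] * n,
        "correct_finger": cols.pop("correct_finger", ["none"] * n),
        "luminance_map": ["lightleft"] * n,
        "hard_trial": [False] * n,
        "iti_s": [np.nan] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)
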