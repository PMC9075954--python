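"""Angular binning, the normalized-Euclidean classifier, and all regimes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from wmdecode import decoding
from wmdecode.decoding import (
    DecoderModel,
    PairSet,
    assign_bins,
    localizer_bins,
    orientation_bins,
    predict_nedc,
    spatial_bins,
    train_nedc,
)
from wmdecode.preprocess import TrialPattern

from conftest import toy_trial_table


def make_pattern(data, angles=None, fingers=None, conditions=None, centered=True):
    data = np.asarray(data, float)
    n = data.shape[0]
    labels = toy_trial_table(
        list(np.arange(n, dtype=float)),
        target_angle_deg=list(angles) if angles is not None else [0.0] * n,
        correct_finger=list(fingers) if fingers is not None else ["none"] * n,
        condition=list(conditions) if conditions is not None else ["informative"] * n,
    )
    return TrialPattern(data=data, labels=labels, centered=centered)


class TestAssignBins:
    def test_spatial_scheme_examples(self):
        scheme = spatial_bins()
        assert assign_bins([0.0], scheme)[0] == 0
        assert assign_bins([22.5], scheme)[0] == 1  # half-open upper edge
        assert assign_bins([22.4], scheme)[0] == 0
        assert assign_bins([359.0], scheme)[0] == 0
        assert assign_bins([180.0], scheme)[0] == 4

    def test_overlapping_localizer_scheme(self):
        scheme = localizer_bins()
        # |52.5 - 45| = 7.5 <= 30 but |52.5 - 90| = 37.5 > 30 -> only bin 1
        assert assign_bins([52.5], scheme)[0] == [1]
        # 67.5 is within 30 deg of both 45 and 90 -> bins 1 and 2
        assert assign_bins([67.5], scheme)[0] == [1, 2]

    def test_orientation_scheme_mod_180(self):
        scheme = orientation_bins()
        assert assign_bins([183.0 % 180.0], scheme)[0] == 0  # 3 deg -> bin 0
        assert assign_bins([91.0], scheme)[0] == 2  # 91 deg -> the 90 bin

    @given(st.floats(min_value=-720.0, max_value=720.0, allow_nan=False))
    def test_total_function_on_finite_angles(self, angle):
        label = assign_bins([angle], spatial_bins())[0]
        assert 0 <= label < 8
        # the assigned bin center is the nearest center (half-open ties up)
        d = np.abs(decoding._signed_circ_diff(angle, 45.0 * label, 360.0))
        assert d <= 22.5


class TestTrainNEDC:
    def test_hand_computed_means_and_pooled_variance(self):
        a = np.array([[0.0, 0.0], [0.0, 2.0]])
        b = np.array([[2.0, 0.0], [2.0, 2.0]])
        with pytest.warns(UserWarning, match="zero pooled variance"):
            model = train_nedc(a, b)
        assert np.allclose(model.class_means, [[0.0, 1.0], [2.0, 1.0]])
        # voxel 0 has no within-class variance (floored); voxel 1 pools the
        # two unbiased class variances: (2 + 2) / 2 = 2
        assert model.pooled_var[0] == pytest.approx(1e-12)
        assert model.pooled_var[1] == pytest.approx(2.0)

    def test_identical_points_floor_and_warn(self):
        x = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning):
            model = train_nedc(x, x + 1)
        assert np.all(model.pooled_var == 1e-12)

    def test_imbalanced_classes_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            train_nedc(np.zeros((3, 2)), np.ones((2, 2)))

    def test_voxel_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(4, 5)), rng.normal(size=(4, 5)) + 1
        perm = rng.permutation(5)
        m1 = train_nedc(a, b)
        m2 = train_nedc(a[:, perm], b[:, perm])
        assert np.allclose(m1.class_means[:, perm], m2.class_means)
        assert np.allclose(m1.pooled_var[perm], m2.pooled_var)


class TestPredictNEDC:
    def test_class_mean_classified_correctly(self):
        model = DecoderModel(
            class_means=np.array([[0.0, 0.0], [2.0, 0.0]]),
            pooled_var=np.array([1.0, 1.0]),
            class_labels=(0, 1),
            n_train=2,
        )
        assert predict_nedc(model, [[0.0, 0.0]])[0] == 0
        assert predict_nedc(model, [[2.0, 0.0]])[0] == 1

    def test_hand_evaluated_normalized_distance(self):
        # means A=(0,0), B=(2,0); var=(4,1); x=(1.2,0): d_A=0.36 > d_B=0.16
        model = DecoderModel(
            class_means=np.array([[0.0, 0.0], [2.0, 0.0]]),
            pooled_var=np.array([4.0, 1.0]),
            class_labels=(0, 1),
            n_train=2,
        )
        assert predict_nedc(model, [[1.2, 0.0]])[0] == 1

    def test_tie_goes_to_lower_label(self):
        model = DecoderModel(
            class_means=np.array([[0.0], [2.0]]),
            pooled_var=np.array([1.0]),
            class_labels=(3, 7),
            n_train=2,
        )
        assert predict_nedc(model, [[1.0]])[0] == 3

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_matches_diagonal_covariance_oracle(self, seed):
        """NEDC equals an independently coded diagonal-covariance
        nearest-mean rule on random small instances."""
        rng = np.random.default_rng(seed)
        n_vox = rng.integers(1, 7)
        n_per = rng.integers(2, 9)
        a = rng.normal(size=(n_per, n_vox))
        b = rng.normal(size=(n_per, n_vox)) + rng.normal()
        x = rng.normal(size=(5, n_vox))
        model = train_nedc(a, b)
        got = predict_nedc(model, x)
        # oracle: explicit per-voxel standardization then plain Euclidean
        sd = np.sqrt(0.5 * (a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)))
        sd = np.maximum(sd, np.sqrt(1e-12))
        da = np.linalg.norm((x - a.mean(0)) / sd, axis=1)
        db = np.linalg.norm((x - b.mean(0)) / sd, axis=1)
        oracle = np.where(da <= db, 0, 1)
        assert np.array_equal(got, oracle)

    def test_scale_equivariance_of_accuracy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 6))
        b = rng.normal(size=(10, 6)) + 0.8
        x = rng.normal(size=(20, 6)) + 0.4
        scale = rng.uniform(0.1, 10.0, 6)
        shift = rng.normal(size=6)
        base = predict_nedc(train_nedc(a, b), x)
        scaled = predict_nedc(
            train_nedc(a * scale + shift, b * scale + shift), x * scale + shift
        )
        assert np.array_equal(base, scaled)


class TestSpatialDecode:
    def _separable_pattern(self, n_per_bin=6, noise=0.05, seed=0, bins=range(8)):
        rng = np.random.default_rng(seed)
        angles, rows = [], []
        for b in bins:
            proto = rng.normal(size=16)
            for _ in range(n_per_bin):
                angles.append(45.0 * b + rng.uniform(-20, 20))
                rows.append(proto + rng.normal(scale=noise, size=16))
        data = np.asarray(rows) - np.mean(rows, axis=1, keepdims=True)
        return make_pattern(data, angles=np.asarray(angles) % 360)

    def test_accuracy_is_mean_of_pair_accuracies(self):
        sets = [
            PairSet(
                train_a=np.zeros((2, 2)),
                train_b=np.ones((2, 2)),
                test=np.zeros((1, 2)),
                test_is_b=np.array([False]),
                pair=(k, k + 4),
            )
            for k in range(4)
        ]
        for ps in sets:
            ps.train_a[0, 0] = 0.01  # avoid zero variance warnings
            ps.train_b[0, 0] = 1.01
        acc, pair_accs, excluded, n = decoding.pair_sets_accuracy(sets)
        assert acc == pytest.approx(np.mean(pair_accs))
        assert n == 4

    def test_perfectly_separable_data_decodes_perfectly(self):
        tp = self._separable_pattern()
        res = decoding.spatial_decode(tp, tp)
        assert res.accuracy == 1.0
        assert len(res.pair_accuracies) == 4

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for rep in range(30):
            data = rng.normal(size=(64, 12))
            data -= data.mean(axis=1, keepdims=True)
            angles = np.repeat(np.arange(8) * 45.0, 8)
            train = make_pattern(data, angles=angles)
            test = make_pattern(
                rng.normal(size=(64, 12)) - 0.0, angles=rng.permutation(angles)
            )
            test.data -= test.data.mean(axis=1, keepdims=True)
            accs.append(decoding.spatial_decode(train, test).accuracy)
        # binomial CI around 0.5 for the replicate mean
        sem = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * sem + 0.02

    def test_empty_pair_excluded_and_flagged(self):
        train = self._separable_pattern()
        test = self._separable_pattern(bins=[0, 4, 1, 5, 2, 6])  # nothing in (3,7)
        res = decoding.spatial_decode(train, test)
        assert res.excluded_pairs == [(3, 7)]
        assert len(res.pair_accuracies) == 3

    def test_uncentered_patterns_rejected(self):
        tp = self._separable_pattern()
        tp.centered = False
        with pytest.raises(ValueError, match="centered"):
            decoding.spatial_decode(tp, tp)


class TestWithinConditionCV:
    def test_fold_and_prediction_counts(self):
        tp = TestSpatialDecode()._separable_pattern(n_per_bin=10)
        res = decoding.spatial_decode_within_condition(tp, seed=0)
        assert res.n_test == 80  # every trial tested exactly once
        assert res.accuracy == 1.0  # noiseless separable data

    def test_equivalence_with_exhaustive_fold_oracle(self):
        """With equal class sizes and separable data, accuracy does not
        depend on how held-out trials are paired: brute-force all pairings
        of 4 trials per class and compare."""
        rng = np.random.default_rng(5)
        proto_a, proto_b = rng.normal(size=10), rng.normal(size=10) + 2.0
        Xa = proto_a + rng.normal(scale=0.05, size=(4, 10))
        Xb = proto_b + rng.normal(scale=0.05, size=(4, 10))
        X = np.vstack([Xa, Xb])
        idx_a, idx_b = np.arange(4), np.arange(4, 8)

        def fold_accuracy(pairing):
            correct = 0
            for ta, tb in pairing:
                tr_a = np.setdiff1d(idx_a, [ta])
                tr_b = np.setdiff1d(idx_b, [tb])
                model = train_nedc(X[tr_a], X[tr_b])
                correct += int(predict_nedc(model, X[[ta]])[0] == 0)
                correct += int(predict_nedc(model, X[[tb]])[0] == 1)
            return correct / 8

        oracle_accs = {
            fold_accuracy(list(zip(idx_a, perm)))
            for perm in itertools.permutations(idx_b)
        }
        assert oracle_accs == {1.0}
        got, n = decoding._leave_two_out_pair(X, idx_a, idx_b, np.random.default_rng(0))
        assert (got, n) == (1.0, 8)

    def test_condition_filter(self):
        tp = TestSpatialDecode()._separable_pattern(n_per_bin=6)
        conds = ["informative" if i % 2 == 0 else "uninformative" for i in range(tp.n_trials)]
        tp.labels["condition"] = conds
        res = decoding.spatial_decode_within_condition(tp, condition="informative", seed=0)
        assert res.n_test == tp.n_trials // 2


class TestActionDecode:
    def _session(self, signs, w, noise, rng, n=40):
        fingers = np.array(["left", "right"])[rng.integers(0, 2, n)]
        pm = np.where(fingers == "right", 1.0, -1.0)
        data = np.outer(pm * signs, w) + rng.normal(scale=noise, size=(n, len(w)))
        data -= data.mean(axis=1, keepdims=True)
        return make_pattern(data, fingers=fingers)

    def test_strong_signal_decodes_above_09(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=12)
        s1 = self._session(1.0, w, 0.3, rng)
        s2 = self._session(1.0, w, 0.3, rng)
        res = decoding.action_decode(s1, s2, seed=0)
        assert res.accuracy > 0.9
        assert res.regime == "cross_session_action"

    def test_null_signal_at_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(40):
            w = np.zeros(12)
            s1 = self._session(1.0, w, 1.0, rng)
            s2 = self._session(1.0, w, 1.0, rng)
            accs.append(decoding.action_decode(s1, s2, seed=0).accuracy)
        sem = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * sem + 0.02

    def test_luminance_confound_cannot_support_transfer(self):
        """A signal tied to the luminance mapping (which flips between
        sessions) reverses under cross-session transfer: it can never
        produce above-chance action decoding."""
        rng = np.random.default_rng(2)
        w = rng.normal(size=12)
        s1 = self._session(+1.0, w, 0.3, rng)  # luminance aligned with finger
        s2 = self._session(-1.0, w, 0.3, rng)  # mapping flipped in session 2
        cross = decoding.action_decode(s1, s2, seed=0)
        assert cross.accuracy <= 0.5
        # the same signal is fully decodable without the flip
        same = decoding.action_decode(s1, self._session(+1.0, w, 0.3, rng), seed=0)
        assert same.accuracy > 0.9


class TestDiskOrientationDecode:
    def test_rotation_mod_180_binning(self):
        scheme = orientation_bins()
        assert assign_bins([183.0 % 180], scheme)[0] == 0
        assert assign_bins([91.0 % 180], scheme)[0] == 2

    def test_orientation_tuned_voxels_decodable(self):
        rng = np.random.default_rng(0)
        prefs = rng.uniform(0, 180, 16)

        def session(n=48):
            rots = rng.uniform(0, 360, n)
            data = np.stack(
                [np.cos(2 * np.deg2rad((r % 180) - prefs)) for r in rots]
            ) + rng.normal(scale=0.3, size=(n, 16))
            data -= data.mean(axis=1, keepdims=True)
            tp = make_pattern(data)
            tp.labels["preview_rotation_deg"] = rots
            return tp

        res = decoding.disk_orientation_decode(session(), session(), seed=0)
        assert res.accuracy > 0.8
        assert res.regime == "disk_orientation"


class TestTimecourseDecode:
    def test_output_length_and_prestim_chance(self):
        rng = np.random.default_rng(0)
        n_tr, n_vox = 6, 10
        angles = np.repeat(np.arange(8) * 45.0, 6)
        train = make_pattern(
            rng.normal(size=(48, n_vox))
            + np.array([[np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))] + [0.0] * 8 for a in angles]),
            angles=angles,
        )
        train.data -= train.data.mean(axis=1, keepdims=True)
        tensor = rng.normal(size=(48, n_tr, n_vox))
        # inject signal only at TRs 3-5
        for t in range(3, 6):
            tensor[:, t, 0] += 3 * np.cos(np.deg2rad(angles))
            tensor[:, t, 1] += 3 * np.sin(np.deg2rad(angles))
        labels = make_pattern(np.zeros((48, n_vox)), angles=angles).labels
        results = decoding.timecourse_decode(
            "spatial", train_pattern=train, test_tensor=tensor, test_labels=labels
        )
        assert len(results) == n_tr
        accs = [r.accuracy for r in results]
        assert np.mean(accs[3:]) > np.mean(accs[:3]) + 0.2
        assert all(r.timepoint_tr == i for i, r in enumerate(results))
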