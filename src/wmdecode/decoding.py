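"""Circular-bin multivariate decoding with a normalized-Euclidean classifier.

The decoding scheme discretizes a circular label (polar angle of a
remembered target, or the orientation of a disk boundary) into evenly
spaced bins and trains one binary classifier per pair of bins lying
180 degrees apart (90 degrees for orientation), so that each classifier
sees a balanced two-class problem and chance is 50%.  The classifier is a
nearest-class-mean rule in per-voxel variance-normalized space ("normalized
Euclidean distance"): class means and a pooled per-voxel variance are
estimated from training patterns, and a test pattern is assigned to the
class whose mean is closest under

    d(x, c) = sum_v (x_v - mu_cv)^2 / var_v .

Supported train/test regimes mirror a cross-task generalization design:
train on an independent mapping task or sensory localizer and test on the
main task, leave-two-out cross-validation within one task condition,
cross-session transfer for action (finger) decoding, and per-TR
time-resolved variants of the spatial and action decoders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from wmdecode.preprocess import TrialPattern

__all__ = [
    "BinScheme",
    "spatial_bins",
    "localizer_bins",
    "orientation_bins",
    "assign_bins",
    "DecoderModel",
    "train_nedc",
    "predict_nedc",
    "DecodingResult",
    "PairSet",
    "build_pair_sets",
    "pair_sets_accuracy",
    "spatial_decode",
    "spatial_decode_within_condition",
    "build_action_sets",
    "action_decode",
    "disk_orientation_decode",
    "timecourse_decode",
]

VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class BinScheme:
    """Evenly spaced angular bins on a circle of period 360 or 180 deg."""

    n_bins: int
    width_deg: float
    centers_deg: tuple
    overlapping: bool
    period_deg: float

    def __post_init__(self):
        spacing = self.period_deg / self.n_bins
        diffs = np.diff(list(self.centers_deg) + [self.centers_deg[0] + self.period_deg])
        if not np.allclose(diffs, spacing):
            raise ValueError("bin centers must be evenly spaced at period/n_bins")
        if not self.overlapping and self.width_deg > spacing:
            raise ValueError("non-overlapping bins cannot be wider than their spacing")


def spatial_bins() -> BinScheme:
    """Eight non-overlapping 45-deg bins, first centered at 0 deg."""
    return BinScheme(8, 45.0, tuple(45.0 * k for k in range(8)), False, 360.0)


def localizer_bins() -> BinScheme:
    """Eight slightly overlapping 60-deg bins on the same eight centers."""
    return BinScheme(8, 60.0, tuple(45.0 * k for k in range(8)), True, 360.0)


def orientation_bins() -> BinScheme:
    """Four 45-deg orientation bins centered at 0/45/90/135 (period 180)."""
    return BinScheme(4, 45.0, (0.0, 45.0, 90.0, 135.0), False, 180.0)


def _signed_circ_diff(a, b, period):
    """Signed circular difference a-b in [-period/2, period/2)."""
    return (np.asarray(a) - b + period / 2.0) % period - period / 2.0


def assign_bins(angles_deg, scheme: BinScheme):
    """Assign angles to bins.

    Non-overlapping schemes return an int array: the unique bin whose
    half-open arc ``[center - w/2, center + w/2)`` contains the angle.
    Overlapping schemes return a list of index lists: every bin whose arc
    contains the angle (inclusive lower edge, exclusive upper edge).
    """
    angles = np.asarray(angles_deg, float) % scheme.period_deg
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    d = np.stack(
        [_signed_circ_diff(angles, c, scheme.period_deg) for c in scheme.centers_deg], axis=1
    )
    half = scheme.width_deg / 2.0
    member = (d >= -half) & (d < half)
    if scheme.overlapping:
        return [list(np.flatnonzero(row)) for row in member]
    labels = member.argmax(axis=1)
    if not member.any(axis=1).all():
        raise ValueError("non-overlapping scheme failed to cover an angle")
    return labels


@dataclass
class DecoderModel:
    """Fitted binary normalized-Euclidean-distance classifier."""

    class_means: np.ndarray  # (2, V)
    pooled_var: np.ndarray  # (V,)
    class_labels: tuple
    n_train: int  # per class


def train_nedc(train_a: np.ndarray, train_b: np.ndarray, class_labels=(0, 1)) -> DecoderModel:
    """Fit class means and pooled per-voxel variance from balanced classes.

    The pooled variance is the equal-weight average of the two classes'
    unbiased per-voxel variances; voxels whose pooled variance is zero are
    floored at 1e-12 with a warning.
    """
    a = np.atleast_2d(np.asarray(train_a, float))
    b = np.atleast_2d(np.asarray(train_b, float))
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"training classes must be balanced, got {a.shape[0]} vs {b.shape[0]} trials"
        )
    if a.shape[0] < 2:
        raise ValueError("need at least two training trials per class")
    means = np.stack([a.mean(axis=0), b.mean(axis=0)])
    pooled = 0.5 * (a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1))
    if np.any(pooled <= VAR_FLOOR):
        warnings.warn("zero pooled variance in some voxels; flooring at 1e-12")
        pooled = np.maximum(pooled, VAR_FLOOR)
    return DecoderModel(
        class_means=means, pooled_var=pooled, class_labels=tuple(class_labels), n_train=a.shape[0]
    )


def predict_nedc(model: DecoderModel, test: np.ndarray) -> np.ndarray:
    """Predict class labels by minimum variance-normalized distance.

    Ties go deterministically to the lower class label.
    """
    x = np.atleast_2d(np.asarray(test, float))
    d = ((x[:, None, :] - model.class_means[None, :, :]) ** 2 / model.pooled_var).sum(axis=2)
    pick = np.where(d[:, 0] <= d[:, 1], 0, 1)
    return np.asarray(model.class_labels)[pick]


@dataclass
class DecodingResult:
    """Accuracy of one decoding analysis (chance is 0.5 for all regimes)."""

    accuracy: float
    n_test: int
    regime: str
    pair_accuracies: list = field(default_factory=list)
    excluded_pairs: list = field(default_factory=list)
    condition: str | None = None
    participant: int | None = None
    roi: str | None = None
    timepoint_tr: int | None = None


@dataclass
class PairSet:
    """Train/test arrays for one binary classifier."""

    train_a: np.ndarray
    train_b: np.ndarray
    test: np.ndarray  # (n_test, V); may be empty
    test_is_b: np.ndarray  # (n_test,) bool
    pair: tuple


def _shuffled_pair(ps: PairSet, rng) -> tuple[np.ndarray, np.ndarray]:
    """Permute training labels across the two classes, preserving counts."""
    pooled = np.concatenate([ps.train_a, ps.train_b])
    perm = rng.permutation(pooled.shape[0])
    n = ps.train_a.shape[0]
    return pooled[perm[:n]], pooled[perm[n:]]


def pair_sets_accuracy(pair_sets, rng=None, shuffle_train=False):
    """Mean accuracy over binary pair classifiers.

    Each classifier is trained (optionally on label-shuffled training
    data, for permutation nulls) and scored on its own test trials; pairs
    with no test trials are excluded and reported.  The headline accuracy
    is the unweighted mean over the contributing pairs.
    """
    accs, excluded, n_test = [], [], 0
    for ps in pair_sets:
        if ps.test.shape[0] == 0:
            excluded.append(ps.pair)
            continue
        if shuffle_train:
            a, b = _shuffled_pair(ps, rng)
        else:
            a, b = ps.train_a, ps.train_b
        model = train_nedc(a, b, class_labels=(0, 1))
        pred = predict_nedc(model, ps.test)
        accs.append(float(np.mean(pred == ps.test_is_b.astype(int))))
        n_test += ps.test.shape[0]
    if not accs:
        raise ValueError("no pair has any test trials")
    return float(np.mean(accs)), accs, excluded, n_test


def _opposite_pairs(scheme: BinScheme):
    """Bin pairs separated by half the period: (0,4),(1,5),(2,6),(3,7)
    for the 8-bin spatial scheme, (0,2),(1,3) for orientations."""
    half = scheme.n_bins // 2
    return [(k, k + half) for k in range(half)]


def _train_rows(pattern, bins, b, overlapping):
    if overlapping:
        mask = np.array([b in lab for lab in bins])
    else:
        mask = bins == b
    return pattern.data[mask]


def build_pair_sets(
    train_pattern: TrialPattern,
    test_pattern: TrialPattern,
    train_scheme: BinScheme | None = None,
    test_scheme: BinScheme | None = None,
    angle_col: str = "target_angle_deg",
):
    """Construct the opposite-bin :class:`PairSet` list for spatial decoding.

    Train and test schemes must share bin centers (the training scheme may
    be the overlapping localizer variant); test trials are routed to the
    unique pair containing their bin.
    """
    train_scheme = train_scheme or spatial_bins()
    test_scheme = test_scheme or spatial_bins()
    if train_scheme.centers_deg != test_scheme.centers_deg:
        raise ValueError("train and test schemes must share bin centers")
    _check_centered(train_pattern, test_pattern)
    train_bins = assign_bins(train_pattern.labels[angle_col].to_numpy(), train_scheme)
    test_bins = assign_bins(test_pattern.labels[angle_col].to_numpy(), test_scheme)
    sets = []
    for a, b in _opposite_pairs(test_scheme):
        tr_a = _train_rows(train_pattern, train_bins, a, train_scheme.overlapping)
        tr_b = _train_rows(train_pattern, train_bins, b, train_scheme.overlapping)
        mask = (test_bins == a) | (test_bins == b)
        sets.append(
            PairSet(
                train_a=tr_a,
                train_b=tr_b,
                test=test_pattern.data[mask],
                test_is_b=(test_bins[mask] == b),
                pair=(a, b),
            )
        )
    return sets


def _check_centered(*patterns):
    for p in patterns:
        if not p.centered:
            raise ValueError("patterns must be mean-centered across voxels before decoding")


def spatial_decode(
    train_pattern: TrialPattern,
    test_pattern: TrialPattern,
    train_scheme: BinScheme | None = None,
    test_scheme: BinScheme | None = None,
    regime: str = "train_mapping",
    **meta,
) -> DecodingResult:
    """Cross-task spatial decoding: four opposite-bin binary classifiers.

    Final accuracy is the unweighted mean of the four pair accuracies,
    each classifier scored only on test trials falling in its own pair.
    """
    sets = build_pair_sets(train_pattern, test_pattern, train_scheme, test_scheme)
    acc, pair_accs, excluded, n_test = pair_sets_accuracy(sets)
    return DecodingResult(
        accuracy=acc,
        n_test=n_test,
        regime=regime,
        pair_accuracies=pair_accs,
        excluded_pairs=excluded,
        **meta,
    )


def _leave_two_out_pair(X, idx_a, idx_b, rng):
    """Leave-one-per-class-out CV for one bin pair; every trial tested once."""
    idx_a = rng.permutation(idx_a)
    idx_b = rng.permutation(idx_b)
    folds = max(len(idx_a), len(idx_b))
    seq_a = np.resize(idx_a, folds)  # cycle the shorter class
    seq_b = np.resize(idx_b, folds)
    predicted = {}
    for f in range(folds):
        ta, tb = seq_a[f], seq_b[f]
        tr_a = np.setdiff1d(idx_a, [ta])
        tr_b = np.setdiff1d(idx_b, [tb])
        n = min(len(tr_a), len(tr_b))
        if n < 2:
            raise ValueError("too few trials per class for leave-two-out CV")
        if len(tr_a) > n:
            tr_a = rng.permutation(tr_a)[:n]
        if len(tr_b) > n:
            tr_b = rng.permutation(tr_b)[:n]
        model = train_nedc(X[tr_a], X[tr_b])
        for t, truth in ((ta, 0), (tb, 1)):
            if t not in predicted:
                predicted[t] = (int(predict_nedc(model, X[[t]])[0]), truth)
    correct = sum(pred == truth for pred, truth in predicted.values())
    return correct / len(predicted), len(predicted)


def spatial_decode_within_condition(
    pattern: TrialPattern,
    condition: str | None = None,
    seed: int = 0,
    scheme: BinScheme | None = None,
    **meta,
) -> DecodingResult:
    """Within-task spatial decoding with leave-two-out cross-validation.

    For each opposite-bin pair, folds hold out one trial per class (the
    pairing of held-out trials is a seeded random matching) so the
    training set stays balanced, and every trial is tested exactly once.
    Pair accuracies are pooled over folds, then averaged across pairs.
    """
    scheme = scheme or spatial_bins()
    _check_centered(pattern)
    if condition is not None:
        pattern = pattern.select(pattern.labels["condition"].to_numpy() == condition)
    rng = np.random.default_rng(seed)
    bins = assign_bins(pattern.labels["target_angle_deg"].to_numpy(), scheme)
    accs, counts = [], 0
    for a, b in _opposite_pairs(scheme):
        idx_a = np.flatnonzero(bins == a)
        idx_b = np.flatnonzero(bins == b)
        acc, n = _leave_two_out_pair(pattern.data, idx_a, idx_b, rng)
        accs.append(acc)
        counts += n
    return DecodingResult(
        accuracy=float(np.mean(accs)),
        n_test=counts,
        regime="within_condition",
        pair_accuracies=accs,
        condition=condition,
        **meta,
    )


def _binary_label_sets(train_pattern, test_pattern, label_col, classes, rng):
    """One cross-direction PairSet on a binary label, training balanced by
    seeded subsampling of the larger class."""
    y_tr = train_pattern.labels[label_col].to_numpy()
    a_idx = np.flatnonzero(y_tr == classes[0])
    b_idx = np.flatnonzero(y_tr == classes[1])
    n = min(len(a_idx), len(b_idx))
    if n < 2:
        raise ValueError(f"need >= 2 training trials per class for {classes}")
    if len(a_idx) > n:
        a_idx = rng.permutation(a_idx)[:n]
    if len(b_idx) > n:
        b_idx = rng.permutation(b_idx)[:n]
    y_te = test_pattern.labels[label_col].to_numpy()
    mask = (y_te == classes[0]) | (y_te == classes[1])
    return PairSet(
        train_a=train_pattern.data[a_idx],
        train_b=train_pattern.data[b_idx],
        test=test_pattern.data[mask],
        test_is_b=(y_te[mask] == classes[1]),
        pair=classes,
    )


def build_action_sets(pattern_s1, pattern_s2, label_col="correct_finger", seed=0):
    """Cross-session finger-decoding pair sets (both train directions)."""
    _check_centered(pattern_s1, pattern_s2)
    rng = np.random.default_rng(seed)
    classes = ("left", "right")
    return [
        _binary_label_sets(pattern_s1, pattern_s2, label_col, classes, rng),
        _binary_label_sets(pattern_s2, pattern_s1, label_col, classes, rng),
    ]


def action_decode(pattern_s1, pattern_s2, label_col="correct_finger", seed=0, **meta):
    """Decode the correct response finger across sessions.

    Trains on one session and tests on the other, in both directions, and
    averages the two accuracies.  Labels follow the *correct* finger, so
    the session-wise flip of the luminance-to-finger mapping guarantees a
    pure luminance signal cannot support transfer.
    """
    sets = build_action_sets(pattern_s1, pattern_s2, label_col, seed)
    acc, pair_accs, excluded, n_test = pair_sets_accuracy(sets)
    return DecodingResult(
        accuracy=acc,
        n_test=n_test,
        regime="cross_session_action",
        pair_accuracies=pair_accs,
        excluded_pairs=excluded,
        **meta,
    )


def build_orientation_sets(pattern_s1, pattern_s2, angle_col="preview_rotation_deg", seed=0):
    """Cross-session disk-orientation pair sets: two classifiers
    (0 vs 90 deg, 45 vs 135 deg) x two train directions."""
    _check_centered(pattern_s1, pattern_s2)
    rng = np.random.default_rng(seed)
    scheme = orientation_bins()
    sets = []
    for train_p, test_p in ((pattern_s1, pattern_s2), (pattern_s2, pattern_s1)):
        tr_bins = assign_bins(train_p.labels[angle_col].to_numpy() % 180.0, scheme)
        te_bins = assign_bins(test_p.labels[angle_col].to_numpy() % 180.0, scheme)
        for a, b in _opposite_pairs(scheme):
            ia, ib = np.flatnonzero(tr_bins == a), np.flatnonzero(tr_bins == b)
            n = min(len(ia), len(ib))
            if n < 2:
                raise ValueError("too few training trials in an orientation bin")
            ia, ib = rng.permutation(ia)[:n], rng.permutation(ib)[:n]
            mask = (te_bins == a) | (te_bins == b)
            sets.append(
                PairSet(
                    train_a=train_p.data[ia],
                    train_b=train_p.data[ib],
                    test=test_p.data[mask],
                    test_is_b=(te_bins[mask] == b),
                    pair=(a, b),
                )
            )
    return sets


def disk_orientation_decode(pattern_s1, pattern_s2, seed=0, **meta) -> DecodingResult:
    """Decode the preview-disk boundary orientation (mod 180 deg).

    Orientations are binned at 0/45/90/135 deg; two binary classifiers
    (0 vs 90, 45 vs 135) are trained per cross-session direction and all
    accuracies averaged.
    """
    sets = build_orientation_sets(pattern_s1, pattern_s2, seed=seed)
    acc, pair_accs, excluded, n_test = pair_sets_accuracy(sets)
    return DecodingResult(
        accuracy=acc,
        n_test=n_test,
        regime="disk_orientation",
        pair_accuracies=pair_accs,
        excluded_pairs=excluded,
        **meta,
    )


def timecourse_decode(
    regime: str,
    *,
    train_pattern: TrialPattern | None = None,
    test_tensor: np.ndarray | None = None,
    test_labels=None,
    tensor_s1: np.ndarray | None = None,
    labels_s1=None,
    tensor_s2: np.ndarray | None = None,
    labels_s2=None,
    seed: int = 0,
    **meta,
) -> list[DecodingResult]:
    """Per-TR decoding across an epoch.

    ``regime="spatial"`` trains once on a window-averaged mapping-task
    pattern and tests on every TR of the main-task epoch tensor;
    ``regime="action"`` trains and tests at the same TR but across
    sessions (both directions averaged).  Patterns at each TR are
    mean-centered across voxels before decoding.
    """
    from wmdecode.preprocess import mean_center_trials

    results = []
    if regime == "spatial":
        if train_pattern is None or test_tensor is None or test_labels is None:
            raise ValueError("spatial regime needs train_pattern, test_tensor, test_labels")
        for t in range(test_tensor.shape[1]):
            tp = mean_center_trials(
                TrialPattern(data=test_tensor[:, t, :], labels=test_labels, timepoint_tr=t)
            )
            res = spatial_decode(train_pattern, tp, regime="timecourse_spatial", **meta)
            res.timepoint_tr = t
            results.append(res)
    elif regime == "action":
        if tensor_s1 is None or tensor_s2 is None:
            raise ValueError("action regime needs tensor_s1/labels_s1 and tensor_s2/labels_s2")
        for t in range(tensor_s1.shape[1]):
            p1 = mean_center_trials(TrialPattern(data=tensor_s1[:, t, :], labels=labels_s1))
            p2 = mean_center_trials(TrialPattern(data=tensor_s2[:, t, :], labels=labels_s2))
            res = action_decode(p1, p2, seed=seed, **meta)
            res.regime = "timecourse_action"
            res.timepoint_tr = t
            results.append(res)
    else:
        raise ValueError(f"unknown time-course regime {regime!r}")
    return results
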