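"""Group-level permutation inference on per-participant statistics.

The group statistic throughout is a *signed* Wilcoxon-type rank sum of
paired differences: zeros are dropped, absolute differences are ranked
with average ranks on ties, and the statistic is ``sum(sign(d) * rank)``.
It is positive when the first member of each pair tends to exceed the
second.  Three permutation schemes build the null distributions:

* above-chance tests re-run the decoder with shuffled training labels on
  every iteration and count iterations on which the signed-rank statistic
  of (real - shuffled) fails to be positive (one-tailed);
* condition-difference tests flip each participant's condition pair with
  probability one half and count exceedances in both tails (two-tailed,
  doubled smaller tail);
* the two-way repeated-measures ANOVA permutes each participant's cell
  values across all ROI x condition cells and counts permuted F values at
  or above the observed ones.

P-values follow exact counting (no +1 smoothing), so p = 0 can occur at
finite iteration counts.  No multiple-comparison correction is applied
across timepoints or ROIs; an optional Benjamini-Hochberg helper is
provided but never applied implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "PermutationOutcome",
    "AnovaOutcome",
    "signed_rank_stat",
    "perm_above_chance",
    "perm_condition_diff",
    "rm_anova_f",
    "perm_rm_anova",
    "timepoint_condition_tests",
    "behavioral_tests",
    "benjamini_hochberg",
    "significance_tier",
]


@dataclass
class PermutationOutcome:
    """Observed statistic, permutation null and counted p-value."""

    observed_stat: float
    null_stats: np.ndarray
    n_iter: int
    tail: str  # "one_greater" or "two_sided"
    p_value: float
    seed: int | None = None
    note: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class AnovaOutcome:
    """Two-way repeated-measures F statistics with permutation p-values."""

    F_roi: float
    F_condition: float
    F_interaction: float
    df: dict
    p_roi: float
    p_condition: float
    p_interaction: float
    seed: int | None = None


def signed_rank_stat(diffs) -> float:
    """Signed rank sum: zeros dropped, average ranks on ties.

    ``sum(sign(d_i) * rank(|d_i|))``; positive iff the differences tend to
    be positive.  Raises if every difference is zero.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; signed-rank statistic undefined")
    ranks = sp_stats.rankdata(np.abs(d))
    return float(np.sum(np.sign(d) * ranks))


def perm_above_chance(
    real_accs,
    null_decoder_fn,
    n_iter: int = 1000,
    seed: int = 0,
    chance: float = 0.5,
) -> PermutationOutcome:
    """One-tailed group test that decoding exceeds a shuffled-label null.

    ``null_decoder_fn(rng)`` must re-run the decoding for every
    participant with training labels permuted (class counts preserved) and
    return the per-participant null accuracies.  Each iteration computes
    the signed-rank statistic of (real - null); the p-value is the
    fraction of iterations on which that statistic is <= 0.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    real = np.asarray(real_accs, float)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_iter)
    for i in range(n_iter):
        null = np.asarray(null_decoder_fn(rng), float)
        diffs = real - null
        stats[i] = signed_rank_stat(diffs) if np.any(diffs != 0) else 0.0
    p = float(np.mean(stats <= 0))
    observed = (
        signed_rank_stat(real - chance) if np.any(real != chance) else 0.0
    )
    return PermutationOutcome(
        observed_stat=observed,
        null_stats=stats,
        n_iter=n_iter,
        tail="one_greater",
        p_value=p,
        seed=seed,
    )


def perm_condition_diff(
    acc_cond1,
    acc_cond2,
    n_iter: int = 1000,
    seed: int = 0,
) -> PermutationOutcome:
    """Two-tailed sign-flip test for a paired condition difference.

    The observed statistic is the signed-rank statistic of
    (condition 1 - condition 2).  On each iteration every participant's
    pair is swapped with probability 0.5 and the statistic recomputed; the
    p-value doubles the smaller of the two exceedance counts (capped at
    1).  If the two conditions are identical for every participant the
    outcome is a "no difference" sentinel with p = 1.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    a = np.asarray(acc_cond1, float)
    b = np.asarray(acc_cond2, float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must be paired")
    diffs = a - b
    if np.all(diffs == 0):
        return PermutationOutcome(
            observed_stat=0.0,
            null_stats=np.zeros(n_iter),
            n_iter=n_iter,
            tail="two_sided",
            p_value=1.0,
            seed=seed,
            note="no difference between conditions",
        )
    obs = signed_rank_stat(diffs)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_iter)
    for i in range(n_iter):
        flips = rng.random(diffs.size) < 0.5
        d = np.where(flips, -diffs, diffs)
        stats[i] = signed_rank_stat(d) if np.any(d != 0) else 0.0
    n_ge = int(np.sum(stats >= obs))
    n_le = int(np.sum(stats <= obs))
    p = min(1.0, 2.0 * min(n_ge, n_le) / n_iter)
    return PermutationOutcome(
        observed_stat=obs,
        null_stats=stats,
        n_iter=n_iter,
        tail="two_sided",
        p_value=p,
        seed=seed,
    )


def rm_anova_f(table: np.ndarray) -> tuple[dict, dict]:
    """Classical two-way within-subject ANOVA F statistics.

    ``table`` is (participants, factor A levels, factor B levels); each
    effect is tested against its own subject-by-factor interaction error
    term.  Returns ``(F, df)`` dicts keyed by ``roi`` (factor A),
    ``condition`` (factor B) and ``interaction``.
    """
    A = np.asarray(table, float)
    if A.ndim != 3:
        raise ValueError("table must be participants x roi x condition")
    if np.isnan(A).any():
        raise ValueError("missing cells in the ANOVA table")
    n, a, b = A.shape
    grand = A.mean()
    subj = A.mean(axis=(1, 2))
    fa = A.mean(axis=(0, 2))
    fb = A.mean(axis=(0, 1))
    cell = A.mean(axis=0)
    sa = A.mean(axis=2)  # (n, a)
    sb = A.mean(axis=1)  # (n, b)

    ss_a = n * b * np.sum((fa - grand) ** 2)
    ss_b = n * a * np.sum((fb - grand) ** 2)
    ss_ab = n * np.sum((cell - fa[:, None] - fb[None, :] + grand) ** 2)
    ss_as = b * np.sum((sa - subj[:, None] - fa[None, :] + grand) ** 2)
    ss_bs = a * np.sum((sb - subj[:, None] - fb[None, :] + grand) ** 2)
    resid = (
        A
        - sa[:, :, None]
        - sb[:, None, :]
        - cell[None, :, :]
        + subj[:, None, None]
        + fa[None, :, None]
        + fb[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    df = {
        "roi": (a - 1, (a - 1) * (n - 1)),
        "condition": (b - 1, (b - 1) * (n - 1)),
        "interaction": ((a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    }
    F = {
        "roi": (ss_a / df["roi"][0]) / (ss_as / df["roi"][1]),
        "condition": (ss_b / df["condition"][0]) / (ss_bs / df["condition"][1]),
        "interaction": (ss_ab / df["interaction"][0]) / (ss_abs / df["interaction"][1]),
    }
    return F, df


def perm_rm_anova(table: np.ndarray, n_iter: int = 1000, seed: int = 0) -> AnovaOutcome:
    """Permutation two-way repeated-measures ANOVA.

    The null permutes each participant's scores across all ROI x condition
    cells independently; per effect, p is the fraction of iterations whose
    permuted F is >= the observed F.
    """
    A = np.asarray(table, float)
    F_obs, df = rm_anova_f(A)
    n, a, b = A.shape
    rng = np.random.default_rng(seed)
    counts = {"roi": 0, "condition": 0, "interaction": 0}
    flat = A.reshape(n, a * b)
    for _ in range(n_iter):
        perm = np.stack([row[rng.permutation(a * b)] for row in flat]).reshape(n, a, b)
        F_perm, _ = rm_anova_f(perm)
        for key in counts:
            if F_perm[key] >= F_obs[key]:
                counts[key] += 1
    return AnovaOutcome(
        F_roi=F_obs["roi"],
        F_condition=F_obs["condition"],
        F_interaction=F_obs["interaction"],
        df=df,
        p_roi=counts["roi"] / n_iter,
        p_condition=counts["condition"] / n_iter,
        p_interaction=counts["interaction"] / n_iter,
        seed=seed,
    )


def timepoint_condition_tests(
    values_cond1: np.ndarray,
    values_cond2: np.ndarray,
    n_iter: int = 1000,
    seed: int = 0,
) -> list[PermutationOutcome]:
    """Condition-difference sign-flip test at every timepoint.

    ``values_cond*`` are (participants, timepoints); one independent
    two-tailed :func:`perm_condition_diff` is run per timepoint.  No
    multiple-comparison correction is applied.
    """
    v1 = np.atleast_2d(np.asarray(values_cond1, float))
    v2 = np.atleast_2d(np.asarray(values_cond2, float))
    if v1.shape != v2.shape:
        raise ValueError("condition arrays must be paired")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(v1.shape[1])
    return [
        perm_condition_diff(v1[:, t], v2[:, t], n_iter=n_iter, seed=int(seeds[t] % (2**31)))
        for t in range(v1.shape[1])
    ]


def _paired_t(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    if np.all(d == 0):
        return 0.0, 1.0, d.size - 1
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance non-zero differences: t statistic undefined")
    t, p = sp_stats.ttest_rel(x, y)
    return float(t), float(p), d.size - 1


def behavioral_tests(accuracy_by_participant, rt_by_participant) -> dict:
    """Paired two-sided t-tests on behavioral accuracy and response time.

    Each input is (participants, 2) with columns (informative,
    uninformative).  Returns per-measure t, df and p.
    """
    out = {}
    for name, arr in (("accuracy", accuracy_by_participant), ("rt", rt_by_participant)):
        arr = np.asarray(arr, float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"{name} must be (participants, 2)")
        t, p, df = _paired_t(arr[:, 0], arr[:, 1])
        out[name] = {"t": t, "df": df, "p": p}
    return out


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask (optional; never applied by default)."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.flatnonzero(passed)) + 1 if passed.any() else 0
    mask = np.zeros(m, bool)
    mask[order[:k]] = True
    return mask


def significance_tier(p: float) -> int:
    """Dot-size tier used for plotting parity: 3 if p<0.001, 2 if p<0.01,
    1 if p<0.05, else 0."""
    return 3 if p < 0.001 else 2 if p < 0.01 else 1 if p < 0.05 else 0
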