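"""End-to-end orchestration of simulated working-memory experiments.

``run_experiment`` wires the full analysis graph on synthetic data:
design generation -> BOLD simulation -> preprocessing -> FIR
deconvolution and multivariate decoding -> group permutation statistics,
for N simulated participants and a configurable set of ROI information
profiles.  Every random draw derives from a single master seed through a
documented splitting rule, so any stage can be reproduced in isolation
and two runs with the same configuration produce hash-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wmdecode import decoding, deconvolution, preprocess, stats
from wmdecode.design import (
    generate_button_localizer_design,
    generate_main_task_design,
    generate_mapping_design,
    generate_spatial_localizer_design,
)
from wmdecode.io import dataframe_hash
from wmdecode.simulate import concat_sessions, make_ground_truth, simulate_session

__all__ = [
    "ExperimentConfig",
    "ResultsBundle",
    "run_experiment",
    "qualitative_pattern_check",
]

log = logging.getLogger("wmdecode")

#: Epoch lengths (TRs from trial onset) per task; long enough for the
#: analysis windows while staying inside the padded run tails.
EPOCH_TRS = {"main": 24, "mapping": 13, "spatial_localizer": 8, "button_localizer": 8}

DEFAULT_ROIS = {
    "V1_like": {"profile": "visual_like", "n_voxels": 50},
    "IPS_like": {"profile": "parietal_like", "n_voxels": 50},
    "S1M1_like": {"profile": "sensorimotor_like", "n_voxels": 50},
    "null_roi": {"profile": "null", "n_voxels": 50},
}

DEFAULT_ANALYSES = {
    "behavioral": True,
    "univariate": True,
    "spatial": True,
    "within_condition": False,
    "spatial_localizer_train": False,
    "action": True,
    "action_localizer_train": False,
    "disk": True,
    "timecourse": False,
}

CONDITIONS = ("informative", "uninformative")

# Group behavioral parameters the synthetic participants are drawn from:
# (mean, between-participant sd) per condition.
BEHAVIOR_MODEL = {
    "accuracy": {"informative": (93.92, 5.19), "uninformative": (89.83, 2.74)},
    "rt": {"informative": (0.57, 0.073), "uninformative": (1.08, 0.147)},
}
_BEHAVIOR_PARTICIPANT_R = 0.7  # within-participant correlation across conditions


@dataclass
class ExperimentConfig:
    """Configuration of one simulated experiment.

    ``rois`` maps ROI names to ``{"profile": ..., "n_voxels": ...}``;
    ``ground_truth_overrides`` maps ROI names to keyword overrides passed
    to :func:`wmdecode.simulate.make_ground_truth`.  ``analyses`` toggles
    pipeline stages by name (see :data:`DEFAULT_ANALYSES`).
    """

    n_participants: int = 6
    rois: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROIS.items()})
    ground_truth_overrides: dict = field(default_factory=dict)
    analyses: dict = field(default_factory=lambda: dict(DEFAULT_ANALYSES))
    n_iter: int = 1000
    n_iter_signflip: int | None = None  # sign-flip/ANOVA nulls; None -> n_iter
    master_seed: int = 0
    n_spatial_localizer_runs: int = 4
    n_button_localizer_runs: int = 6
    out_dir: str | None = None

    def __post_init__(self):
        merged = dict(DEFAULT_ANALYSES)
        merged.update(self.analyses)
        self.analyses = merged

    @property
    def iter_signflip(self) -> int:
        return self.n_iter if self.n_iter_signflip is None else self.n_iter_signflip

    # -- seed splitting -------------------------------------------------
    def seed_for(self, stage: str, *indices: int) -> int:
        """Derive a child seed: master_seed + CRC32(stage) + indices."""
        entropy = [int(self.master_seed), zlib.crc32(stage.encode())] + [int(i) for i in indices]
        return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ResultsBundle:
    """Tidy result tables plus a manifest tying every row to its seeds."""

    behavioral: pd.DataFrame
    hrf: pd.DataFrame
    decoding: pd.DataFrame
    stats: pd.DataFrame
    anova: pd.DataFrame
    manifest: dict

    def tables(self) -> dict:
        return {
            "behavioral": self.behavioral,
            "hrf": self.hrf,
            "decoding": self.decoding,
            "stats": self.stats,
            "anova": self.anova,
        }

    def table_hashes(self) -> dict:
        return {name: dataframe_hash(df) for name, df in self.tables().items()}

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(directory / f"{name}.csv", index=False)
        manifest = dict(self.manifest)
        manifest["table_hashes"] = self.table_hashes()
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return directory


def simulate_behavior(config: ExperimentConfig) -> pd.DataFrame:
    """Draw per-participant behavioral summaries (accuracy %, RT s).

    Participants share a latent ability factor across conditions so the
    paired structure of the group comparison is preserved.
    """
    rng = np.random.default_rng(config.seed_for("behavior"))
    r = _BEHAVIOR_PARTICIPANT_R
    rows = []
    for p in range(1, config.n_participants + 1):
        u = {m: rng.normal() for m in BEHAVIOR_MODEL}
        row = {"participant": p}
        for measure, conds in BEHAVIOR_MODEL.items():
            for cond, (mean, sd) in conds.items():
                e = rng.normal()
                value = mean + sd * (r * u[measure] + np.sqrt(1 - r**2) * e)
                if measure == "accuracy":
                    value = float(np.clip(value, 0.0, 100.0))
                else:
                    value = float(max(value, 0.05))
                row[f"{measure}_{cond}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-participant data preparation


def _prep_patterns(ts_z, table, task, center=True):
    tensor = preprocess.epoch_trials(ts_z, table, EPOCH_TRS[task])
    tp = preprocess.average_window(tensor, task, table)
    return (preprocess.mean_center_trials(tp) if center else tp), tensor


def _simulate_participant(config: ExperimentConfig, p: int, roi: str, spec: dict):
    """Simulate and preprocess all enabled tasks for one participant/ROI."""
    profile = spec["profile"]
    overrides = config.ground_truth_overrides.get(roi, {})
    gt = make_ground_truth(
        profile, spec["n_voxels"], config.seed_for("gt", p, _crc(roi)), **overrides
    )
    an = config.analyses
    out = {"gt": gt}

    d_main = {s: generate_main_task_design(p, s, config.seed_for("design_main")) for s in (1, 2)}
    ts_main = {
        s: preprocess.zscore_runs(
            simulate_session(d_main[s], gt, seed=config.seed_for("sim_main", p, _crc(roi), s))
        )
        for s in (1, 2)
    }
    out["d_main"] = d_main
    out["ts_main"] = ts_main
    out["main_tp"] = {}
    out["main_tensor"] = {}
    for s in (1, 2):
        tp, tensor = _prep_patterns(ts_main[s], d_main[s], "main")
        out["main_tp"][s] = tp
        out["main_tensor"][s] = tensor

    if an["spatial"] or an["within_condition"] or an["timecourse"]:
        d_map = generate_mapping_design(p, config.seed_for("design_map"))
        ts_map = preprocess.zscore_runs(
            simulate_session(d_map, gt, seed=config.seed_for("sim_map", p, _crc(roi)))
        )
        out["map_tp"], _ = _prep_patterns(ts_map, d_map, "mapping")
        out["d_map"] = d_map
    if an["spatial_localizer_train"]:
        d_loc = generate_spatial_localizer_design(
            config.n_spatial_localizer_runs, config.seed_for("design_sloc", p)
        )
        ts_loc = preprocess.zscore_runs(
            simulate_session(d_loc, gt, seed=config.seed_for("sim_sloc", p, _crc(roi)))
        )
        out["sloc_tp"], _ = _prep_patterns(ts_loc, d_loc, "spatial_localizer")
    if an["action_localizer_train"]:
        d_bloc = generate_button_localizer_design(
            config.n_button_localizer_runs, config.seed_for("design_bloc", p)
        )
        ts_bloc = preprocess.zscore_runs(
            simulate_session(d_bloc, gt, seed=config.seed_for("sim_bloc", p, _crc(roi)))
        )
        out["bloc_tp"], _ = _prep_patterns(ts_bloc, d_bloc, "button_localizer")
    return out


def _crc(name: str) -> int:
    return zlib.crc32(name.encode()) % (2**16)


def _select_cond(tp, condition):
    return tp.select(tp.labels["condition"].to_numpy() == condition)


def _both_sessions_tp(data, condition):
    tp1 = _select_cond(data["main_tp"][1], condition)
    tp2 = _select_cond(data["main_tp"][2], condition)
    merged = dataclasses.replace(
        tp1,
        data=np.concatenate([tp1.data, tp2.data]),
        labels=pd.concat([tp1.labels, tp2.labels], ignore_index=True),
    )
    return merged


# ---------------------------------------------------------------------------
# the experiment driver


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Run every enabled analysis on freshly simulated data.

    Returns a :class:`ResultsBundle`; deterministic under
    ``config.master_seed``.  Raises at the first failing stage with a
    stage-named diagnostic (no silent skipping).
    """
    t0 = time.time()
    an = config.analyses
    participants = range(1, config.n_participants + 1)

    behavioral = (
        simulate_behavior(config) if an["behavioral"] else pd.DataFrame()
    )

    decode_rows: list[dict] = []
    hrf_rows: list[pd.DataFrame] = []
    stats_rows: list[dict] = []
    anova_rows: list[dict] = []
    # (roi, regime, condition) -> {participant: pair_sets} for permutation nulls
    registry: dict = {}
    # (roi, regime, condition) -> {participant: accuracy}
    acc_registry: dict = {}
    hrf_group: dict = {}

    needs_sim = any(
        an[k]
        for k in (
            "univariate",
            "spatial",
            "within_condition",
            "spatial_localizer_train",
            "action",
            "action_localizer_train",
            "disk",
            "timecourse",
        )
    )

    for roi, spec in (config.rois.items() if needs_sim else []):
        log.info("simulating + decoding ROI %s (%s)", roi, spec["profile"])
        for p in participants:
            try:
                data = _simulate_participant(config, p, roi, spec)
            except Exception as err:  # pragma: no cover - diagnostics path
                raise RuntimeError(f"stage simulate failed for roi={roi} participant={p}") from err

            if an["univariate"]:
                ts_all = concat_sessions(data["ts_main"][1], data["ts_main"][2])
                table_all = pd.concat(
                    [data["d_main"][1], data["d_main"][2]], ignore_index=True
                )
                design = deconvolution.build_fir_design(
                    table_all, ts_all, conditions=list(CONDITIONS)
                )
                est = deconvolution.fit_fir(ts_all, design)
                hrf_rows.append(est.tidy(participant=p, roi=roi))
                hrf_group.setdefault(roi, []).append(est.roi_mean)

            for condition in CONDITIONS:
                test_tp = _both_sessions_tp(data, condition)
                if an["spatial"]:
                    sets = decoding.build_pair_sets(data["map_tp"], test_tp)
                    _record(
                        decode_rows, registry, acc_registry, sets,
                        roi, "train_mapping", condition, p,
                    )
                if an["spatial_localizer_train"]:
                    sets = decoding.build_pair_sets(
                        data["sloc_tp"], test_tp, train_scheme=decoding.localizer_bins()
                    )
                    _record(
                        decode_rows, registry, acc_registry, sets,
                        roi, "train_sensory_localizer", condition, p,
                    )
                if an["within_condition"]:
                    res = decoding.spatial_decode_within_condition(
                        test_tp, seed=config.seed_for("cv", p, _crc(roi)),
                        condition=None, participant=p, roi=roi,
                    )
                    res.condition = condition
                    decode_rows.append(_row(res))
                    acc_registry.setdefault((roi, "within_condition", condition), {})[p] = (
                        res.accuracy
                    )
                if an["action"]:
                    sets = decoding.build_action_sets(
                        _select_cond(data["main_tp"][1], condition),
                        _select_cond(data["main_tp"][2], condition),
                        seed=config.seed_for("action_balance", p, _crc(roi)),
                    )
                    _record(
                        decode_rows, registry, acc_registry, sets,
                        roi, "cross_session_action", condition, p,
                    )
                if an["action_localizer_train"]:
                    rngseed = config.seed_for("bloc_balance", p, _crc(roi))
                    sets = [
                        decoding._binary_label_sets(
                            data["bloc_tp"], test_tp, "correct_finger",
                            ("left", "right"), np.random.default_rng(rngseed),
                        )
                    ]
                    _record(
                        decode_rows, registry, acc_registry, sets,
                        roi, "train_button_localizer", condition, p,
                    )
                if an["disk"]:
                    sets = decoding.build_orientation_sets(
                        _select_cond(data["main_tp"][1], condition),
                        _select_cond(data["main_tp"][2], condition),
                        seed=config.seed_for("disk_balance", p, _crc(roi)),
                    )
                    _record(
                        decode_rows, registry, acc_registry, sets,
                        roi, "disk_orientation", condition, p,
                    )
                if an["timecourse"]:
                    results = decoding.timecourse_decode(
                        "spatial",
                        train_pattern=data["map_tp"],
                        test_tensor=np.concatenate(
                            [data["main_tensor"][1], data["main_tensor"][2]]
                        )[_cond_mask(data, condition)],
                        test_labels=_cond_labels(data, condition),
                        participant=p,
                        roi=roi,
                    )
                    for res in results:
                        res.condition = condition
                        decode_rows.append(_row(res))

    # ----- group statistics ------------------------------------------------
    if an["behavioral"] and len(behavioral):
        beh = stats.behavioral_tests(
            behavioral[["accuracy_informative", "accuracy_uninformative"]].to_numpy(),
            behavioral[["rt_informative", "rt_uninformative"]].to_numpy(),
        )
        for measure, res in beh.items():
            stats_rows.append(
                {
                    "roi": "behavior",
                    "regime": "behavioral",
                    "test": f"{measure}_condition_diff",
                    "condition": "informative_vs_uninformative",
                    "statistic": res["t"],
                    "p": res["p"],
                    "n_iter": 0,
                    "tail": "two_sided",
                    "seed": config.seed_for("behavior"),
                    "tier": stats.significance_tier(res["p"]),
                }
            )

    for (roi, regime, condition), sets_by_p in sorted(
        registry.items(), key=lambda kv: str(kv[0])
    ):
        accs = np.array([acc_registry[(roi, regime, condition)][p] for p in participants])
        seed = config.seed_for("perm_above", _crc(roi), _crc(regime), _crc(condition))

        def null_fn(rng, _sets=sets_by_p):
            return [
                decoding.pair_sets_accuracy(_sets[p], rng=rng, shuffle_train=True)[0]
                for p in participants
            ]

        outcome = stats.perm_above_chance(accs, null_fn, n_iter=config.n_iter, seed=seed)
        stats_rows.append(_stat_row(roi, regime, "above_chance", condition, outcome))

    for (roi, regime), _ in sorted(
        {(roi, regime): None for roi, regime, _ in acc_registry}.items(), key=str
    ):
        key1, key2 = (roi, regime, CONDITIONS[0]), (roi, regime, CONDITIONS[1])
        if key1 not in acc_registry or key2 not in acc_registry:
            continue
        a1 = np.array([acc_registry[key1][p] for p in participants])
        a2 = np.array([acc_registry[key2][p] for p in participants])
        outcome = stats.perm_condition_diff(
            a1, a2, n_iter=config.iter_signflip,
            seed=config.seed_for("perm_diff", _crc(roi), _crc(regime)),
        )
        stats_rows.append(
            _stat_row(roi, regime, "condition_diff", "informative_vs_uninformative", outcome)
        )

    for regime in sorted({regime for _, regime, _ in acc_registry}):
        rois_here = sorted({roi for roi, reg, _ in acc_registry if reg == regime})
        if len(rois_here) < 2:
            continue
        table = np.stack(
            [
                np.stack(
                    [
                        [acc_registry[(roi, regime, cond)][p] for cond in CONDITIONS]
                        for roi in rois_here
                    ]
                )
                for p in participants
            ]
        )  # (n, roi, cond)
        outcome = stats.perm_rm_anova(
            table, n_iter=config.iter_signflip,
            seed=config.seed_for("perm_anova", _crc(regime)),
        )
        anova_rows.append(
            {
                "regime": regime,
                "F_roi": outcome.F_roi,
                "F_condition": outcome.F_condition,
                "F_interaction": outcome.F_interaction,
                "df_roi": str(outcome.df["roi"]),
                "df_condition": str(outcome.df["condition"]),
                "df_interaction": str(outcome.df["interaction"]),
                "p_roi": outcome.p_roi,
                "p_condition": outcome.p_condition,
                "p_interaction": outcome.p_interaction,
                "n_iter": config.n_iter,
                "seed": outcome.seed,
            }
        )

    if an["univariate"]:
        for roi, mats in hrf_group.items():
            stack = np.stack(mats)  # (n, cond, lag)
            outcomes = stats.timepoint_condition_tests(
                stack[:, 0, :], stack[:, 1, :], n_iter=config.iter_signflip,
                seed=config.seed_for("perm_hrf", _crc(roi)),
            )
            for lag, outcome in enumerate(outcomes):
                row = _stat_row(roi, "univariate_hrf", "condition_diff",
                                "informative_vs_uninformative", outcome)
                row["timepoint"] = lag
                stats_rows.append(row)

    bundle = ResultsBundle(
        behavioral=behavioral,
        hrf=pd.concat(hrf_rows, ignore_index=True) if hrf_rows else pd.DataFrame(),
        decoding=pd.DataFrame(decode_rows),
        stats=pd.DataFrame(stats_rows),
        anova=pd.DataFrame(anova_rows),
        manifest={
            "config": config.to_dict(),
            "rois": {roi: spec["profile"] for roi, spec in config.rois.items()},
            "master_seed": config.master_seed,
            "elapsed_s": round(time.time() - t0, 2),
        },
    )
    if config.out_dir:
        bundle.save(config.out_dir)
    return bundle


def _cond_mask(data, condition):
    labels = pd.concat([data["d_main"][1], data["d_main"][2]], ignore_index=True)
    return (labels["condition"] == condition).to_numpy()


def _cond_labels(data, condition):
    labels = pd.concat([data["d_main"][1], data["d_main"][2]], ignore_index=True)
    return labels[labels["condition"] == condition].reset_index(drop=True)


def _record(decode_rows, registry, acc_registry, sets, roi, regime, condition, p):
    acc, pair_accs, excluded, n_test = decoding.pair_sets_accuracy(sets)
    decode_rows.append(
        {
            "participant": p,
            "roi": roi,
            "condition": condition,
            "regime": regime,
            "timepoint": None,
            "accuracy": acc,
            "n_test": n_test,
        }
    )
    registry.setdefault((roi, regime, condition), {})[p] = sets
    acc_registry.setdefault((roi, regime, condition), {})[p] = acc


def _row(res) -> dict:
    return {
        "participant": res.participant,
        "roi": res.roi,
        "condition": res.condition,
        "regime": res.regime,
        "timepoint": res.timepoint_tr,
        "accuracy": res.accuracy,
        "n_test": res.n_test,
    }


def _stat_row(roi, regime, test, condition, outcome) -> dict:
    return {
        "roi": roi,
        "regime": regime,
        "test": test,
        "condition": condition,
        "statistic": outcome.observed_stat,
        "p": outcome.p_value,
        "n_iter": outcome.n_iter,
        "tail": outcome.tail,
        "seed": outcome.seed,
        "tier": stats.significance_tier(outcome.p_value),
    }


# ---------------------------------------------------------------------------
# qualitative pattern check


def qualitative_pattern_check(
    bundle: ResultsBundle,
    alpha: float = 0.05,
    alpha_chance: float = 0.01,
) -> dict:
    """Check the simulated experiment for the expected qualitative pattern.

    (a) visual-profile ROIs decode remembered position better in the
        uninformative than the informative condition (sign-flip p <= alpha
        with the group means ordered uninformative > informative);
    (b) sensorimotor-profile ROIs decode the upcoming action above chance
        in the informative condition (permutation p <= alpha) but sit at
        chance in the uninformative condition (a one-sample t-test of the
        group accuracies against 0.5 does not reject at ``alpha_chance``);
    (c) spatial decoding in sensorimotor-profile ROIs is at chance (same
        t-test criterion, conditions pooled).

    Returns a report dict with per-check pass/fail details and an
    ``all_passed`` flag.
    """
    profiles = bundle.manifest["rois"]
    dec = bundle.decoding
    st = bundle.stats
    report = {"checks": {}, "all_passed": True}

    def add(name, passed, detail):
        report["checks"][name] = {"passed": bool(passed), **detail}
        report["all_passed"] &= bool(passed)

    visual_rois = [r for r, prof in profiles.items() if prof == "visual_like"]
    motor_rois = [r for r, prof in profiles.items() if prof == "sensorimotor_like"]

    for roi in visual_rois:
        sub = st[(st.roi == roi) & (st.regime == "train_mapping") & (st.test == "condition_diff")]
        means = {
            cond: dec[
                (dec.roi == roi) & (dec.regime == "train_mapping") & (dec.condition == cond)
            ].accuracy.mean()
            for cond in CONDITIONS
        }
        p = float(sub.p.iloc[0]) if len(sub) else np.nan
        ok = (
            len(sub) > 0
            and p <= alpha
            and means["uninformative"] > means["informative"]
        )
        add(f"spatial_condition_difference[{roi}]", ok, {"p": p, "means": means})

    for roi in motor_rois:
        sub_inf = st[
            (st.roi == roi)
            & (st.regime == "cross_session_action")
            & (st.test == "above_chance")
            & (st.condition == "informative")
        ]
        p_inf = float(sub_inf.p.iloc[0]) if len(sub_inf) else np.nan
        uninf = dec[
            (dec.roi == roi)
            & (dec.regime == "cross_session_action")
            & (dec.condition == "uninformative")
        ].accuracy.to_numpy()
        ok_uninf, detail_uninf = _at_chance(uninf, alpha_chance)
        ok = len(sub_inf) > 0 and p_inf <= alpha and ok_uninf
        add(
            f"action_informative_only[{roi}]",
            ok,
            {"p_informative": p_inf, "uninformative_chance": detail_uninf},
        )

        spatial = dec[(dec.roi == roi) & (dec.regime == "train_mapping")]
        pooled = spatial.groupby("participant").accuracy.mean().to_numpy()
        ok_sp, detail_sp = _at_chance(pooled, alpha_chance)
        add(f"spatial_at_chance[{roi}]", ok_sp, detail_sp)

    return report


def _at_chance(accs, alpha_chance):
    """'At chance' criterion: one-sample t vs 0.5 fails to reject."""
    from scipy import stats as sp_stats

    accs = np.asarray(accs, float)
    if accs.size < 2:
        return False, {"error": "too few accuracies"}
    if np.all(accs == accs[0]):
        p = 1.0 if accs[0] == 0.5 else 0.0
    else:
        p = float(sp_stats.ttest_1samp(accs, 0.5).pvalue)
    return bool(p > alpha_chance), {
        "mean": float(accs.mean()),
        "t_test_p": p,
        "alpha_chance": alpha_chance,
    }
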