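# wmdecode

Synthetic-data pipeline for studying **flexible spatial- versus
motor-based codes in visual working memory** with fMRI multivariate
pattern analysis. The package generates fully counterbalanced
event-related task designs, simulates voxelwise BOLD time series whose
information content is known exactly, and runs the complete analysis
chain used to characterize how delay-period memory codes depend on
whether the upcoming motor response can be planned in advance.

It is aimed at researchers who want a tested, ground-truth-validated
re-implementation of this analysis style — FIR deconvolution,
circular-bin decoding with cross-task generalization, and
permutation-based group inference — that can be exercised end to end
without any scanner data.

## The model and the analyses

**Generative model.** Voxel $v$ responds to a remembered angle
$\theta$ with von Mises tuning

$$a_v(\theta) = b + g_c \, \exp\{\kappa_v(\cos(\theta - \mu_v) - 1)\}
  \; + \; w_v \, s(\text{finger}, \text{hemisphere}_v),$$

where $g_c$ is a condition-dependent gain (active during the 3.5–16.5 s
delay window), $w_v$ a signed action weight ($s = +1$ for presses
contralateral to the voxel's hemisphere, active during the delay only
when the response is pre-plannable), and $b$ a baseline. Event boxcars
are convolved with a double-gamma HRF (TR = 0.8 s) and summed with
AR(1) Gaussian noise.

**Decoder.** Angles are binned into eight 45° bins; four binary
classifiers discriminate bins 180° apart using the normalized Euclidean
distance (nearest class mean after per-voxel pooled-variance
normalization),

$$\hat{c}(x) = \arg\min_c \sum_v (x_v - \bar{x}_{cv})^2 / \sigma_v^2,$$

and the reported accuracy is the unweighted mean over the four
classifiers (chance = 50%). Decoders train on an independent mapping
task or localizer and test on main-task delay patterns, or
cross-validate within condition / across sessions.

**Inference.** Group tests use a signed rank statistic
$\sum_i \mathrm{sign}(d_i)\,\mathrm{rank}(|d_i|)$ with permutation
nulls: label-shuffled retraining for above-chance tests, Bernoulli
condition swaps for paired differences, and within-participant cell
shuffles for a two-way repeated-measures ANOVA (ROI × condition).

## Worked example

```python
from wmdecode.pipeline import ExperimentConfig, run_experiment, qualitative_pattern_check

cfg = ExperimentConfig(
    n_participants=6,
    rois={
        "V1_like":   {"profile": "visual_like",       "n_voxels": 50},
        "S1M1_like": {"profile": "sensorimotor_like", "n_voxels": 50},
    },
    analyses={"behavioral": True, "spatial": True, "action": True,
              "univariate": False, "disk": False},
    n_iter=200, n_iter_signflip=1000, master_seed=1,
)
bundle = run_experiment(cfg)
print(bundle.decoding.groupby(["roi", "regime", "condition"]).accuracy.agg(["mean", "sem"]).round(3))
print(qualitative_pattern_check(bundle)["all_passed"])
```

Output (seconds of runtime):

```
                                               mean    sem
roi       regime               condition
S1M1_like cross_session_action informative    0.959  0.006
                               uninformative  0.468  0.021
          train_mapping        informative    0.494  0.014
                               uninformative  0.504  0.007
V1_like   cross_session_action informative    0.510  0.020
                               uninformative  0.488  0.011
          train_mapping        informative    0.772  0.010
                               uninformative  0.890  0.004
True
```

Reading the table: the visual-profile ROI decodes the remembered angle
well above the 50% chance level, and better when the response could not
be pre-planned (0.890 uninformative vs 0.772 informative; sign-flip
permutation p = 0.042 in `bundle.stats`) — the signature of a
sensory-like spatial code that weakens when an action plan can replace
it. The sensorimotor-profile ROI shows the complementary pattern: the
upcoming finger press is decodable across sessions only in the
informative condition (0.959 vs 0.468; above-chance permutation p = 0),
while its spatial decoding stays at chance. `qualitative_pattern_check`
verifies exactly this dissociation against the simulation's ground
truth.

A command-line front end mirrors the library
(`wmdecode all|simulate|decode|univariate|stats|check`, each accepting
`--config`, `--seed`, `--out`, `--n-iter`, `--quiet`).

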