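"""Desk-scale study analogues run on the synthetic generator.

These functions reproduce the study designs — electrode-subset search,
multi-band vs single-band estimation accuracy, dependability split, and
the temporal/spatial activation analysis — on a seeded synthetic cohort,
and are shared by the command line, the acceptance script and the test
suite.

Scale choices: cohorts default to four subjects recorded for 30 s at
2 kHz.  MAV envelopes vary on the 0.1 s window timescale, so feature and
target streams are subsampled (``stride`` columns, default 80, i.e. 25
samples/s) before model fitting and scoring; boosting runs at a reduced
depth/round count for these experiments.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .boosting import BoostingParams, fit_muscle_set, predict_muscle_set
from .evaluation import (
    ErrorReport,
    activation_analysis,
    compare_groups,
    dependability_analysis,
    rmse,
)
from .filterbank import (
    FilterBankSpec,
    PreprocessConfig,
    extract_distal_features,
    extract_target_envelopes,
)
from .folds import build_training_folds, crossfit_estimates
from .placement import search_placements
from .signals import MUSCLE_LABELS
from .synth import MixingModel, SynthConfig, generate_recording

#: Boosting settings for the cohort experiments (reduced from the
#: package defaults to desk scale; exposed so callers can override).
EXPERIMENT_BOOSTING = BoostingParams(n_rounds=40, shrinkage=0.3, max_depth=3)


@dataclass
class CohortMember:
    subject: str
    features_multi: np.ndarray  # (175, n_strided)
    features_single: np.ndarray  # (5, n_strided)
    targets: np.ndarray  # (6, n_strided)
    envelopes: np.ndarray  # ground truth, strided


@dataclass
class Cohort:
    members: list[CohortMember]
    stride: int
    config: SynthConfig

    def __iter__(self):
        return iter(self.members)

    def arrays(self, which: str) -> dict:
        """Per-(subject, task) matrices for the fold machinery."""
        return {(m.subject, 0): self._pick(m, which) for m in self.members}

    @staticmethod
    def _pick(member: CohortMember, which: str) -> np.ndarray:
        return {
            "multi": member.features_multi,
            "single": member.features_single,
            "targets": member.targets,
        }[which]


def _jittered_mixing(base: MixingModel, rng: np.random.Generator, sigma: float = 0.15) -> MixingModel:
    """Per-subject anatomy: lognormal jitter on crosstalk gains."""
    gains = base.gains * np.exp(sigma * rng.standard_normal(base.gains.shape))
    return replace(base, gains=gains, attenuation_hz=None)


def make_cohort(
    n_subjects: int = 4,
    config: SynthConfig | None = None,
    *,
    seed: int = 0,
    stride: int = 80,
    spec: FilterBankSpec = FilterBankSpec(),
    preprocess: PreprocessConfig = PreprocessConfig(),
) -> Cohort:
    """Generate recordings for a cohort and extract both feature sets.

    Each subject gets an independently seeded recording with jittered
    crosstalk gains (inter-subject anatomical variation).  Feature and
    target envelope streams are subsampled by ``stride`` after full-rate
    extraction.
    """
    config = config or SynthConfig()
    ss = np.random.SeedSequence(seed)
    members = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        s_mix, s_rec = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2))
        cfg = replace(config, mixing=_jittered_mixing(config.mixing, np.random.default_rng(s_mix)))
        rec = generate_recording(cfg, seed=s_rec)
        feats_multi = extract_distal_features(rec.distal, spec, preprocess=preprocess)
        feats_single = extract_distal_features(
            rec.distal, FilterBankSpec.single_band(spec.full_band), preprocess=preprocess
        )
        targets = extract_target_envelopes(rec.target, preprocess=preprocess)
        members.append(
            CohortMember(
                subject=chr(ord("A") + i),
                features_multi=feats_multi.values[:, ::stride].copy(),
                features_single=feats_single.values[:, ::stride].copy(),
                targets=targets.values[:, ::stride].copy(),
                envelopes=rec.envelopes[:, ::stride].copy(),
            )
        )
    return Cohort(members, stride, config)


def _gbt_fit_predict(params: BoostingParams, seed: int | None):
    def fit_predict(X_tr, L_tr, X_te):
        models = fit_muscle_set(X_tr.T, L_tr, params, seed=seed)
        return predict_muscle_set(models, X_te.T)

    return fit_predict


def estimation_accuracy_experiment(
    cohort: Cohort,
    params: BoostingParams = EXPERIMENT_BOOSTING,
    *,
    seed: int = 0,
) -> tuple[ErrorReport, dict]:
    """Multi-band pipeline vs single-band baseline, target-subject pooling.

    For each subject, boosted models train on half of that subject's
    record pooled with every other subject's full record, estimate the
    held-out half (with the swap), and the concatenated estimates are
    scored by per-muscle RMSE against the measured envelopes.  Returns an
    :class:`ErrorReport` whose table has one row per (subject, muscle,
    pipeline), with the Mann-Whitney comparison of the two pipelines'
    RMSE populations, plus the stitched estimates for further analysis.
    """
    targets = cohort.arrays("targets")
    lengths = {k: v.shape[1] for k, v in targets.items()}
    rows = []
    estimates: dict = {}
    for pipeline, which in (("proposed", "multi"), ("baseline", "single")):
        feats = cohort.arrays(which)
        estimates[pipeline] = {}
        for member in cohort:
            folds = build_training_folds(lengths, member.subject)
            est = crossfit_estimates(folds, feats, targets, _gbt_fit_predict(params, seed))
            key = (member.subject, 0)
            estimates[pipeline][key] = est[key]
            for i, label in enumerate(MUSCLE_LABELS):
                rows.append(
                    {
                        "subject": member.subject,
                        "task": 0,
                        "muscle": label,
                        "pipeline": pipeline,
                        "rmse": rmse(targets[key][i], est[key][i]),
                    }
                )
    table = pd.DataFrame(rows)
    stat, p = compare_groups(
        table.loc[table.pipeline == "proposed", "rmse"],
        table.loc[table.pipeline == "baseline", "rmse"],
    )
    return ErrorReport(table, stat, p), estimates


def dependability_experiment(
    cohort: Cohort,
    params: BoostingParams = EXPERIMENT_BOOSTING,
    *,
    seed: int = 0,
) -> ErrorReport:
    """First-half vs second-half models on the (stationary) cohort."""
    return dependability_analysis(
        cohort.arrays("multi"),
        cohort.arrays("targets"),
        _gbt_fit_predict(params, seed),
        muscle_labels=list(MUSCLE_LABELS),
    )


def activation_accuracy_table(
    measured: dict, estimated: dict, threshold_fraction: float = 0.20
) -> pd.DataFrame:
    """Temporal/spatial activation accuracy per (subject, muscle)."""
    rows = []
    for key, meas in measured.items():
        est = estimated[key]
        for i, label in enumerate(MUSCLE_LABELS):
            res = activation_analysis(meas[i], est[i], threshold_fraction)
            rows.append(
                {
                    "subject": key[0],
                    "muscle": label,
                    "temporal_accuracy": res.temporal_accuracy,
                    "spatial_accuracy": res.spatial_accuracy,
                }
            )
    return pd.DataFrame(rows)


def placement_experiment(cohort: Cohort):
    """Exhaustive electrode-subset search on single-band MAV features."""
    features = {m.subject: m.features_single for m in cohort}
    targets = {m.subject: m.targets for m in cohort}
    return search_placements(features, targets)
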