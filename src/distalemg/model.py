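"""Model/Results interface for the distal-EMG envelope estimator.

``MuscleActivityModel`` holds one calibration session — the distal
feature matrix A(k) and measured target envelopes L(k) — plus the
boosting configuration; ``fit()`` trains the six per-muscle boosted
ensembles and returns a ``MuscleActivityResults`` carrying the models,
in-sample diagnostics and a ``summary()`` table.  Prediction on new
distal recordings goes through the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosting import (
    BoostedEnsemble,
    BoostingParams,
    fit_muscle_set,
    load_ensembles,
    predict_muscle_set,
    save_ensembles,
)
from .evaluation import activation_analysis, rmse
from .filterbank import (
    FeatureMatrix,
    FilterBankSpec,
    PreprocessConfig,
    extract_distal_features,
    extract_target_envelopes,
)
from .signals import MUSCLE_LABELS, ParameterError, SignalRecord


class MuscleActivityModel:
    """Envelope-estimation model for one user's calibration data.

    Parameters
    ----------
    features : (n_features, n_samples) array or FeatureMatrix
        Distal feature streams A(k).
    targets : (6, n_samples) array
        Measured target-muscle MAV envelopes L(k).
    params : BoostingParams
        Gradient-boosting hyperparameters.
    """

    def __init__(
        self,
        features,
        targets,
        params: BoostingParams = BoostingParams(),
        *,
        feature_names: list[str] | None = None,
        muscle_labels=MUSCLE_LABELS,
    ) -> None:
        if isinstance(features, FeatureMatrix):
            feature_names = features.row_labels
            features = features.values
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.targets = np.atleast_2d(np.asarray(targets, dtype=float))
        if self.features.shape[1] != self.targets.shape[1]:
            raise ParameterError("features and targets must cover the same samples")
        self.params = params
        self.feature_names = feature_names
        self.muscle_labels = list(muscle_labels)[: self.targets.shape[0]]
        self._spec: FilterBankSpec | None = None
        self._preprocess: PreprocessConfig | None = None

    @classmethod
    def from_recordings(
        cls,
        distal: SignalRecord,
        target: SignalRecord,
        *,
        spec: FilterBankSpec = FilterBankSpec(),
        preprocess: PreprocessConfig = PreprocessConfig(),
        params: BoostingParams = BoostingParams(),
        stride: int = 1,
    ) -> "MuscleActivityModel":
        """Build the design from raw calibration recordings.

        Runs the full preprocessing (notch, filter bank, MAV) on both
        records; ``stride`` subsamples the envelope streams for faster
        fitting.
        """
        feats = extract_distal_features(distal, spec, preprocess=preprocess)
        targ = extract_target_envelopes(target, preprocess=preprocess)
        model = cls(
            feats.values[:, ::stride],
            targ.values[:, ::stride],
            params,
            feature_names=feats.row_labels,
            muscle_labels=targ.labels,
        )
        model._spec = spec
        model._preprocess = preprocess
        return model

    def fit(self, seed: int | None = None) -> "MuscleActivityResults":
        ensembles = fit_muscle_set(
            self.features.T,
            self.targets,
            self.params,
            seed=seed,
            target_labels=self.muscle_labels,
            feature_names=self.feature_names,
        )
        return MuscleActivityResults(self, ensembles)


@dataclass
class MuscleActivityResults:
    """Fitted per-muscle ensembles with diagnostics."""

    model: MuscleActivityModel
    ensembles: list[BoostedEnsemble]

    @property
    def fittedvalues(self) -> np.ndarray:
        """In-sample estimated envelopes (6, n)."""
        return predict_muscle_set(self.ensembles, self.model.features.T)

    def predict(self, features=None, distal: SignalRecord | None = None) -> np.ndarray:
        """Estimate envelopes for new feature columns or a raw distal record."""
        if distal is not None:
            if self.model._spec is None:
                raise ParameterError(
                    "model was not built from recordings; pass features instead"
                )
            fm = extract_distal_features(
                distal, self.model._spec, preprocess=self.model._preprocess
            )
            features = fm.values
        if features is None:
            return self.fittedvalues
        if isinstance(features, FeatureMatrix):
            features = features.values
        return predict_muscle_set(self.ensembles, np.atleast_2d(features).T)

    def diagnostics(self) -> pd.DataFrame:
        """Per-muscle in-sample RMSE, correlation and activation accuracy."""
        fitted = self.fittedvalues
        rows = []
        for i, (label, ens) in enumerate(zip(self.model.muscle_labels, self.ensembles)):
            meas = self.model.targets[i]
            act = activation_analysis(meas, fitted[i])
            rows.append(
                {
                    "muscle": label,
                    "rmse": rmse(meas, fitted[i]),
                    "correlation": float(np.corrcoef(meas, fitted[i])[0, 1]),
                    "temporal_accuracy": act.temporal_accuracy,
                    "spatial_accuracy": act.spatial_accuracy,
                    "trees": ens.n_rounds,
                    "final_train_loss": ens.train_losses[-1],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        diag = self.diagnostics()
        p = self.model.params
        lines = [
            "Distal-EMG muscle activity estimation".center(70),
            "=" * 70,
            f"Samples: {self.model.targets.shape[1]}   Features: {self.model.features.shape[0]}   "
            f"Muscles: {len(self.ensembles)}",
            f"Boosting: H={p.n_rounds}  shrinkage={p.shrinkage}  max_depth={p.max_depth}  "
            f"loss={p.loss}",
            "-" * 70,
            diag.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
                columns=[
                    "muscle",
                    "rmse",
                    "correlation",
                    "temporal_accuracy",
                    "spatial_accuracy",
                ],
            ),
            "=" * 70,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        save_ensembles(self.ensembles, path)

    @classmethod
    def load(cls, path, model: MuscleActivityModel | None = None) -> "MuscleActivityResults":
        ensembles = load_ensembles(path)
        if model is None:
            # results detached from a design: prediction on explicit features only
            n_feat = len(ensembles[0].feature_names or [])
            model = MuscleActivityModel(
                np.zeros((max(n_feat, 1), 0)),
                np.zeros((len(ensembles), 0)),
                ensembles[0].params,
                feature_names=ensembles[0].feature_names,
                muscle_labels=[e.target_label or f"L{i+1}" for i, e in enumerate(ensembles)],
            )
        return cls(model, ensembles)
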