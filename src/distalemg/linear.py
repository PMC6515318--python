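"""Affine mixing regression L(k) = M A(k) + b used for placement design.

M is (n_targets, n_features) — 6 x 5 in the electrode-placement
experiment, where the features are the single-band MAVs of the candidate
distal channels — and b is a per-target intercept.  Fitting is ordinary
least squares over all time steps jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signals import ParameterError


@dataclass
class LinearMixModel:
    M: np.ndarray  # (n_targets, n_features)
    b: np.ndarray  # (n_targets,)

    def predict(self, A: np.ndarray) -> np.ndarray:
        """Apply the affine map per sample: A is (n_features, n_samples)."""
        A = np.atleast_2d(np.asarray(A, dtype=float))
        if A.shape[0] != self.M.shape[1]:
            raise ParameterError(
                f"feature dimension {A.shape[0]} does not match model ({self.M.shape[1]})"
            )
        return self.M @ A + self.b[:, None]


def fit_linear(A: np.ndarray, L: np.ndarray) -> LinearMixModel:
    """Least-squares fit of M, b from features A (f, n) and targets L (t, n).

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning (lstsq behaviour).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if A.shape[1] != L.shape[1]:
        raise ParameterError("A and L must cover the same samples")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(L))):
        raise ParameterError("nonfinite values in regression inputs")
    n = A.shape[1]
    design = np.hstack([A.T, np.ones((n, 1))])  # (n, f+1)
    coef, _, rank, _ = np.linalg.lstsq(design, L.T, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design; returning minimum-norm solution", stacklevel=2)
    return LinearMixModel(M=coef[:-1].T.copy(), b=coef[-1].copy())


def predict_linear(model: LinearMixModel, A: np.ndarray) -> np.ndarray:
    return model.predict(A)
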