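"""Electrode-position design: exhaustive subset search over ankle channels.

For every nonempty subset of the candidate positions (A1..A5), an affine
mixing model is fitted from the subset's single-band MAV features to the
six target-muscle envelopes under the split-half-with-swap protocol;
measured and stitched held-out estimates are scored by per-muscle
Pearson correlation.  Subsets are ranked by the median of their
correlations (mean and min are available as alternatives) and the best
combination is selected — ties break toward fewer electrodes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .folds import crossfit_estimates, split_half_folds
from .linear import fit_linear
from .signals import DISTAL_LABELS, MUSCLE_LABELS, ParameterError


def enumerate_combinations(positions=DISTAL_LABELS, max_size: int | None = None, *, min_size: int = 1):
    """Unordered subsets of sizes ``min_size..max_size``, in deterministic order.

    Ordered by size, then lexicographically; A1..A5 yield 5 singletons
    (sizes 1..1), 10 pairs (2..2) and 31 subsets in total (1..5).
    """
    positions = list(positions)
    if not positions:
        raise ParameterError("no candidate positions")
    if max_size is None:
        max_size = len(positions)
    if max_size > len(positions):
        raise ParameterError("max_size exceeds the number of positions")
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    out = []
    for size in range(min_size, max_size + 1):
        out.extend(tuple(c) for c in itertools.combinations(positions, size))
    return out


@dataclass
class CombinationScore:
    """Correlation scorecard of one electrode subset."""

    subset: tuple[str, ...]
    correlations: np.ndarray  # (n_series, 6): one row per subject (or 1)
    p_values: np.ndarray
    ranking: str = "median"

    def __post_init__(self) -> None:
        self.correlations = np.atleast_2d(np.asarray(self.correlations, dtype=float))
        self.p_values = np.atleast_2d(np.asarray(self.p_values, dtype=float))

    @property
    def per_muscle(self) -> np.ndarray:
        """Median correlation per muscle across subjects."""
        return np.nanmedian(self.correlations, axis=0)

    @property
    def statistic(self) -> float:
        vals = self.correlations[np.isfinite(self.correlations)]
        if vals.size == 0:
            return -np.inf
        if self.ranking == "median":
            return float(np.median(vals))
        if self.ranking == "mean":
            return float(np.mean(vals))
        if self.ranking == "min":
            return float(np.min(vals))
        raise ParameterError(f"unknown ranking statistic {self.ranking!r}")

    # kept for readability at call sites
    @property
    def median_correlation(self) -> float:
        return float(np.nanmedian(self.correlations))


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def score_combination(
    subset,
    features: dict,
    targets: dict,
    *,
    ranking: str = "median",
    fit_predict=None,
) -> CombinationScore:
    """Fit the subset's linear model per subject (split halves with swap).

    ``features`` maps subject -> (5, n) single-band MAV matrix with rows
    ordered A1..A5; ``targets`` maps subject -> (6, n) measured envelope
    matrix.  Correlations are computed per subject per muscle on the
    concatenated held-out estimates; constant series yield NaN (excluded
    from the ranking statistic) with a warning.
    """
    subset = tuple(subset)
    if not subset:
        raise ParameterError("empty electrode subset")
    rows = [DISTAL_LABELS.index(ch) for ch in subset]
    if fit_predict is None:
        def fit_predict(X_tr, L_tr, X_te):
            return fit_linear(X_tr, L_tr).predict(X_te)
    corrs, pvals = [], []
    for subject in features:
        feats = {(subject, 0): np.atleast_2d(features[subject])[rows]}
        targ = {(subject, 0): np.atleast_2d(targets[subject])}
        folds = split_half_folds({k: v.shape[1] for k, v in targ.items()})
        est = crossfit_estimates(folds, feats, targ, fit_predict)[(subject, 0)]
        meas = targ[(subject, 0)]
        rp = [_pearson_with_p(meas[i], est[i]) for i in range(meas.shape[0])]
        corrs.append([r for r, _ in rp])
        pvals.append([p for _, p in rp])
    return CombinationScore(subset, np.array(corrs), np.array(pvals), ranking=ranking)


def select_best(scores: list[CombinationScore]) -> CombinationScore:
    """Argmax by the ranking statistic; ties -> smaller subset, then lexicographic."""
    if not scores:
        raise ParameterError("no combination scores to select from")
    return min(scores, key=lambda s: (-s.statistic, len(s.subset), s.subset))


def search_placements(
    features: dict,
    targets: dict,
    *,
    max_size: int | None = None,
    ranking: str = "median",
) -> tuple[pd.DataFrame, CombinationScore]:
    """Score every subset and return (report table, best combination)."""
    scores = [
        score_combination(sub, features, targets, ranking=ranking)
        for sub in enumerate_combinations(max_size=max_size)
    ]
    rows = []
    for s in scores:
        row = {"subset": "-".join(s.subset), "size": len(s.subset), "statistic": s.statistic}
        for i, label in enumerate(MUSCLE_LABELS):
            row[f"r_{label}"] = s.per_muscle[i]
            row[f"p_{label}"] = float(np.nanmedian(s.p_values[:, i]))
        rows.append(row)
    return pd.DataFrame(rows), select_best(scores)
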