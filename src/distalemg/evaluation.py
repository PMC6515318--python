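"""Accuracy metrics and activity analyses for estimated envelopes.

Covers RMSE, the threshold-based temporal/spatial activation accuracy,
gait-cycle extraction with dual (amplitude + time) normalization and
cycle averaging, the dependability split-half comparison, and the
Mann-Whitney U group test.

Activation accuracy: per trace, the threshold is a fraction (default
20%) of the amplitude range above the minimum.  Tm and Te are the total
supra-threshold durations of the measured and estimated envelope; Tc the
duration where both are supra-threshold; Vm and Ve sum each trace's
per-interval maxima; Vc sums, per overlap section, the smaller of the
two section maxima (clipped so Vc <= min(Vm, Ve)).  Then

    temporal accuracy = Tc / (Tm + Te - Tc)
    spatial accuracy  = Vc / (Vm + Ve - Vc)

both in [0, 1] with 1 exactly when estimate and measurement agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signals import ParameterError


def rmse(measured, estimated) -> float:
    """Root mean squared error between two equal-length series."""
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(estimated, dtype=float)
    if y.shape != yhat.shape:
        raise ParameterError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ParameterError("empty series")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _threshold(trace: np.ndarray, fraction: float) -> float:
    return float(trace.min() + fraction * np.ptp(trace))


@dataclass
class ActivationAnalysisResult:
    threshold_fraction: float
    threshold_measured: float
    threshold_estimated: float
    intervals_measured: list[tuple[int, int]]
    intervals_estimated: list[tuple[int, int]]
    Tm: int
    Te: int
    Tc: int
    Vm: float
    Ve: float
    Vc: float
    temporal_accuracy: float
    spatial_accuracy: float


def activation_analysis(
    measured, estimated, threshold_fraction: float = 0.20
) -> ActivationAnalysisResult:
    """Threshold-based ON/OFF comparison of measured vs estimated envelopes.

    A flat trace (max == min) has no active intervals; if either trace is
    flat the corresponding accuracy degenerates to 0 with a warning.
    """
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(estimated, dtype=float)
    if y.shape != yhat.shape:
        raise ParameterError("measured and estimated must have equal length")
    if not 0 < threshold_fraction < 1:
        raise ParameterError("threshold_fraction must be in (0, 1)")

    def trace_stats(trace: np.ndarray):
        if np.ptp(trace) == 0:
            warnings.warn("flat trace: no active intervals", stacklevel=3)
            return _threshold(trace, threshold_fraction), np.zeros(trace.size, bool), []
        thr = _threshold(trace, threshold_fraction)
        mask = trace > thr
        return thr, mask, _runs(mask)

    thr_m, mask_m, runs_m = trace_stats(y)
    thr_e, mask_e, runs_e = trace_stats(yhat)
    Tm = int(mask_m.sum())
    Te = int(mask_e.sum())
    both = mask_m & mask_e
    Tc = int(both.sum())
    Vm = float(sum(y[a:b].max() for a, b in runs_m))
    Ve = float(sum(yhat[a:b].max() for a, b in runs_e))
    Vc = float(
        sum(min(y[a:b].max(), yhat[a:b].max()) for a, b in _runs(both))
    )
    Vc = min(Vc, Vm, Ve)  # overlapped volume cannot exceed either total
    temporal = Tc / (Tm + Te - Tc) if (Tm + Te - Tc) > 0 else 0.0
    spatial = Vc / (Vm + Ve - Vc) if (Vm + Ve - Vc) > 0 else 0.0
    return ActivationAnalysisResult(
        threshold_fraction,
        thr_m,
        thr_e,
        runs_m,
        runs_e,
        Tm,
        Te,
        Tc,
        Vm,
        Ve,
        Vc,
        temporal,
        spatial,
    )


def extract_cycles(envelope, cycle_threshold_fraction: float = 0.20) -> list[np.ndarray]:
    """Cut an envelope into gait cycles at upward threshold crossings.

    Cycles run between consecutive upward crossings of the per-trace
    threshold; the incomplete leading and trailing portions are dropped.
    A flat envelope, or one with fewer than two crossings, yields an
    empty list with a warning.
    """
    x = np.asarray(envelope, dtype=float)
    if x.size == 0:
        raise ParameterError("empty envelope")
    if np.ptp(x) == 0:
        warnings.warn("flat envelope: no cycles", stacklevel=2)
        return []
    thr = _threshold(x, cycle_threshold_fraction)
    above = x > thr
    ups = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if ups.size < 2:
        warnings.warn("fewer than one complete cycle", stacklevel=2)
        return []
    return [x[a:b] for a, b in zip(ups[:-1], ups[1:])]


def normalize_cycle(cycle, grid_points: int = 1001) -> np.ndarray:
    """Dual normalization of one cycle.

    Amplitude is mapped to 0-100 via (x - min)/(max - min) * 100; time is
    resampled by linear interpolation onto ``grid_points`` uniform points
    spanning normalized time 0-100 (default 1001 points, step 0.1).
    """
    x = np.asarray(cycle, dtype=float)
    if x.size < 2:
        raise ParameterError("cycle needs at least two samples")
    if np.ptp(x) == 0:
        raise ParameterError("constant cycle cannot be amplitude-normalized")
    t = np.linspace(0.0, 100.0, x.size)
    grid = np.linspace(0.0, 100.0, grid_points)
    y = np.interp(grid, t, x)
    # amplitude map applied on the resampled trace so the output range
    # is exactly [0, 100] for any input cycle
    return (y - y.min()) / np.ptp(y) * 100.0


@dataclass
class GaitCycleSet:
    """Normalized cycles on a common grid with their pointwise mean and sd."""

    cycles: np.ndarray  # (n_cycles, grid)
    grid: np.ndarray
    average: np.ndarray
    sd: np.ndarray


def average_cycles(normalized_cycles) -> GaitCycleSet:
    """Pointwise mean and standard deviation across normalized cycles."""
    cycles = np.atleast_2d(np.asarray(normalized_cycles, dtype=float))
    if cycles.size == 0:
        raise ParameterError("no cycles to average")
    grid = np.linspace(0.0, 100.0, cycles.shape[1])
    return GaitCycleSet(cycles, grid, cycles.mean(axis=0), cycles.std(axis=0))


def compare_groups(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank-sum test; returns (U of group a, p).

    Degenerate all-tied input returns the central U with p = 1 and a
    warning.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied: test degenerate", stacklevel=2)
        return a.size * b.size / 2.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ErrorReport:
    """Per-(subject, task, muscle) RMSE table plus a group comparison."""

    table: pd.DataFrame
    statistic: float | None = None
    p_value: float | None = None

    def median_by_muscle(self, column: str = "rmse") -> pd.Series:
        return self.table.groupby("muscle")[column].median()


def dependability_analysis(
    features: dict,
    targets: dict,
    fit_predict,
    muscle_labels=None,
) -> ErrorReport:
    """First-half vs second-half model comparison (body-movement robustness).

    For every (subject, task) record, two models are trained: one on the
    record's first half and one on its second half, each pooled with the
    full records of every other subject.  Each model is scored by RMSE on
    the complementary half, giving one paired (first, second) RMSE per
    (subject, task, muscle); the two RMSE populations are compared with
    the Mann-Whitney U test.  ``fit_predict(X_tr, L_tr, X_te) -> L_hat``.
    """
    from .folds import Segment, assemble, _halves

    if not targets:
        raise ParameterError("no recordings supplied")
    rows = []
    for key in targets:
        n = np.atleast_2d(targets[key]).shape[1]
        first, second = _halves(n)
        others = [
            Segment(k, 0, np.atleast_2d(targets[k]).shape[1])
            for k in targets
            if k[0] != key[0]
        ]
        for half_name, train_half, test_half in (
            ("first", first, second),
            ("second", second, first),
        ):
            train = [Segment(key, *train_half)] + others
            X_tr = assemble(train, features)
            L_tr = assemble(train, targets)
            X_te = assemble([Segment(key, *test_half)], features)
            L_te = assemble([Segment(key, *test_half)], targets)
            est = np.atleast_2d(fit_predict(X_tr, L_tr, X_te))
            for i in range(L_te.shape[0]):
                label = muscle_labels[i] if muscle_labels else f"L{i + 1}"
                rows.append(
                    {
                        "subject": key[0],
                        "task": key[1] if len(key) > 1 else 0,
                        "muscle": label,
                        "model_half": half_name,
                        "rmse": rmse(L_te[i], est[i]),
                    }
                )
    table = pd.DataFrame(rows)
    firsts = table.loc[table.model_half == "first", "rmse"].to_numpy()
    seconds = table.loc[table.model_half == "second", "rmse"].to_numpy()
    stat, p = compare_groups(firsts, seconds)
    return ErrorReport(table, stat, p)
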