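"""Split-half training folds for calibration experiments.

Two protocols are used:

* **split-half with swap** — every record is cut in two; models train on
  all first halves and are evaluated on all second halves, and vice
  versa, so each time step is estimated exactly once (the
  electrode-placement protocol).
* **target-subject pooling** — for one target subject and task, half of
  the target's record joins the *full* records of every other subject as
  training data; evaluation runs on the target's complementary half,
  again with the swap, and the two estimated halves are concatenated in
  temporal order (the estimation-accuracy protocol).

Folds are derived from record lengths only, so they are reproducible
without access to the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import ParameterError

Key = tuple  # (subject, task)


@dataclass(frozen=True)
class Segment:
    """A contiguous index range of one record."""

    key: tuple
    start: int
    stop: int

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class Fold:
    train: tuple[Segment, ...]
    test: Segment

    @property
    def n_train(self) -> int:
        return sum(s.length for s in self.train)


@dataclass
class TrainingFolds:
    folds: list[Fold]

    def __iter__(self):
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)


def _halves(n: int) -> tuple[tuple[int, int], tuple[int, int]]:
    mid = n // 2
    return (0, mid), (mid, n)


def split_half_folds(lengths: dict) -> TrainingFolds:
    """Every subject/task split in half; train on one half of all, test the other.

    Returns 2 x len(lengths) folds: for each record, one fold testing its
    second half (training on everyone's first halves) and the swap.
    """
    if not lengths:
        raise ParameterError("no recordings supplied")
    folds = []
    for test_key in lengths:
        for test_half in (1, 0):
            train = []
            for key, n in lengths.items():
                first, second = _halves(n)
                train.append(Segment(key, *(first if test_half == 1 else second)))
            first, second = _halves(lengths[test_key])
            test = Segment(test_key, *(second if test_half == 1 else first))
            folds.append(Fold(tuple(train), test))
    return TrainingFolds(folds)


def build_training_folds(lengths: dict, target_subject) -> TrainingFolds:
    """Target-subject pooling with swap, two folds per task of the target.

    ``lengths`` maps (subject, task) -> record length.  For each task of
    the target subject: train on one half of the target's record plus the
    whole records of all other subjects (any task), test on the other
    half; then swap.
    """
    if not lengths:
        raise ParameterError("no recordings supplied")
    target_keys = [k for k in lengths if k[0] == target_subject]
    if not target_keys:
        raise ParameterError(f"target subject {target_subject!r} has no recordings")
    folds = []
    for key in target_keys:
        first, second = _halves(lengths[key])
        others = [
            Segment(k, 0, n) for k, n in lengths.items() if k[0] != target_subject
        ]
        for train_half, test_half in ((first, second), (second, first)):
            train = [Segment(key, *train_half)] + others
            folds.append(Fold(tuple(train), Segment(key, *test_half)))
    return TrainingFolds(folds)


def assemble(segments, arrays: dict) -> np.ndarray:
    """Concatenate the given segments of per-key arrays along the sample axis."""
    parts = []
    for seg in segments:
        arr = np.atleast_2d(arrays[seg.key])
        parts.append(arr[:, seg.start : seg.stop])
    return np.concatenate(parts, axis=1)


def crossfit_estimates(
    folds: TrainingFolds,
    features: dict,
    targets: dict,
    fit_predict,
) -> dict:
    """Run every fold and stitch held-out estimates back in temporal order.

    ``fit_predict(X_train, L_train, X_test) -> L_hat`` encapsulates the
    model.  Returns {key: (n_targets, n) estimated matrix} covering every
    test index exactly once.
    """
    out = {}
    for fold in folds:
        X_tr = assemble(fold.train, features)
        L_tr = assemble(fold.train, targets)
        X_te = assemble([fold.test], features)
        est = np.atleast_2d(fit_predict(X_tr, L_tr, X_te))
        key = fold.test.key
        if key not in out:
            n = np.atleast_2d(targets[key]).shape[1]
            out[key] = np.full((est.shape[0], n), np.nan)
        out[key][:, fold.test.start : fold.test.stop] = est
    for key, arr in out.items():
        if np.any(np.isnan(arr)):
            raise ParameterError(f"folds do not cover every test index for {key}")
    return out
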