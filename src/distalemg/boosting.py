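"""Gradient tree boosting, written out from the additive-model recursion.

Per target muscle, the estimator M is grown stagewise:

    M_0(x)   = argmin_g sum_k Q(y_k, g)
    r_kh     = -dQ(y_k, M(x_k)) / dM(x_k)  evaluated at M_{h-1}
    tree_h   : regression tree fitted to the residuals r_kh,
               terminal regions R_vh
    g_vh     = argmin_g sum_{x_k in R_vh} Q(y_k, M_{h-1}(x_k) + g)
    M_h(x)   = M_{h-1}(x) + nu * sum_v g_vh * 1[x in R_vh]

For the squared-error loss used by default, M_0 is the target mean,
the residuals are y - M_{h-1}(x), and the per-leaf line search g_vh is
the leaf's mean residual.  Trees use exact greedy axis-aligned splits
maximizing variance reduction, with deterministic tie-breaking (lowest
feature index, then lowest threshold), so fits are reproducible without
randomness; a seed argument is accepted for optional row subsampling.

Training samples are feature columns of A(k) (one column per time step);
targets are the corresponding MAV samples of one muscle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .signals import ParameterError


class SquaredErrorLoss:
    """Q(y, f) = (y - f)^2 / 2: mean initializer, residual gradients, mean leaves."""

    name = "squared_error"

    def initial(self, y: np.ndarray) -> float:
        return float(np.mean(y))

    def negative_gradient(self, y: np.ndarray, pred: np.ndarray) -> np.ndarray:
        return y - pred

    def leaf_value(self, y: np.ndarray, pred: np.ndarray) -> float:
        # line search argmin_g sum (y - (pred + g))^2 -> mean residual
        return float(np.mean(y - pred))

    def __call__(self, y: np.ndarray, pred: np.ndarray) -> float:
        return float(np.mean((y - pred) ** 2) / 2.0)


LOSSES = {"squared_error": SquaredErrorLoss}


@dataclass
class RegressionTree:
    """Axis-aligned binary regression tree stored as flat node arrays.

    ``children_left[i] == -1`` marks node i as a leaf with value
    ``value[i]``; internal nodes send ``x[feature[i]] <= threshold[i]``
    left.
    """

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    value: np.ndarray

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.children_left < 0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Route each sample (rows of X) to its leaf; vectorized level walk."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.children_left[node] >= 0
        while np.any(active):
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.children_left[nd], self.children_right[nd])
            active = self.children_left[node] >= 0
        return self.value[node]

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index per sample (for the per-leaf line search)."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.children_left[node] >= 0
        while np.any(active):
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.children_left[nd], self.children_right[nd])
            active = self.children_left[node] >= 0
        return node


def presort(X: np.ndarray) -> np.ndarray:
    """Per-feature stable sort order of the rows of X, reusable across trees."""
    return np.argsort(X, axis=0, kind="stable")


def _best_split(Xs: np.ndarray, ys: np.ndarray, min_samples_leaf: int):
    """Exact greedy search over presorted columns: best split by SSE reduction.

    ``Xs``/``ys`` hold the node's feature values and targets sorted per
    feature (column).  Candidate thresholds are midpoints between
    consecutive distinct sorted values.  Ties on gain break to the lowest
    feature index, then the lowest threshold (row-major argmax over a
    feature x position grid).  Returns None when no split reduces the SSE.
    """
    n = Xs.shape[0]
    if n < 2 * min_samples_leaf:
        return None
    csum = np.cumsum(ys, axis=0)
    total = csum[-1]
    k = np.arange(1, n, dtype=float)[:, None]
    left_sum = csum[:-1]
    # SSE reduction = L^2/k + R^2/(n-k) - T^2/n (sum-of-squares term cancels)
    score = left_sum**2 / k + (total - left_sum) ** 2 / (n - k)
    valid = Xs[1:] > Xs[:-1]
    if min_samples_leaf > 1:
        pos = np.arange(1, n)[:, None]
        valid &= (pos >= min_samples_leaf) & (n - pos >= min_samples_leaf)
    score = np.where(valid, score, -np.inf)
    flat = score.T  # (features, n-1): row-major argmax = lowest feature, lowest threshold
    j = int(np.argmax(flat))
    f, pos = divmod(j, n - 1)
    if not np.isfinite(flat[f, pos]):
        return None
    ysum = float(ys[:, 0].sum())
    gain = float(flat[f, pos]) - ysum**2 / n
    if gain <= 1e-12 * max(1.0, float(np.dot(ys[:, 0], ys[:, 0]))):
        return None
    thr = 0.5 * (Xs[pos, f] + Xs[pos + 1, f])
    if thr <= Xs[pos, f]:  # degenerate midpoint from float rounding
        thr = np.nextafter(Xs[pos, f], Xs[pos + 1, f])
    return f, float(thr)


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int = 6,
    min_samples_leaf: int = 1,
    presorted: np.ndarray | None = None,
) -> RegressionTree:
    """Grow an exact-greedy variance-reduction tree to ``max_depth``.

    ``presorted`` (from :func:`presort`) lets callers amortize the sort
    across the trees of an ensemble; child nodes inherit sorted order by
    filtering, so no further sorting happens during growth.
    """
    feature, threshold, left, right, value = [], [], [], [], []
    if presorted is None:
        presorted = presort(X)

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        return len(feature) - 1

    def grow(order: np.ndarray, depth: int) -> int:
        # order: (m, F) row indices of this node, sorted per feature
        node = new_node()
        yv = y[order[:, 0]]
        if depth >= max_depth or order.shape[0] < 2 or np.ptp(yv) == 0:
            value[node] = float(np.mean(yv))
            return node
        Xs = np.take_along_axis(X, order, axis=0)
        split = _best_split(Xs, y[order], min_samples_leaf)
        if split is None:
            value[node] = float(np.mean(yv))
            return node
        f, thr = split
        go_left = X[:, f] <= thr
        m = go_left[order]  # (m, F); same True count in every column
        n_left = int(m[:, 0].sum())
        feature[node] = f
        threshold[node] = thr
        left[node] = grow(order.T[m.T].reshape(X.shape[1], n_left).T, depth + 1)
        right[node] = grow(
            order.T[~m.T].reshape(X.shape[1], order.shape[0] - n_left).T, depth + 1
        )
        return node

    grow(presorted, 0)
    return RegressionTree(
        np.asarray(feature, dtype=np.int64),
        np.asarray(threshold, dtype=float),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
        np.asarray(value, dtype=float),
    )


@dataclass
class BoostingParams:
    """Boosting hyperparameters (defaults follow common regression practice)."""

    n_rounds: int = 100  # H
    shrinkage: float = 0.3  # nu
    max_depth: int = 6
    min_samples_leaf: int = 1
    loss: str = "squared_error"
    subsample: float = 1.0  # <1 enables seeded stochastic row subsampling


@dataclass
class BoostedEnsemble:
    """One trained boosted-tree model for one target muscle."""

    initial: float
    trees: list[RegressionTree]
    params: BoostingParams
    target_label: str = ""
    feature_names: list[str] | None = None
    train_losses: list[float] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.trees)

    def predict(self, X: np.ndarray, feature_names: list[str] | None = None) -> np.ndarray:
        """Predict the envelope for feature rows X (n_samples, n_features).

        If both the ensemble and the caller carry feature names, columns
        are aligned by name, so predictions are invariant to column order.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if feature_names is not None and self.feature_names is not None:
            if sorted(feature_names) != sorted(self.feature_names):
                raise ParameterError("feature names do not match the training features")
            perm = [feature_names.index(nm) for nm in self.feature_names]
            X = X[:, perm]
        elif self.feature_names is not None and X.shape[1] != len(self.feature_names):
            raise ParameterError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        out = np.full(X.shape[0], self.initial)
        for tree in self.trees:
            out += self.params.shrinkage * tree.predict(X)
        return out


def fit_gbt(
    X: np.ndarray,
    y: np.ndarray,
    params: BoostingParams = BoostingParams(),
    *,
    seed: int | None = None,
    target_label: str = "",
    feature_names: list[str] | None = None,
) -> BoostedEnsemble:
    """Stagewise boosting fit of one muscle's envelope on feature rows X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ParameterError("X must be (n_samples, n_features) matching y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ParameterError("nonfinite values in training data")
    if params.n_rounds < 0:
        raise ParameterError("n_rounds must be >= 0")
    if y.size < 2 and params.n_rounds > 0:
        raise ParameterError("need at least 2 samples to boost")
    loss = LOSSES[params.loss]()
    rng = np.random.default_rng(seed)
    pred = np.full(y.size, loss.initial(y))
    ensemble = BoostedEnsemble(
        initial=float(pred[0]) if y.size else 0.0,
        trees=[],
        params=params,
        target_label=target_label,
        feature_names=list(feature_names) if feature_names is not None else None,
    )
    ensemble.train_losses.append(loss(y, pred))
    sorted_order = presort(X) if params.n_rounds > 0 and params.subsample >= 1.0 else None
    for _ in range(params.n_rounds):
        residual = loss.negative_gradient(y, pred)
        if params.subsample < 1.0:
            m = max(2, int(round(params.subsample * y.size)))
            rows = np.sort(rng.choice(y.size, size=m, replace=False))
            tree = fit_tree(
                X[rows], residual[rows], params.max_depth, params.min_samples_leaf
            )
        else:
            tree = fit_tree(
                X,
                residual,
                params.max_depth,
                params.min_samples_leaf,
                presorted=sorted_order,
            )
        # per-leaf line search on the full sample (exact for squared error)
        leaves = tree.apply(X)
        for leaf in np.unique(leaves):
            in_leaf = leaves == leaf
            tree.value[leaf] = loss.leaf_value(y[in_leaf], pred[in_leaf])
        pred = pred + params.shrinkage * tree.value[leaves]
        ensemble.trees.append(tree)
        ensemble.train_losses.append(loss(y, pred))
    return ensemble


def fit_muscle_set(
    X: np.ndarray,
    L: np.ndarray,
    params: BoostingParams = BoostingParams(),
    *,
    seed: int | None = None,
    target_labels: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> list[BoostedEnsemble]:
    """One independent ensemble per target-muscle row of L (6, n_samples)."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    labels = target_labels or [f"L{i + 1}" for i in range(L.shape[0])]
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(L.shape[0])]
    return [
        fit_gbt(
            X,
            L[i],
            params,
            seed=seeds[i],
            target_label=labels[i],
            feature_names=feature_names,
        )
        for i in range(L.shape[0])
    ]


def predict_muscle_set(ensembles: list[BoostedEnsemble], X: np.ndarray) -> np.ndarray:
    """Stack per-muscle predictions into an estimated envelope matrix (6, n)."""
    return np.vstack([m.predict(X) for m in ensembles])


# --- plain-text serialization (bit-exact prediction round-trip) ------------


def _tree_to_dict(tree: RegressionTree) -> dict:
    return {
        "feature": tree.feature.tolist(),
        "threshold": [v.hex() for v in tree.threshold],
        "children_left": tree.children_left.tolist(),
        "children_right": tree.children_right.tolist(),
        "value": [v.hex() for v in tree.value],
    }


def _tree_from_dict(d: dict) -> RegressionTree:
    return RegressionTree(
        np.asarray(d["feature"], dtype=np.int64),
        np.asarray([float.fromhex(v) for v in d["threshold"]], dtype=float),
        np.asarray(d["children_left"], dtype=np.int64),
        np.asarray(d["children_right"], dtype=np.int64),
        np.asarray([float.fromhex(v) for v in d["value"]], dtype=float),
    )


def save_ensembles(ensembles: list[BoostedEnsemble], path) -> None:
    """Write models to a structured text file (floats hex-encoded, lossless)."""
    payload = []
    for m in ensembles:
        payload.append(
            {
                "target_label": m.target_label,
                "initial": m.initial.hex(),
                "params": vars(m.params),
                "feature_names": m.feature_names,
                "train_losses": m.train_losses,
                "trees": [_tree_to_dict(t) for t in m.trees],
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensembles(path) -> list[BoostedEnsemble]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for d in payload:
        out.append(
            BoostedEnsemble(
                initial=float.fromhex(d["initial"]),
                trees=[_tree_from_dict(t) for t in d["trees"]],
                params=BoostingParams(**d["params"]),
                target_label=d["target_label"],
                feature_names=d["feature_names"],
                train_losses=list(d["train_losses"]),
            )
        )
    return out
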