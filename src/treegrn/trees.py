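"""Regression trees grown by variance reduction, and their randomized ensembles.

This module is the numerical heart of the package. A regression tree is grown
by recursively splitting the sample with binary tests ``x_var <= threshold``,
at each node choosing the split that maximizes the reduction of the output
variance

    I(N) = #S * Var(S) - #S_t * Var(S_t) - #S_f * Var(S_f)

where ``S`` is the set of samples reaching node ``N`` and ``S_t``/``S_f`` the
subsets for which the test is true/false. Variances are *population* variances
(divide by the count): with that convention the importances of a fully grown
tree with pure leaves telescope exactly to the total output variance
``#S * Var(S)`` of its root sample.

Two randomized ensemble variants are provided:

Random Forests (``method="RF"``)
    Each tree is grown on a bootstrap sample; at each node ``K`` candidate
    variables are drawn uniformly without replacement and, for each, the best
    threshold among midpoints of consecutive distinct sorted values is found
    exhaustively.

Extra-Trees (``method="ET"``)
    Each tree is grown on the full sample; at each node ``K`` distinct
    variables are drawn and for each a single threshold is drawn uniformly at
    random within the variable's observed range at the node; the best of these
    ``K`` random splits is kept.

The variable importance of an input is the sum of ``I`` over the nodes where
it splits, averaged over the trees of the ensemble.

Determinism: ties between equal-score splits are broken toward the lowest
variable index, then the lowest threshold; each ensemble consumes a single
seeded random stream split per-tree via ``numpy.random.SeedSequence.spawn``,
so results do not depend on scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .data import LearningSample
from .exceptions import ConfigurationError

__all__ = [
    "EnsembleConfig",
    "RegressionTree",
    "TreeEnsemble",
    "VarianceReductionForest",
    "variance_reduction",
    "fit_regression_tree",
    "fit_ensemble",
    "tree_variable_importances",
    "ensemble_variable_importances",
]

_LEAF = -1

# relative band within which two split scores count as tied; keeps split
# selection invariant to float summation order (row permutations, exactly
# rescaled inputs) while being far below any meaningful score difference
_TIE_EPS = 1e-9


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def variance_reduction(parent_outputs, left_outputs, right_outputs) -> float:
    """Total output-variance reduction of a binary split.

    Returns ``#S*Var(S) - #S_t*Var(S_t) - #S_f*Var(S_f)`` with population
    variances. The value is non-negative up to floating-point rounding for any
    true partition of the parent.

    Raises
    ------
    ConfigurationError
        If either child is empty or the children do not partition the parent.
    """
    parent = np.asarray(parent_outputs, dtype=np.float64)
    left = np.asarray(left_outputs, dtype=np.float64)
    right = np.asarray(right_outputs, dtype=np.float64)
    if left.size == 0 or right.size == 0:
        raise ConfigurationError("both children of a split must be non-empty")
    if left.size + right.size != parent.size:
        raise ConfigurationError("children must partition the parent sample")
    return float(
        parent.size * parent.var() - left.size * left.var() - right.size * right.var()
    )


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyper-parameters of a randomized tree ensemble.

    Parameters
    ----------
    method : {"RF", "ET"}
        Random Forests or Extra-Trees.
    n_trees : int
        Ensemble size ``T`` (default 1000).
    k : int or {"sqrt", "all"}
        Number of candidate variables per node. ``"sqrt"`` resolves to
        ``max(1, floor(sqrt(m)))``, ``"all"`` to ``m``.
    seed : int, SeedSequence or None
        Master seed of the ensemble's random stream.
    min_split : int
        Minimum node size to attempt a split (default 2: trees fully grown).
    bootstrap : bool
        RF only: draw each tree's sample with replacement (default True).
        Extra-Trees always use the full sample.
    """

    method: str = "RF"
    n_trees: int = 1000
    k: int | str = "sqrt"
    seed: object = None
    min_split: int = 2
    bootstrap: bool = True

    def __post_init__(self):
        method = str(self.method).upper()
        object.__setattr__(self, "method", method)
        if method not in ("RF", "ET"):
            raise ConfigurationError(f"method must be 'RF' or 'ET', got {self.method!r}")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.min_split < 2:
            raise ConfigurationError("min_split must be >= 2")
        if isinstance(self.k, str):
            if self.k not in ("sqrt", "all"):
                raise ConfigurationError(
                    f"symbolic k must be 'sqrt' or 'all', got {self.k!r}"
                )
        elif int(self.k) < 1:
            raise ConfigurationError("k must be >= 1")

    def resolve_k(self, n_inputs: int) -> int:
        """Resolve the symbolic K against the number of inputs ``m``."""
        if self.k == "sqrt":
            return max(1, int(np.floor(np.sqrt(n_inputs))))
        if self.k == "all":
            return n_inputs
        k = int(self.k)
        if not 1 <= k <= n_inputs:
            raise ConfigurationError(f"k={k} outside [1, m={n_inputs}]")
        return k


@dataclass(frozen=True)
class RegressionTree:
    """A fitted regression tree stored as flat parallel arrays.

    ``feature[i] == -1`` marks a leaf. For internal nodes, samples with
    ``x[feature] <= threshold`` go to ``children_left``. ``n_node_samples``,
    ``impurity`` (population variance of the node's outputs) and ``reduction``
    (the variance reduction achieved by the node's split; 0 at leaves) are the
    per-node metadata from which importances are computed.
    """

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    n_node_samples: np.ndarray
    impurity: np.ndarray
    value: np.ndarray
    reduction: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    @property
    def n_leaves(self) -> int:
        return int((self.feature == _LEAF).sum())

    @property
    def n_internal_nodes(self) -> int:
        return self.n_nodes - self.n_leaves

    def predict(self, X) -> np.ndarray:
        """Mean output of the leaf each row falls into."""
        X = np.asarray(X, dtype=np.float64)
        out = np.empty(X.shape[0])
        for r in range(X.shape[0]):
            node = 0
            while self.feature[node] != _LEAF:
                if X[r, self.feature[node]] <= self.threshold[node]:
                    node = self.children_left[node]
                else:
                    node = self.children_right[node]
            out[r] = self.value[node]
        return out

    def variable_importances(self, n_inputs: int) -> np.ndarray:
        """Sum of variance reductions per input variable (zeros if unused)."""
        internal = self.feature != _LEAF
        return np.bincount(
            self.feature[internal],
            weights=self.reduction[internal],
            minlength=n_inputs,
        )


class _TreeBuilder:
    """Grows one tree; collects node records into lists, frozen at the end."""

    __slots__ = (
        "X", "y", "k", "method", "min_split", "rng",
        "feature", "threshold", "left", "right", "n_samples",
        "impurity", "value", "reduction",
    )

    def __init__(self, X, y, k, method, min_split, rng):
        self.X = X
        self.y = y
        self.k = k
        self.method = method
        self.min_split = min_split
        self.rng = rng
        self.feature = []
        self.threshold = []
        self.left = []
        self.right = []
        self.n_samples = []
        self.impurity = []
        self.value = []
        self.reduction = []

    def build(self) -> RegressionTree:
        n = self.X.shape[0]
        # explicit stack: (sample indices, parent node id, is_right_child)
        stack = [(np.arange(n), -1, False)]
        while stack:
            idx, parent, is_right = stack.pop()
            node_id = self._add_node(idx, parent, is_right)
            y_node = self.y[idx]
            if idx.size < self.min_split or y_node.max() == y_node.min():
                continue  # leaf: undersized or pure
            split = self._find_split(idx, y_node)
            if split is None:
                continue  # no usable split (e.g. all drawn variables constant)
            var, thr, score = split
            self.feature[node_id] = var
            self.threshold[node_id] = thr
            self.reduction[node_id] = max(score, 0.0)
            goes_left = self.X[idx, var] <= thr
            # push right first so the left child is grown (and numbered) first
            stack.append((idx[~goes_left], node_id, True))
            stack.append((idx[goes_left], node_id, False))
        return RegressionTree(
            feature=np.asarray(self.feature, dtype=np.intp),
            threshold=np.asarray(self.threshold, dtype=np.float64),
            children_left=np.asarray(self.left, dtype=np.intp),
            children_right=np.asarray(self.right, dtype=np.intp),
            n_node_samples=np.asarray(self.n_samples, dtype=np.intp),
            impurity=np.asarray(self.impurity, dtype=np.float64),
            value=np.asarray(self.value, dtype=np.float64),
            reduction=np.asarray(self.reduction, dtype=np.float64),
        )

    def _add_node(self, idx, parent, is_right) -> int:
        node_id = len(self.feature)
        y_node = self.y[idx]
        self.feature.append(_LEAF)
        self.threshold.append(np.nan)
        self.left.append(_LEAF)
        self.right.append(_LEAF)
        self.n_samples.append(idx.size)
        self.impurity.append(float(y_node.var()))
        self.value.append(float(y_node.mean()))
        self.reduction.append(0.0)
        if parent >= 0:
            if is_right:
                self.right[parent] = node_id
            else:
                self.left[parent] = node_id
        return node_id

    def _candidates(self) -> np.ndarray:
        m = self.X.shape[1]
        if self.k >= m:
            return np.arange(m)
        # sorted ascending so that the first argmax below is the lowest index
        return np.sort(self.rng.choice(m, size=self.k, replace=False))

    def _find_split(self, idx, y_node):
        if self.method == "RF":
            return self._find_split_exhaustive(idx, y_node)
        return self._find_split_random(idx, y_node)

    def _find_split_exhaustive(self, idx, y_node):
        """Best (variable, midpoint-threshold) among K drawn variables.

        Vectorized over candidate variables: one argsort of the node's
        sub-matrix, then prefix sums give the variance reduction of every
        admissible threshold in closed form:

            I = (sum_L)^2/n_L + (sum_R)^2/n_R - (sum)^2/n
        """
        cand = self._candidates()
        Xs = self.X[idx][:, cand]                       # (n, K)
        n = idx.size
        order = np.argsort(Xs, axis=0, kind="stable")
        xs = np.take_along_axis(Xs, order, axis=0)
        ys = y_node[order]                              # (n, K)
        csum = np.cumsum(ys, axis=0)
        total = csum[-1, 0]
        n_left = np.arange(1, n, dtype=np.float64)[:, None]
        s_left = csum[:-1]
        score = (
            s_left * s_left / n_left
            + (total - s_left) * (total - s_left) / (n - n_left)
            - total * total / n
        )
        score[xs[:-1] == xs[1:]] = -np.inf              # no threshold between ties
        col_best = score.max(axis=0)
        top = col_best.max()
        if not np.isfinite(top):
            return None
        # tie-break with a tolerance so that mathematically equal splits
        # (whose float scores differ only by summation order) resolve to the
        # lowest variable index, then the lowest threshold, bit-stably
        eps = _TIE_EPS * max(1.0, abs(top))
        j = int(np.argmax(col_best >= top - eps))       # first qualifying column
        i = int(np.argmax(score[:, j] >= col_best[j] - eps))
        thr = 0.5 * (xs[i, j] + xs[i + 1, j])
        return int(cand[j]), float(thr), float(score[i, j])

    def _find_split_random(self, idx, y_node):
        """Best among K fully random (variable, uniform threshold) splits."""
        cand = self._candidates()
        Xs = self.X[idx][:, cand]
        lo = Xs.min(axis=0)
        hi = Xs.max(axis=0)
        usable = hi > lo
        if not usable.any():
            return None
        n = idx.size
        # one uniform draw per candidate keeps the stream layout fixed
        thr = lo + self.rng.random(cand.size) * (hi - lo)
        in_left = Xs <= thr
        n_left = in_left.sum(axis=0).astype(np.float64)
        s_left = y_node @ in_left
        total = y_node.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            score = (
                s_left * s_left / n_left
                + (total - s_left) * (total - s_left) / (n - n_left)
                - total * total / n
            )
        score[~usable] = -np.inf
        top = score.max()
        if not np.isfinite(top):
            return None
        eps = _TIE_EPS * max(1.0, abs(top))
        j = int(np.argmax(score >= top - eps))          # lowest index among ties
        return int(cand[j]), float(thr[j]), float(score[j])


def _grow_tree(X, y, k, method, min_split, rng) -> RegressionTree:
    return _TreeBuilder(X, y, k, method, min_split, rng).build()


class VarianceReductionForest(RegressorMixin, BaseEstimator):
    """Randomized ensemble of variance-reduction regression trees.

    A scikit-learn-compatible regressor whose ``feature_importances_`` are the
    *unnormalized* mean variance reductions per input — the quantity used to
    weight regulatory links. Trees are fully grown by default (``min_split=2``,
    no depth cap, no pruning).

    Parameters
    ----------
    method : {"RF", "ET"}, default "RF"
        Random Forests (bootstrap + exhaustive thresholds over K drawn
        variables) or Extra-Trees (full sample + K random splits).
    n_trees : int, default 1000
        Number of trees ``T``.
    k : int or {"sqrt", "all"}, default "sqrt"
        Candidate variables per node; see :meth:`EnsembleConfig.resolve_k`.
    bootstrap : bool, default True
        RF only; ignored by Extra-Trees.
    min_split : int, default 2
        Minimum node size to attempt a split.
    random_state : int, SeedSequence or None
        Master seed; the per-tree streams are spawned from it.

    Attributes
    ----------
    trees_ : list of RegressionTree
    root_samples_ : list of ndarray
        Per tree, the row indices it was grown on (a bootstrap draw for RF
        with bootstrap, ``arange(N)`` otherwise).
    feature_importances_ : ndarray of shape (n_features,)
        Mean over trees of the summed variance reductions per variable.
    """

    def __init__(
        self,
        method: str = "RF",
        n_trees: int = 1000,
        k: int | str = "sqrt",
        bootstrap: bool = True,
        min_split: int = 2,
        random_state=None,
    ):
        self.method = method
        self.n_trees = n_trees
        self.k = k
        self.bootstrap = bootstrap
        self.min_split = min_split
        self.random_state = random_state

    def _config(self) -> EnsembleConfig:
        return EnsembleConfig(
            method=self.method,
            n_trees=self.n_trees,
            k=self.k,
            seed=self.random_state,
            min_split=self.min_split,
            bootstrap=self.bootstrap,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64, ensure_min_samples=2)
        config = self._config()
        n, m = X.shape
        k = config.resolve_k(m)
        use_bootstrap = config.method == "RF" and config.bootstrap
        children = _as_seed_sequence(config.seed).spawn(config.n_trees)
        trees = []
        root_samples = []
        for child_seq in children:
            rng = np.random.default_rng(child_seq)
            if use_bootstrap:
                rows = rng.integers(0, n, size=n)
            else:
                rows = np.arange(n)
            trees.append(
                _grow_tree(X[rows], y[rows], k, config.method, config.min_split, rng)
            )
            root_samples.append(rows)
        self.n_features_in_ = m
        self.k_ = k
        self.trees_ = trees
        self.root_samples_ = root_samples
        self.feature_importances_ = np.mean(
            [t.variable_importances(m) for t in trees], axis=0
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = check_array(X, dtype=np.float64)
        pred = np.zeros(X.shape[0])
        for tree in self.trees_:
            pred += tree.predict(X)
        return pred / len(self.trees_)


@dataclass(frozen=True)
class TreeEnsemble:
    """A fitted ensemble: its config, trees, and per-tree training subsamples."""

    config: EnsembleConfig
    trees: tuple
    root_samples: tuple
    n_inputs: int

    def __post_init__(self):
        if len(self.trees) != self.config.n_trees:
            raise ConfigurationError("tree count does not match config.n_trees")


def fit_regression_tree(
    sample: LearningSample, config: EnsembleConfig, rng
) -> RegressionTree:
    """Grow a single tree on the (un-bootstrapped) learning sample."""
    if sample.n_samples < config.min_split:
        raise ConfigurationError(
            f"need at least min_split={config.min_split} samples"
        )
    k = config.resolve_k(sample.n_inputs)
    return _grow_tree(
        sample.inputs, sample.outputs, k, config.method, config.min_split, rng
    )


def fit_ensemble(sample: LearningSample, config: EnsembleConfig) -> TreeEnsemble:
    """Fit a full ensemble on a learning sample (functional facade)."""
    forest = VarianceReductionForest(
        method=config.method,
        n_trees=config.n_trees,
        k=config.k,
        bootstrap=config.bootstrap,
        min_split=config.min_split,
        random_state=config.seed,
    ).fit(sample.inputs, sample.outputs)
    return TreeEnsemble(
        config=config,
        trees=tuple(forest.trees_),
        root_samples=tuple(forest.root_samples_),
        n_inputs=sample.n_inputs,
    )


def tree_variable_importances(tree: RegressionTree, n_inputs: int) -> np.ndarray:
    """Per-variable summed variance reductions of one tree."""
    return tree.variable_importances(n_inputs)


def ensemble_variable_importances(ensemble: TreeEnsemble) -> np.ndarray:
    """Mean of the per-tree importance vectors."""
    return np.mean(
        [t.variable_importances(ensemble.n_inputs) for t in ensemble.trees], axis=0
    )
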