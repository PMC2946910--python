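"""Network inference: one tree ensemble per target gene, aggregated into a
global ranking of directed regulatory links.

The procedure decomposes the inference of a ``p``-gene network into ``p``
feature-ranking problems. For each target gene ``j`` an ensemble of regression
trees predicts ``x_j`` from the candidate regulators' expression; the
variance-reduction importance ``w_ij`` of regulator ``i`` in that model is the
weight of the putative link ``i -> j``. Because every gene is first scaled to
unit variance, the total importance a model can distribute equals the (unit)
output variance of its target, which makes weights from different per-target
models directly comparable: the global ranking is simply the union of the
per-target weight vectors sorted by weight, with no further renormalization.

Directionality transforms used in the challenge-style analyses are also provided:
:func:`symmetrize_max` (undirected evaluation), :func:`swap_directions`
(testing whether the higher of ``w_ij``/``w_ji`` carries the true direction),
and :func:`threshold_to_network` (top-``n`` edge selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import (
    ExpressionMatrix,
    build_learning_sample,
    normalize_unit_variance,
)
from .exceptions import ConfigurationError, DataIntegrityError
from .trees import EnsembleConfig, VarianceReductionForest, _as_seed_sequence

__all__ = [
    "LinkRanking",
    "PredictedNetwork",
    "GENIE3",
    "rank_regulators_for_target",
    "infer_network",
    "symmetrize_max",
    "swap_directions",
    "threshold_to_network",
]

logger = logging.getLogger("treegrn")


@dataclass(frozen=True)
class LinkRanking:
    """A weight-sorted list of directed candidate links ``regulator -> target``.

    Links are sorted by weight descending; ties are broken deterministically
    by ascending regulator index, then ascending target index (indices in the
    gene-universe order). Self-links never appear, and there is at most one
    entry per ordered gene pair.
    """

    gene_names: tuple
    regulator_idx: np.ndarray
    target_idx: np.ndarray
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        reg = np.asarray(self.regulator_idx, dtype=np.intp)
        tgt = np.asarray(self.target_idx, dtype=np.intp)
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "regulator_idx", reg)
        object.__setattr__(self, "target_idx", tgt)
        object.__setattr__(self, "weights", w)
        if not (reg.shape == tgt.shape == w.shape):
            raise DataIntegrityError("ranking arrays must have equal length")
        if (reg == tgt).any():
            raise DataIntegrityError("self-links are not allowed in a ranking")
        if (w < 0).any():
            raise DataIntegrityError("link weights must be non-negative")
        pairs = set(zip(reg.tolist(), tgt.tolist()))
        if len(pairs) != reg.size:
            raise DataIntegrityError("at most one entry per ordered gene pair")

    @classmethod
    def from_matrix(
        cls,
        weight_matrix: np.ndarray,
        gene_names,
        regulator_subset_idx=None,
        metadata: dict | None = None,
    ) -> "LinkRanking":
        """Build a ranking from a ``p x p`` matrix with ``W[i, j] = w_ij``.

        Only rows in ``regulator_subset_idx`` (default: all genes) contribute
        links; the diagonal is ignored.
        """
        W = np.asarray(weight_matrix, dtype=np.float64)
        p = len(tuple(gene_names))
        if W.shape != (p, p):
            raise DataIntegrityError("weight matrix must be p x p")
        if regulator_subset_idx is None:
            regulator_subset_idx = np.arange(p)
        reg_rows = np.asarray(sorted(set(int(i) for i in regulator_subset_idx)))
        reg, tgt = np.meshgrid(reg_rows, np.arange(p), indexing="ij")
        reg = reg.ravel()
        tgt = tgt.ravel()
        keep = reg != tgt
        reg, tgt = reg[keep], tgt[keep]
        w = W[reg, tgt]
        order = np.lexsort((tgt, reg, -w))
        return cls(
            tuple(gene_names), reg[order], tgt[order], w[order],
            metadata=dict(metadata or {}),
        )

    @classmethod
    def from_pairs(
        cls, gene_names, pairs, metadata: dict | None = None, resort: bool = True
    ) -> "LinkRanking":
        """Build from an iterable of ``(regulator_name, target_name, weight)``.

        With ``resort=False`` the given order is trusted (used when reading a
        ranking file whose order — including tie-breaks — is authoritative).
        """
        gene_names = tuple(gene_names)
        index = {g: i for i, g in enumerate(gene_names)}
        reg, tgt, w = [], [], []
        for r, t, weight in pairs:
            reg.append(index[r])
            tgt.append(index[t])
            w.append(float(weight))
        reg = np.asarray(reg, dtype=np.intp)
        tgt = np.asarray(tgt, dtype=np.intp)
        w = np.asarray(w, dtype=np.float64)
        if resort:
            order = np.lexsort((tgt, reg, -w))
            reg, tgt, w = reg[order], tgt[order], w[order]
        return cls(gene_names, reg, tgt, w, metadata=dict(metadata or {}))

    def __len__(self) -> int:
        return self.weights.size

    def __iter__(self):
        for r, t, w in zip(self.regulator_idx, self.target_idx, self.weights):
            yield self.gene_names[r], self.gene_names[t], float(w)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regulator": [self.gene_names[i] for i in self.regulator_idx],
                "target": [self.gene_names[i] for i in self.target_idx],
                "weight": self.weights,
            }
        )

    def weight_matrix(self) -> np.ndarray:
        """Dense ``p x p`` matrix of the ranking's weights (0 where absent)."""
        p = len(self.gene_names)
        W = np.zeros((p, p))
        W[self.regulator_idx, self.target_idx] = self.weights
        return W

    @property
    def regulator_set_idx(self) -> np.ndarray:
        return np.unique(self.regulator_idx)


@dataclass(frozen=True)
class PredictedNetwork:
    """A concrete directed network obtained by thresholding a ranking."""

    gene_names: tuple
    edges: frozenset  # of (regulator_name, target_name)
    n_edges: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "edges", frozenset(self.edges))
        if len(self.edges) != self.n_edges:
            raise DataIntegrityError("edge count mismatch")


class GENIE3(BaseEstimator):
    """Tree-ensemble gene regulatory network inference (GENIE3 algorithm).

    Fits one :class:`~treegrn.trees.VarianceReductionForest` per target gene
    on the unit-variance-normalized expression matrix and aggregates the
    per-target importance vectors into a global :class:`LinkRanking`.

    Parameters
    ----------
    method : {"RF", "ET"}, default "RF"
    n_trees : int, default 1000
    k : int or {"sqrt", "all"}, default "sqrt"
        ``"sqrt"`` with Random Forests reproduces the challenge-winning
        setting; ``"all"`` (bagging) was the best post-hoc setting on the
        multifactorial benchmarks.
    regulators : sequence of str or None, default None
        Candidate regulator gene names (e.g. known transcription factors).
        ``None`` lets every gene act as a regulator. Genes absent from the
        list still appear as targets.
    bootstrap : bool, default True
    min_split : int, default 2
    random_state : int or None
        Master seed; per-target ensembles use independent substreams, so
        results are independent of scheduling order.

    Attributes
    ----------
    gene_names_ : tuple of str
    regulator_idx_ : ndarray
        Indices of the candidate regulators in ``gene_names_``.
    importance_matrix_ : ndarray of shape (p, p)
        ``[i, j]`` is the weight of the link ``gene i -> gene j`` (0 on the
        diagonal and for non-candidate regulators).
    ranking_ : LinkRanking
        The weight-sorted global ranking over all candidate ordered pairs.

    Examples
    --------
    >>> from treegrn import GENIE3, ExpressionMatrix
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> x = rng.normal(size=(50, 1))
    >>> X = np.hstack([x, 0.9 * x + 0.1 * rng.normal(size=(50, 1)),
    ...                rng.normal(size=(50, 1))])
    >>> model = GENIE3(n_trees=50, random_state=0)
    >>> _ = model.fit(ExpressionMatrix.from_array(X, ["A", "B", "C"]))
    >>> top = model.ranking_.to_frame().iloc[0]
    >>> sorted([top["regulator"], top["target"]])   # the coupled pair wins
    ['A', 'B']
    """

    def __init__(
        self,
        method: str = "RF",
        n_trees: int = 1000,
        k: int | str = "sqrt",
        regulators=None,
        bootstrap: bool = True,
        min_split: int = 2,
        random_state=None,
    ):
        self.method = method
        self.n_trees = n_trees
        self.k = k
        self.regulators = regulators
        self.bootstrap = bootstrap
        self.min_split = min_split
        self.random_state = random_state

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix.from_dataframe(X)
        return ExpressionMatrix.from_array(np.asarray(X, dtype=np.float64))

    def fit(self, X, y=None):
        """Infer the ranking from an expression matrix.

        ``X`` may be an :class:`~treegrn.data.ExpressionMatrix`, a pandas
        DataFrame (columns = genes) or a plain ``N x p`` array. Raw expression
        values are expected: unit-variance normalization is applied here,
        before any tree is grown.
        """
        matrix = self._as_matrix(X)
        p = matrix.n_genes
        if p < 2:
            raise ConfigurationError("network inference needs at least 2 genes")
        if self.regulators is None:
            regulator_names = list(matrix.gene_names)
        else:
            regulator_names = list(dict.fromkeys(self.regulators))
            for name in regulator_names:
                matrix.gene_index(name)
            if not regulator_names:
                raise ConfigurationError("empty candidate-regulator list")
        reg_idx = np.asarray(sorted(matrix.gene_index(g) for g in regulator_names))

        normalized = normalize_unit_variance(matrix)
        master = _as_seed_sequence(self.random_state)
        target_seeds = master.spawn(p)
        logger.info(
            "inferring network: p=%d genes, %d candidate regulators, "
            "method=%s, T=%d, K=%s, seed=%s",
            p, reg_idx.size, self.method, self.n_trees, self.k, self.random_state,
        )

        W = np.zeros((p, p))
        for j, target in enumerate(matrix.gene_names):
            candidates = [
                g for g in regulator_names if g != target
            ]
            if not candidates:
                raise ConfigurationError(
                    f"no candidate regulators left for target {target!r}"
                )
            weights = _target_weights(
                normalized, target, candidates,
                method=self.method, n_trees=self.n_trees, k=self.k,
                bootstrap=self.bootstrap, min_split=self.min_split,
                seed=target_seeds[j],
            )
            for name, w in weights.items():
                W[matrix.gene_index(name), j] = w
            logger.info("target %d/%d (%s) done", j + 1, p, target)

        self.gene_names_ = matrix.gene_names
        self.regulator_idx_ = reg_idx
        self.importance_matrix_ = W
        self.ranking_ = LinkRanking.from_matrix(
            W,
            matrix.gene_names,
            regulator_subset_idx=reg_idx,
            metadata={
                "method": self.method,
                "n_trees": self.n_trees,
                "k": self.k,
                "bootstrap": self.bootstrap,
                "random_state": self.random_state,
                "regulators": tuple(regulator_names),
            },
        )
        return self


def _target_weights(
    normalized: ExpressionMatrix,
    target: str,
    candidates,
    *,
    method, n_trees, k, bootstrap, min_split, seed,
) -> dict:
    """Importance of each candidate regulator for one target gene.

    A constant target column (all-zero after normalization) gets a zero
    weight vector without fitting any model.
    """
    outputs = normalized.column(target)
    if outputs.max() == outputs.min():
        logger.info("target %s is constant; assigning zero weights", target)
        return {g: 0.0 for g in candidates}
    sample = build_learning_sample(normalized, target, candidates)
    forest = VarianceReductionForest(
        method=method, n_trees=n_trees, k=k, bootstrap=bootstrap,
        min_split=min_split, random_state=seed,
    ).fit(sample.inputs, sample.outputs)
    return dict(zip(sample.input_genes, forest.feature_importances_))


def rank_regulators_for_target(
    matrix: ExpressionMatrix,
    target: str,
    regulators="all",
    config: EnsembleConfig | None = None,
) -> pd.Series:
    """Importance weights of the candidate regulators for one target gene.

    ``matrix`` is expected to be unit-variance normalized already (this is the
    building block of :func:`infer_network`, which normalizes internally).
    Returns a Series indexed by regulator name, in matrix order.
    """
    config = config or EnsembleConfig()
    if isinstance(regulators, str):
        if regulators != "all":
            raise ConfigurationError("regulators must be a gene list or 'all'")
        candidates = [g for g in matrix.gene_names if g != target]
    else:
        wanted = list(dict.fromkeys(regulators))
        for g in wanted:
            matrix.gene_index(g)
        candidates = [g for g in matrix.gene_names if g in set(wanted) and g != target]
    if not candidates:
        raise ConfigurationError(f"no candidate regulators for target {target!r}")
    matrix.gene_index(target)
    weights = _target_weights(
        matrix, target, candidates,
        method=config.method, n_trees=config.n_trees, k=config.k,
        bootstrap=config.bootstrap, min_split=config.min_split, seed=config.seed,
    )
    return pd.Series([weights[g] for g in candidates], index=candidates, name=target)


def infer_network(
    matrix,
    regulators="all",
    config: EnsembleConfig | None = None,
    **kwargs,
) -> LinkRanking:
    """Functional facade over :class:`GENIE3`: raw matrix in, ranking out."""
    if config is None:
        config = EnsembleConfig(**kwargs)
    elif kwargs:
        raise ConfigurationError("pass either a config or keyword overrides, not both")
    reg = None if (isinstance(regulators, str) and regulators == "all") else list(regulators)
    model = GENIE3(
        method=config.method,
        n_trees=config.n_trees,
        k=config.k,
        regulators=reg,
        bootstrap=config.bootstrap,
        min_split=config.min_split,
        random_state=config.seed,
    )
    return model.fit(matrix).ranking_


def symmetrize_max(ranking: LinkRanking) -> LinkRanking:
    """Undirected view: give both directions of a pair the larger weight.

    Requires a ranking over the full gene universe (every gene a candidate
    regulator). Idempotent.
    """
    p = len(ranking.gene_names)
    if ranking.regulator_set_idx.size != p:
        raise ConfigurationError(
            "symmetrization requires a ranking over the full gene universe"
        )
    W = ranking.weight_matrix()
    M = np.maximum(W, W.T)
    return LinkRanking.from_matrix(
        M, ranking.gene_names,
        metadata={**ranking.metadata, "transform": "symmetrize_max"},
    )


def swap_directions(ranking: LinkRanking) -> LinkRanking:
    """Exchange ``w_ij`` and ``w_ji`` for every gene pair (an involution)."""
    p = len(ranking.gene_names)
    if ranking.regulator_set_idx.size != p:
        raise ConfigurationError(
            "direction swapping requires a ranking over the full gene universe"
        )
    W = ranking.weight_matrix()
    return LinkRanking.from_matrix(
        W.T, ranking.gene_names,
        metadata={**ranking.metadata, "transform": "swap_directions"},
    )


def threshold_to_network(ranking: LinkRanking, n_edges: int) -> PredictedNetwork:
    """Keep the top ``n_edges`` links of the (tie-broken) ranking order."""
    if not 0 <= n_edges <= len(ranking):
        raise ConfigurationError(
            f"n_edges={n_edges} outside [0, {len(ranking)}]"
        )
    edges = frozenset(
        (ranking.gene_names[r], ranking.gene_names[t])
        for r, t in zip(
            ranking.regulator_idx[:n_edges], ranking.target_idx[:n_edges]
        )
    )
    return PredictedNetwork(
        gene_names=ranking.gene_names,
        edges=edges,
        n_edges=n_edges,
        metadata={"source": dict(ranking.metadata), "cutoff_edges": n_edges},
    )
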