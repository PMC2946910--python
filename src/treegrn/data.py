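"""Steady-state expression matrices and per-target-gene learning samples.

The central container is :class:`ExpressionMatrix`: ``N`` experimental
conditions by ``p`` genes, with gene names and condition identifiers kept
alongside the values. Network inference decomposes such a matrix into one
regression problem per gene — a :class:`LearningSample` whose inputs are the
expression profiles of the candidate regulators and whose output is the
profile of the target gene.

All expression profiles are brought to zero mean and unit *population*
variance before any tree is grown (:func:`normalize_unit_variance`): the
importance of a regulator is measured in units of explained output variance,
so unit-variance outputs are what make importances from different per-gene
models comparable in a single global ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataIntegrityError

__all__ = [
    "ExpressionMatrix",
    "LearningSample",
    "normalize_unit_variance",
    "build_learning_sample",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """An ``N × p`` matrix of expression levels with gene/condition labels.

    Parameters
    ----------
    values : ndarray of shape (n_conditions, n_genes)
        Real-valued expression levels; must be finite.
    gene_names : tuple of str
        Unique identifiers of the ``p`` genes, one per column.
    condition_ids : tuple of str
        Identifiers of the ``N`` conditions, one per row.
    """

    values: np.ndarray
    gene_names: tuple
    condition_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))
        if values.ndim != 2:
            raise DataIntegrityError("expression values must form a 2-D matrix")
        n, p = values.shape
        if n < 2 or p < 2:
            raise DataIntegrityError(
                f"need at least 2 conditions and 2 genes, got {n} x {p}"
            )
        if len(self.gene_names) != p:
            raise DataIntegrityError(
                f"{len(self.gene_names)} gene names for {p} columns"
            )
        if len(self.condition_ids) != n:
            raise DataIntegrityError(
                f"{len(self.condition_ids)} condition ids for {n} rows"
            )
        if len(set(self.gene_names)) != p:
            raise DataIntegrityError("gene names must be unique")
        if not np.isfinite(values).all():
            raise DataIntegrityError("expression values must all be finite")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_array(
        cls,
        values,
        gene_names: Sequence[str] | None = None,
        condition_ids: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Wrap a plain array, synthesizing ``G1..Gp`` / ``C1..CN`` labels."""
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise DataIntegrityError("expression values must form a 2-D matrix")
        n, p = values.shape
        if gene_names is None:
            gene_names = [f"G{i + 1}" for i in range(p)]
        if condition_ids is None:
            condition_ids = [f"C{i + 1}" for i in range(n)]
        return cls(values, tuple(gene_names), tuple(condition_ids))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Columns are genes, rows are conditions (index becomes the ids)."""
        return cls(
            frame.to_numpy(dtype=np.float64),
            tuple(str(c) for c in frame.columns),
            tuple(str(i) for i in frame.index),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.condition_ids),
            columns=list(self.gene_names),
        )

    # -- accessors --------------------------------------------------------

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @cached_property
    def _name_to_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_names)}

    def gene_index(self, name: str) -> int:
        try:
            return self._name_to_index[name]
        except KeyError:
            raise KeyError(f"unknown gene name: {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.gene_index(name)]


@dataclass(frozen=True)
class LearningSample:
    """The regression problem for one target gene.

    ``inputs`` holds the expression of the candidate regulators (``N × m``),
    ``outputs`` the expression of the target (length ``N``). The target gene
    itself is never among the inputs: a gene may not explain itself.
    """

    target_gene: str
    input_genes: tuple
    inputs: np.ndarray
    outputs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "input_genes", tuple(self.input_genes))
        inputs = np.asarray(self.inputs, dtype=np.float64)
        outputs = np.asarray(self.outputs, dtype=np.float64)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "outputs", outputs)
        if self.target_gene in self.input_genes:
            raise DataIntegrityError("target gene must not appear among inputs")
        if len(self.input_genes) < 1:
            raise ConfigurationError("learning sample needs at least one input gene")
        if inputs.ndim != 2 or inputs.shape[1] != len(self.input_genes):
            raise DataIntegrityError("inputs shape does not match input_genes")
        if inputs.shape[0] != outputs.shape[0]:
            raise DataIntegrityError("inputs and outputs disagree on sample count")

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[1]


def normalize_unit_variance(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale it to unit population variance.

    Constant genes (zero variance) are mapped to all-zero columns rather than
    raising: flat probes occur in real compendia, and a zero column simply
    receives and contributes zero importance downstream.

    The transform is idempotent: applying it twice equals applying it once
    (up to floating-point round-off).
    """
    values = matrix.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population (ddof=0)
    out = np.zeros_like(values)
    live = sd > 0
    out[:, live] = (values[:, live] - mean[live]) / sd[live]
    return ExpressionMatrix(out, matrix.gene_names, matrix.condition_ids)


def build_learning_sample(
    matrix: ExpressionMatrix,
    target_gene: str,
    candidate_regulators: Iterable[str] | str = "all",
) -> LearningSample:
    """Assemble the regression problem for one target gene.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Expression data (normalized or raw — this function does not rescale).
    target_gene : str
        The gene whose profile is the regression output.
    candidate_regulators : iterable of str or "all"
        Genes allowed as inputs, e.g. the known transcription factors.
        ``"all"`` uses every gene. The target is always excluded, so with
        ``"all"`` the problem has ``m = p - 1`` inputs.

    Raises
    ------
    KeyError
        If the target or a candidate regulator is not in the matrix.
    ConfigurationError
        If no candidate regulator remains after removing the target.
    """
    target_idx = matrix.gene_index(target_gene)
    if isinstance(candidate_regulators, str):
        if candidate_regulators != "all":
            raise ConfigurationError(
                f"candidate_regulators must be a gene list or 'all', "
                f"got {candidate_regulators!r}"
            )
        reg_idx = [i for i in range(matrix.n_genes) if i != target_idx]
    else:
        wanted = set(candidate_regulators)
        for name in wanted:
            matrix.gene_index(name)  # raises KeyError for unknown genes
        reg_idx = [
            i
            for i, g in enumerate(matrix.gene_names)
            if g in wanted and i != target_idx
        ]
    if not reg_idx:
        raise ConfigurationError(
            f"no candidate regulators left for target {target_gene!r}"
        )
    return LearningSample(
        target_gene=target_gene,
        input_genes=tuple(matrix.gene_names[i] for i in reg_idx),
        inputs=matrix.values[:, reg_idx],
        outputs=matrix.values[:, target_idx],
    )
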