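"""Synthetic gene networks and multifactorial steady-state expression data.

The generator emulates the *structure* of multifactorial perturbation
experiments: in every condition the basal activation of **all** genes is
shifted simultaneously by small independent random amounts, the network
settles to a steady state, and the state is measured with noise. It makes no
attempt to reproduce a detailed kinetic model of transcription — its job is
to provide a ground-truth topology against which inference and evaluation can
be exercised end to end.

Two steady-state models are available:

linear (default)
    ``x = A x + b`` solved in closed form, with the weighted adjacency ``A``
    rescaled to spectral radius <= 0.9 so a unique stable steady state exists.
sigmoid
    ``x = sigma(A x + b)`` iterated to a fixed point, exercising the
    non-linear regime tree ensembles are meant to handle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix
from .evaluation import GoldStandard
from .exceptions import ConfigurationError, SimulationError

__all__ = [
    "SyntheticNetwork",
    "SimulationConfig",
    "generate_random_network",
    "simulate_multifactorial",
    "dream4_like_config",
]

_SPECTRAL_RADIUS_CAP = 0.9


@dataclass(frozen=True)
class SyntheticNetwork:
    """A ground-truth directed, signed, weighted network without self-edges.

    ``adjacency[j, i]`` is the effect of regulator ``i`` on target ``j``
    (zero where no edge). Cycles are permitted; self-edges are not.
    """

    adjacency: np.ndarray
    gene_names: tuple

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=np.float64)
        object.__setattr__(self, "adjacency", A)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        p = len(self.gene_names)
        if A.shape != (p, p):
            raise ConfigurationError("adjacency must be p x p")
        if np.diagonal(A).any():
            raise ConfigurationError("self-edges are not allowed")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    def edges(self):
        """Yield ``(regulator_name, target_name, weight)`` for every edge."""
        tgt, reg = np.nonzero(self.adjacency)
        for j, i in zip(tgt, reg):
            yield self.gene_names[i], self.gene_names[j], float(self.adjacency[j, i])

    def to_gold_standard(self) -> GoldStandard:
        return GoldStandard(
            gene_names=self.gene_names,
            positives=frozenset((r, t) for r, t, _ in self.edges()),
        )

    def in_degrees(self) -> np.ndarray:
        return (self.adjacency != 0).sum(axis=1)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a multifactorial steady-state experiment.

    Parameters
    ----------
    n_conditions : int
        Number of measured conditions ``N`` (default 100, the size of the
        in-silico multifactorial benchmarks).
    perturbation_sd : float
        Standard deviation of the per-gene basal-activation shift applied in
        each condition, in units of the basal level (default 0.3: "slight"
        perturbations around a basal level of 1).
    noise_sd : float
        Standard deviation of the additive measurement noise (default 0.05,
        a typical technical-noise scale relative to the basal level).
    model : {"linear", "sigmoid"}
    seed : int or None
    """

    n_conditions: int = 100
    perturbation_sd: float = 0.3
    noise_sd: float = 0.05
    model: str = "linear"
    seed: object = None

    def __post_init__(self):
        if self.n_conditions < 2:
            raise ConfigurationError("need at least 2 conditions")
        if self.perturbation_sd <= 0 or self.noise_sd < 0:
            raise ConfigurationError("scales must be positive")
        if self.model not in ("linear", "sigmoid"):
            raise ConfigurationError(f"unknown model {self.model!r}")


def dream4_like_config(seed=None, **overrides) -> SimulationConfig:
    """The benchmark-sized preset: p is chosen by the caller, N = 100."""
    return SimulationConfig(seed=seed, **overrides)


def generate_random_network(
    p: int,
    expected_in_degree: float,
    seed=None,
    weight_range: tuple = (0.3, 0.8),
) -> SyntheticNetwork:
    """Erdos-Renyi-style random regulatory network.

    Every ordered non-self pair is an edge independently with probability
    ``expected_in_degree / (p - 1)``; edge magnitudes are uniform in
    ``weight_range`` with random sign. The weighted adjacency is rescaled, if
    needed, so its spectral radius does not exceed 0.9 (keeping the linear
    steady-state model stable).
    """
    if p < 2:
        raise ConfigurationError("need at least 2 genes")
    prob = expected_in_degree / (p - 1)
    if not 0 <= prob <= 1:
        raise ConfigurationError(
            f"expected_in_degree={expected_in_degree} infeasible for p={p}"
        )
    rng = np.random.default_rng(seed)
    present = rng.random((p, p)) < prob
    np.fill_diagonal(present, False)
    lo, hi = weight_range
    magnitude = rng.uniform(lo, hi, size=(p, p))
    sign = rng.choice([-1.0, 1.0], size=(p, p))
    A = np.where(present, magnitude * sign, 0.0)
    radius = np.max(np.abs(np.linalg.eigvals(A))) if A.any() else 0.0
    if radius > _SPECTRAL_RADIUS_CAP:
        A *= _SPECTRAL_RADIUS_CAP / radius
    return SyntheticNetwork(A, tuple(f"G{i + 1}" for i in range(p)))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _sigmoid_fixed_point(A, b, max_iter=200, tol=1e-8):
    x = np.full(b.shape, 0.5)
    for _ in range(max_iter):
        x_next = _sigmoid(A @ x + b)
        if np.max(np.abs(x_next - x)) < tol:
            return x_next
        x = x_next
    return None


def simulate_multifactorial(
    network: SyntheticNetwork, config: SimulationConfig
) -> ExpressionMatrix:
    """Simulate ``N`` multifactorial steady-state expression profiles.

    Each condition draws an independent per-gene basal shift
    ``delta ~ Normal(0, perturbation_sd**2)`` on top of a basal level of 1,
    solves the steady state of the chosen model, and adds measurement noise.
    For the sigmoid model a non-converged condition is retried with a fresh
    draw, up to 10 times, before :class:`SimulationError` is raised.
    """
    rng = np.random.default_rng(config.seed)
    p = network.n_genes
    A = network.adjacency
    basal = np.ones(p)
    N = config.n_conditions
    states = np.empty((N, p))
    if config.model == "linear":
        deltas = rng.normal(0.0, config.perturbation_sd, size=(N, p))
        states = np.linalg.solve(np.eye(p) - A, (basal + deltas).T).T
    else:
        for cond in range(N):
            for _ in range(10):
                delta = rng.normal(0.0, config.perturbation_sd, size=p)
                x = _sigmoid_fixed_point(A, basal + delta)
                if x is not None:
                    states[cond] = x
                    break
            else:
                raise SimulationError(
                    f"condition {cond}: fixed point did not converge in 10 attempts"
                )
    noise = rng.normal(0.0, config.noise_sd, size=(N, p)) if config.noise_sd else 0.0
    return ExpressionMatrix.from_array(
        states + noise,
        gene_names=network.gene_names,
        condition_ids=[f"C{i + 1}" for i in range(N)],
    )
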