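import numpy as np
import pytest

from treegrn import (
    EnsembleConfig,
    SimulationConfig,
    auroc,
    generate_random_network,
    infer_network,
    simulate_multifactorial,
    swap_directions,
)

BENCHMARK_SEEDS = 5


def run_linear_benchmark(base_seed: int = 0):
    """The end-to-end recovery benchmark: a 20-gene linear-Gaussian network
    with expected in-degree 2, N=150 multifactorial conditions, inferred with
    bagged trees (RF, T=100, K=all). Returns per-seed AUROC of the inferred
    ranking, of the direction-swapped ranking, and of a shuffled-ranking null.
    """
    results = []
    for s in range(BENCHMARK_SEEDS):
        ss = np.random.SeedSequence([base_seed, s])
        net_seed, sim_seed, inf_seed, null_seed = ss.spawn(4)
        network = generate_random_network(20, 2.0, seed=net_seed)
        matrix = simulate_multifactorial(
            network, SimulationConfig(n_conditions=150, seed=sim_seed)
        )
        ranking = infer_network(
            matrix,
            config=EnsembleConfig(method="RF", n_trees=100, k="all", seed=inf_seed),
        )
        gold = network.to_gold_standard()
        shuffled = _shuffle_ranking(ranking, null_seed)
        results.append(
            {
                "auroc": auroc(ranking, gold),
                "auroc_swapped": auroc(swap_directions(ranking), gold),
                "auroc_shuffled": auroc(shuffled, gold),
                "network": network,
                "ranking": ranking,
                "gold": gold,
            }
        )
    return results


def _shuffle_ranking(ranking, seed):
    from treegrn import LinkRanking

    rng = np.random.default_rng(seed)
    n = len(ranking)
    perm = rng.permutation(n)
    # distinct strictly decreasing weights in a random pair order
    weights = np.linspace(1.0, 0.5, n)
    return LinkRanking(
        ranking.gene_names,
        ranking.regulator_idx[perm],
        ranking.target_idx[perm],
        weights,
    )


@pytest.fixture(scope="session")
def linear_benchmark():
    return run_linear_benchmark(base_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
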