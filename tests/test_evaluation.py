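import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from oracles import enumeration_aupr, pairwise_auroc

from treegrn import (
    EvaluationError,
    GoldStandard,
    LinkRanking,
    PredictedNetwork,
    asymmetry_proportion,
    aupr,
    auroc,
    direction_error_rate,
    empirical_pvalue,
    evaluate_ranking,
    geometric_mean_pvalues,
    overall_score,
    pr_roc_curves,
    regulator_rank_analysis,
)

# Table-2-style per-network p-values of the winning and runner-up submissions
PVALS_AUPR_BEST = [3.3e-34, 7.9e-54, 1.8e-54, 5.5e-47, 4.6e-44]
PVALS_AUROC_BEST = [3.3e-18, 1.1e-28, 9.7e-34, 6.7e-33, 1.9e-34]
PVALS_AUPR_2ND = [5.6e-23, 9.7e-50, 6.6e-43, 1.5e-35, 4.4e-23]
PVALS_AUROC_2ND = [1.7e-17, 5.4e-21, 4.9e-28, 1.9e-23, 1.1e-24]


def pnpn_case():
    """Four-pair universe whose ranking order is P, N, P, N."""
    genes = ("A", "B", "C")
    ranking = LinkRanking.from_pairs(
        genes,
        [("A", "B", 0.9), ("A", "C", 0.8), ("B", "A", 0.7), ("B", "C", 0.6)],
    )
    gold = GoldStandard(
        genes,
        positives={("A", "B"), ("B", "A")},
        explicit_negatives={("A", "C"), ("B", "C")},
    )
    return ranking, gold


def random_case(rng, p, n_pos):
    genes = tuple(f"G{i}" for i in range(p))
    W = rng.random((p, p))
    if rng.random() < 0.5:
        W = np.round(W, 1)  # inject weight ties
    np.fill_diagonal(W, 0)
    ranking = LinkRanking.from_matrix(W, genes)
    pairs = [(a, b) for a in genes for b in genes if a != b]
    chosen = rng.choice(len(pairs), size=n_pos, replace=False)
    gold = GoldStandard(genes, positives={pairs[i] for i in chosen})
    return ranking, gold


def aligned_arrays(ranking, gold):
    labels, weights = [], []
    pos, neg = gold.positives, gold.negatives
    for r, t, w in ranking:
        if (r, t) in pos or (r, t) in neg:
            labels.append((r, t) in pos)
            weights.append(w)
    return np.asarray(weights), np.asarray(labels)


class TestCurves:
    def test_pnpn_precision_sequence(self):
        ranking, gold = pnpn_case()
        precision, recall, fpr, tpr = pr_roc_curves(ranking, gold)
        np.testing.assert_allclose(precision, [1, 0.5, 2 / 3, 0.5])
        np.testing.assert_allclose(recall, [0.5, 0.5, 1.0, 1.0])
        np.testing.assert_allclose(fpr, [0, 0.5, 0.5, 1.0])

    def test_recall_and_fpr_monotone(self, rng):
        ranking, gold = random_case(rng, 8, 10)
        _, recall, fpr, _ = pr_roc_curves(ranking, gold)
        assert (np.diff(recall) >= 0).all()
        assert (np.diff(fpr) >= 0).all()

    def test_no_positives_is_an_evaluation_error(self):
        ranking, _ = pnpn_case()
        gold = GoldStandard(("A", "B", "C"), positives=set())
        with pytest.raises(EvaluationError):
            pr_roc_curves(ranking, gold)


class TestAreas:
    def test_perfect_ranking_scores_one(self):
        genes = ("A", "B", "C")
        ranking = LinkRanking.from_pairs(
            genes,
            [("A", "B", 0.9), ("B", "A", 0.8), ("A", "C", 0.2), ("B", "C", 0.1)],
        )
        gold = GoldStandard(
            genes,
            positives={("A", "B"), ("B", "A")},
            explicit_negatives={("A", "C"), ("B", "C")},
        )
        assert aupr(ranking, gold) == 1.0
        assert auroc(ranking, gold) == 1.0

    def test_pnpn_worked_examples(self):
        ranking, gold = pnpn_case()
        assert aupr(ranking, gold) == pytest.approx((1 + 2 / 3) / 2)
        assert auroc(ranking, gold) == pytest.approx(0.75)

    def test_reversed_ranking_complements_auroc(self):
        ranking, gold = pnpn_case()
        reversed_ranking = LinkRanking.from_pairs(
            ranking.gene_names,
            [(r, t, 1.0 - w) for r, t, w in ranking],
        )
        assert auroc(reversed_ranking, gold) == pytest.approx(1 - auroc(ranking, gold))

    def test_areas_match_pairwise_oracles_on_random_rankings(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = int(rng.integers(4, 15))  # up to 14*13 = 182 pairs
            n_pairs = p * (p - 1)
            n_pos = int(rng.integers(1, n_pairs))
            ranking, gold = random_case(rng, p, n_pos)
            weights, labels = aligned_arrays(ranking, gold)
            assert auroc(ranking, gold) == pytest.approx(
                pairwise_auroc(weights, labels), abs=1e-12
            )
            assert aupr(ranking, gold) == pytest.approx(
                enumeration_aupr(labels), abs=1e-12
            )

    def test_auroc_matches_sklearn(self, rng):
        ranking, gold = random_case(rng, 10, 20)
        weights, labels = aligned_arrays(ranking, gold)
        assert auroc(ranking, gold) == pytest.approx(roc_auc_score(labels, weights))

    def test_inserting_top_positive_never_decreases_areas(self, rng):
        for _ in range(20):
            p = int(rng.integers(4, 9))
            ranking, gold = random_case(rng, p, int(rng.integers(2, p)))
            # promote one positive that is not already ranked first
            frame = ranking.to_frame()
            top_w = frame["weight"].max()
            for reg, tgt in gold.positives:
                promoted = LinkRanking.from_pairs(
                    ranking.gene_names,
                    [
                        (r, t, (top_w + 1.0) if (r, t) == (reg, tgt) else w)
                        for r, t, w in ranking
                    ],
                )
                assert aupr(promoted, gold) >= aupr(ranking, gold) - 1e-12
                assert auroc(promoted, gold) >= auroc(ranking, gold) - 1e-12

    def test_random_ranking_aupr_null_expectation(self):
        # for average precision the null mean sits slightly above the positive
        # fraction (the first positive often lands early with precision ~1);
        # 0.1398 is the Monte-Carlo null mean for 10 positives in 100 pairs
        rng = np.random.default_rng(0)
        n, n_pos = 100, 10
        values = []
        for _ in range(1000):
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, n_pos, replace=False)] = True
            values.append(enumeration_aupr(labels))
        assert np.mean(values) == pytest.approx(0.1398, abs=0.01)
        assert np.mean(values) > n_pos / n


class TestPValues:
    def test_floor_and_ceiling(self):
        _, gold = pnpn_case()
        # observed below every null draw -> p = 1; above every draw -> floor
        assert empirical_pvalue(-1.0, "auroc", gold, B=99, seed=0) == 1.0
        assert empirical_pvalue(1.1, "aupr", gold, B=999, seed=0) == pytest.approx(
            1 / 1000
        )

    def test_median_null_auroc_has_pvalue_half(self):
        genes = tuple(f"G{i}" for i in range(6))
        pairs = [(a, b) for a in genes for b in genes if a != b]
        gold = GoldStandard(genes, positives=set(pairs[:15]))  # 15 pos, 15 neg
        p = empirical_pvalue(0.5, "auroc", gold, B=999, seed=3)
        assert abs(p - 0.5) < 0.05

    def test_geometric_mean_of_reported_pvalues(self):
        gm_aupr = geometric_mean_pvalues(PVALS_AUPR_BEST)
        gm_auroc = geometric_mean_pvalues(PVALS_AUROC_BEST)
        assert abs(gm_aupr - 1.0e-46) <= 0.05e-46
        assert abs(gm_auroc - 1.4e-29) <= 0.0505e-29
        assert geometric_mean_pvalues([0.2, 0.2, 0.2]) == pytest.approx(0.2)

    def test_overall_score_reproduces_reported_challenge_scores(self):
        assert overall_score(PVALS_AUPR_BEST, PVALS_AUROC_BEST) == pytest.approx(
            37.428, abs=0.05
        )
        assert overall_score(PVALS_AUPR_2ND, PVALS_AUROC_2ND) == pytest.approx(
            28.165, abs=0.05
        )
        assert overall_score([1, 1], [1, 1]) == 0.0


class TestDirectionality:
    def test_asymmetry_proportion_counts_one_way_edges(self):
        genes = ("a", "b", "c", "d")

        def net(edges):
            return PredictedNetwork(genes, frozenset(edges), len(edges))

        assert asymmetry_proportion(net({("a", "b"), ("b", "a")})) == 0.0
        assert asymmetry_proportion(net({("a", "b")})) == 1.0
        assert asymmetry_proportion(
            net({("a", "b"), ("b", "a"), ("c", "d")})
        ) == pytest.approx(1 / 3)

    def test_direction_error_rate_worked_cases(self):
        genes = ("a", "b")
        gold = GoldStandard(genes, positives={("a", "b")})
        forward = LinkRanking.from_pairs(genes, [("a", "b", 0.9), ("b", "a", 0.1)])
        backward = LinkRanking.from_pairs(genes, [("a", "b", 0.1), ("b", "a", 0.9)])
        for recall in (0.05, 0.5, 1.0):
            assert direction_error_rate(forward, gold, recall) == 0.0
            assert direction_error_rate(backward, gold, recall) == 1.0

    def test_random_weights_err_about_half_the_time(self):
        p = 30
        genes = tuple(f"G{i}" for i in range(p))
        rng = np.random.default_rng(5)
        pairs = [(a, b) for a in genes for b in genes if a != b]
        rates = []
        for _ in range(10):
            chosen = rng.choice(len(pairs), size=200, replace=False)
            positives = set()
            for i in chosen:
                r, t = pairs[i]
                if (t, r) not in positives:
                    positives.add((r, t))
            gold = GoldStandard(genes, positives=positives)
            W = rng.random((p, p))
            np.fill_diagonal(W, 0)
            ranking = LinkRanking.from_matrix(W, genes)
            rates.append(direction_error_rate(ranking, gold, 1.0))
        assert abs(np.mean(rates) - 0.5) < 0.1

    def test_no_asymmetric_edges_is_an_evaluation_error(self):
        genes = ("a", "b")
        gold = GoldStandard(genes, positives={("a", "b"), ("b", "a")})
        ranking = LinkRanking.from_pairs(genes, [("a", "b", 0.9), ("b", "a", 0.1)])
        with pytest.raises(EvaluationError):
            direction_error_rate(ranking, gold, 1.0)


class TestRegulatorRanks:
    def test_first_and_last_rank_percent(self):
        p = 12  # m = 11 candidates per target
        genes = tuple(f"G{i}" for i in range(p))
        W = np.zeros((p, p))
        W[:, 0] = np.linspace(1.0, 0.1, p)  # regulators of G0: G1 best... G11 worst
        W[0, 0] = 0.0
        ranking = LinkRanking.from_matrix(W, genes)
        gold = GoldStandard(genes, positives={("G1", "G0"), ("G11", "G0")})
        per_edge, _ = regulator_rank_analysis(ranking, gold)
        by_reg = per_edge.set_index("regulator")["rank_percent"]
        assert by_reg["G1"] == 100.0
        assert by_reg["G11"] == 0.0
        assert per_edge["n_candidates"].unique().tolist() == [11]

    def test_uniform_random_local_rankings_center_at_fifty_percent(self):
        rng = np.random.default_rng(8)
        m = 11
        percents = []
        for _ in range(1000):
            rank = rng.integers(1, m + 1)
            percents.append(100 * (m - rank) / (m - 1))
        assert abs(np.mean(percents) - 50.0) < 5.0

    def test_median_grouped_by_in_degree(self):
        genes = ("A", "B", "C", "D")
        W = np.array(
            [
                [0.0, 0.9, 0.1, 0.1],
                [0.1, 0.0, 0.9, 0.1],
                [0.2, 0.1, 0.0, 0.1],
                [0.3, 0.2, 0.3, 0.0],
            ]
        )
        ranking = LinkRanking.from_matrix(W, genes)
        gold = GoldStandard(
            genes, positives={("A", "B"), ("C", "B"), ("B", "C")}
        )
        per_edge, by_deg = regulator_rank_analysis(ranking, gold)
        assert set(by_deg.index) == {1, 2}
        assert len(per_edge) == 3


class TestReport:
    def test_full_report_fields(self, rng):
        ranking, gold = random_case(rng, 6, 8)
        report = evaluate_ranking(ranking, gold, B=99, seed=1)
        assert report.aupr == pytest.approx(aupr(ranking, gold))
        assert report.auroc == pytest.approx(auroc(ranking, gold))
        assert report.n_positives == 8
        assert 1 / 100 <= report.aupr_pvalue <= 1.0
        assert 1 / 100 <= report.auroc_pvalue <= 1.0
        d = report.to_dict()
        assert d["n_permutations"] == 99
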