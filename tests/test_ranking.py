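import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from entrank import (
    CyclicRelationError,
    DegenerateInputError,
    RankVector,
    Scoreboard,
    ValidationError,
    complexity_regression,
    correlation_matrix,
    kendall_tau,
    majority_ranking,
    majority_relation,
    rank_by_metric,
    spearman_rho,
)


def board_from(values: dict, directions: dict | None = None) -> Scoreboard:
    return Scoreboard(pd.DataFrame(values), directions or {})


AGREEING_BOARD = board_from(
    {
        "purity": {"A": 0.9, "B": 0.8, "C": 0.7},
        "nmi": {"A": 0.8, "B": 0.6, "C": 0.4},
        "ari": {"A": 0.7, "B": 0.5, "C": 0.2},
    }
)

# purity: A>B>C, nmi: B>C>A, ari: C>A>B  =>  pairwise majority cycles A>B>C>A
CYCLE_BOARD = board_from(
    {
        "purity": {"A": 0.9, "B": 0.8, "C": 0.7},
        "nmi": {"A": 0.7, "B": 0.9, "C": 0.8},
        "ari": {"A": 0.8, "B": 0.7, "C": 0.9},
    }
)


class TestRankByMetric:
    def test_higher_better_descending(self):
        board = board_from({"purity": {"A": 0.9, "B": 0.7, "C": 0.5}})
        assert rank_by_metric(board, "purity").ranks == {"A": 1, "B": 2, "C": 3}

    def test_lower_better_direction_inverted(self):
        board = board_from({"db": {"A": 0.3, "B": 0.6}})
        assert rank_by_metric(board, "db").ranks == {"A": 1, "B": 2}

    def test_exact_ties_average(self):
        board = board_from({"nmi": {"A": 0.5, "B": 0.5, "C": 0.1}})
        assert rank_by_metric(board, "nmi").ranks == {"A": 1.5, "B": 1.5, "C": 3}

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError):
            rank_by_metric(AGREEING_BOARD, "accuracy")

    def test_direction_tag_required(self):
        with pytest.raises(ValidationError, match="direction"):
            board_from({"mystery": {"A": 1.0, "B": 2.0}})


class TestMajorityRelation:
    def test_unanimous_order_is_transitive(self):
        relation = majority_relation(AGREEING_BOARD)
        assert relation.transitive
        assert relation.winner("A", "B") == "A"
        assert relation.winner("B", "C") == "B"
        assert relation.winner("A", "C") == "A"

    def test_condorcet_cycle_detected(self):
        relation = majority_relation(CYCLE_BOARD)
        assert not relation.transitive
        assert len(relation.cycles) == 1
        assert set(relation.cycles[0]) == {"A", "B", "C"}

    def test_equal_on_all_metrics_is_a_tie(self):
        board = board_from(
            {
                "purity": {"A": 0.5, "B": 0.5},
                "nmi": {"A": 0.5, "B": 0.5},
                "ari": {"A": 0.5, "B": 0.5},
            }
        )
        assert majority_relation(board).winner("A", "B") is None

    def test_missing_external_metric_rejected(self):
        board = board_from({"purity": {"A": 1.0, "B": 0.5}})
        with pytest.raises(ValidationError, match="nmi"):
            majority_relation(board)


class TestMajorityRanking:
    def test_transitive_relation_gives_topological_order(self):
        ranking = majority_ranking(majority_relation(AGREEING_BOARD))
        assert ranking.ranks == {"A": 1, "B": 2, "C": 3}

    def test_cycle_refused_with_listing(self):
        with pytest.raises(CyclicRelationError) as err:
            majority_ranking(majority_relation(CYCLE_BOARD))
        assert err.value.cycles

    def test_forced_copeland_warns(self):
        with pytest.warns(UserWarning, match="Condorcet"):
            ranking = majority_ranking(
                majority_relation(CYCLE_BOARD), force_copeland=True
            )
        # every algorithm wins exactly one pair in the cycle
        assert sorted(ranking.ranks.values()) == [2, 2, 2]

    def test_pairwise_tie_gives_half_copeland_points(self):
        # A beats B, C, D; B and C equal on all metrics (tie) and both beat D
        board = board_from(
            {
                "purity": {"A": 0.9, "B": 0.8, "C": 0.8, "D": 0.7},
                "nmi": {"A": 0.9, "B": 0.8, "C": 0.8, "D": 0.7},
                "ari": {"A": 0.9, "B": 0.8, "C": 0.8, "D": 0.7},
            }
        )
        relation = majority_relation(board)
        assert relation.copeland_scores() == {"A": 3.0, "B": 1.5, "C": 1.5, "D": 0.0}
        assert majority_ranking(relation).ranks == {"A": 1, "B": 2.5, "C": 2.5, "D": 4}


def rv(*ranks):
    return RankVector({chr(ord("a") + i): r for i, r in enumerate(ranks)})


class TestRankCorrelations:
    def test_identical_rankings(self):
        assert kendall_tau(rv(1, 2, 3), rv(1, 2, 3)) == 1.0
        assert spearman_rho(rv(1, 2, 3), rv(1, 2, 3)) == 1.0

    def test_reversed_rankings(self):
        assert kendall_tau(rv(1, 2, 3, 4), rv(4, 3, 2, 1)) == -1.0
        assert spearman_rho(rv(1, 2, 3, 4), rv(4, 3, 2, 1)) == -1.0

    def test_single_swap_hand_values(self):
        assert kendall_tau(rv(1, 2, 3), rv(2, 1, 3)) == pytest.approx(1 / 3)
        assert spearman_rho(rv(1, 2, 3), rv(2, 1, 3)) == pytest.approx(0.5)

    def test_too_few_items_rejected(self):
        with pytest.raises(DegenerateInputError):
            kendall_tau(rv(1), rv(1))

    def test_fully_tied_ranking_rejected(self):
        with pytest.raises(DegenerateInputError):
            kendall_tau(rv(1.5, 1.5), rv(1, 2))
        with pytest.raises(DegenerateInputError):
            spearman_rho(rv(1.5, 1.5), rv(1, 2))

    def test_mismatched_algorithm_sets_rejected(self):
        with pytest.raises(ValidationError):
            kendall_tau(rv(1, 2), RankVector({"x": 1, "y": 2}))

    def test_matches_scipy_on_random_tied_vectors(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n = int(rng.integers(3, 10))
            r1 = scipy.stats.rankdata(rng.integers(0, 5, n))
            r2 = scipy.stats.rankdata(rng.integers(0, 5, n))
            if len(set(r1)) == 1 or len(set(r2)) == 1:
                continue
            v1, v2 = rv(*r1), rv(*r2)
            assert kendall_tau(v1, v2) == pytest.approx(
                scipy.stats.kendalltau(r1, r2).statistic, abs=1e-12
            )
            assert spearman_rho(v1, v2) == pytest.approx(
                scipy.stats.spearmanr(r1, r2).statistic, abs=1e-12
            )

    def test_invariant_to_monotone_value_transformations(self):
        board = board_from(
            {
                "purity": {"A": 0.9, "B": 0.6, "C": 0.3, "D": 0.1},
                "nmi": {"A": 0.5, "B": 0.8, "C": 0.2, "D": 0.4},
            }
        )
        transformed = board_from(
            {
                "purity": {k: np.exp(v) for k, v in board.values["purity"].items()},
                "nmi": {k: v**3 for k, v in board.values["nmi"].items()},
            }
        )
        for metric in ("purity", "nmi"):
            assert rank_by_metric(board, metric).ranks == rank_by_metric(
                transformed, metric
            ).ranks


class TestCorrelationMatrix:
    def test_all_metrics_agree(self):
        board = board_from(
            {
                "entropy": {"A": 3.0, "B": 2.0, "C": 1.0},
                "purity": {"A": 0.9, "B": 0.8, "C": 0.7},
                "nmi": {"A": 0.9, "B": 0.8, "C": 0.7},
                "ari": {"A": 0.9, "B": 0.8, "C": 0.7},
                "sh": {"A": 0.9, "B": 0.8, "C": 0.7},
                "db": {"A": 0.1, "B": 0.2, "C": 0.3},  # lower-better, same order
            }
        )
        report = correlation_matrix(board)
        assert "majority" in report.criteria
        for c1, c2 in itertools.combinations(report.criteria, 2):
            assert report.pair(c1, c2) == (1.0, 1.0)

    def test_db_direction_made_visible(self):
        board = board_from(
            {
                "purity": {"A": 0.9, "B": 0.8, "C": 0.7},
                "nmi": {"A": 0.9, "B": 0.8, "C": 0.7},
                "ari": {"A": 0.9, "B": 0.8, "C": 0.7},
                "db": {"A": 0.2, "B": 0.5, "C": 0.9},
            }
        )
        report = correlation_matrix(board)
        assert report.pair("purity", "db") == (1.0, 1.0)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(31)
        values = {
            m: {f"alg{i}": float(rng.uniform()) for i in range(8)}
            for m in ("entropy", "purity", "nmi", "ari", "sh", "db")
        }
        report = correlation_matrix(board_from(values), force_copeland=True)
        np.testing.assert_allclose(np.diag(report.tau), 1.0)
        np.testing.assert_allclose(report.tau.values, report.tau.values.T)
        np.testing.assert_allclose(report.rho.values, report.rho.values.T)

    def test_matches_independent_oracle_on_random_board(self):
        rng = np.random.default_rng(37)
        values = {
            m: {f"alg{i}": float(rng.uniform()) for i in range(8)}
            for m in ("entropy", "purity", "nmi", "ari", "sh", "db")
        }
        board = board_from(values)
        report = correlation_matrix(board, force_copeland=True)
        for m1, m2 in itertools.combinations(board.metrics, 2):
            r1 = rank_by_metric(board, m1).as_array(sorted(board.algorithms))
            r2 = rank_by_metric(board, m2).as_array(sorted(board.algorithms))
            tau, rho = report.pair(m1, m2)
            assert tau == pytest.approx(scipy.stats.kendalltau(r1, r2).statistic)
            assert rho == pytest.approx(scipy.stats.spearmanr(r1, r2).statistic)


class TestComplexityRegression:
    def test_exact_linear_response(self):
        points = [(q1, q2, 2.0 + 3.0 * q1) for q1, q2 in
                  [(0.1, 0.9), (0.4, 0.6), (0.7, 0.8), (0.2, 0.3)]]
        result = complexity_regression(points)
        assert result.r_squared == pytest.approx(1.0)
        assert result.coef_q1 == pytest.approx(3.0)

    def test_constant_response(self):
        points = [(0.1, 0.9, 0.5), (0.4, 0.6, 0.5), (0.7, 0.8, 0.5)]
        assert complexity_regression(points).r_squared == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(41)
        q1 = rng.uniform(0, 1, 15)
        q2 = rng.uniform(0, 1, 15)
        y = 0.3 + 0.8 * q1 - 0.5 * q2 + rng.normal(0, 0.05, 15)
        result = complexity_regression(list(zip(q1, q2, y)))
        X = np.column_stack([np.ones(15), q1, q2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert result.intercept == pytest.approx(beta[0], abs=1e-10)
        assert result.coef_q1 == pytest.approx(beta[1], abs=1e-10)
        assert result.coef_q2 == pytest.approx(beta[2], abs=1e-10)
        ss_res = float(((y - X @ beta) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        assert result.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_collinear_inputs_flagged(self):
        points = [(q, q, 1.0 + q) for q in (0.1, 0.2, 0.3, 0.4)]  # q1 == q2
        result = complexity_regression(points)
        assert result.collinear
        # minimum-norm solution still reproduces the fit
        assert result.r_squared == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            complexity_regression([(0.1, 0.2, 0.3), (0.4, 0.5, 0.6)])
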