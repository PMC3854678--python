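"""Embedded chain assembly, stationary distributions, and the weak- and
strong-selection characterizations."""

import numpy as np
import pytest

from selrank import (
    FixationMatrix,
    MatrixGame,
    build_chain,
    build_fixation_matrix,
    erf_rule,
    fermi_rule,
    matrix_pair_profile,
    stationary,
    stationary_for_game,
    strong_selection_limit,
    weak_selection_ranking,
)
from selrank.sim_oracle import pairwise_chain, solve_fixation
from selrank.update_rules import fixation_probability


def three_state_tree_stationary(Lam):
    """Markov-chain tree theorem for three states: x_k is proportional to
    the sum over spanning trees rooted at k of the product of edge
    weights."""
    w = Lam
    x = np.array(
        [
            w[1, 0] * w[2, 0] + w[1, 2] * w[2, 0] + w[2, 1] * w[1, 0],
            w[0, 1] * w[2, 1] + w[0, 2] * w[2, 1] + w[2, 0] * w[0, 1],
            w[0, 2] * w[1, 2] + w[0, 1] * w[1, 2] + w[1, 0] * w[0, 2],
        ]
    )
    return x / x.sum()


class TestFixationMatrix:
    def test_neutral_entries_are_one_over_N(self, random_matrix_game):
        fm = build_fixation_matrix(random_matrix_game(3), fermi_rule(1.0), 25, beta=0.0)
        off = fm.rho[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0 / 25)

    def test_symmetric_game_gives_symmetric_matrix(self):
        a = np.array([[1.0, 0.3, 0.7], [0.3, 1.0, 0.2], [0.7, 0.2, 1.0]])
        fm = build_fixation_matrix(MatrixGame(a), fermi_rule(0.8), 12)
        np.testing.assert_allclose(fm.rho, fm.rho.T, atol=1e-13)

    def test_entries_match_absorbing_chain_oracle(self, random_matrix_game):
        game = random_matrix_game(3)
        rule = fermi_rule(1.0)
        N = 10
        fm = build_fixation_matrix(game, rule, N)
        for m in range(3):
            for r in range(3):
                if m == r:
                    continue
                prof = matrix_pair_profile(game, m, r, N)
                assert fm.rho[m, r] == pytest.approx(
                    solve_fixation(pairwise_chain(prof, rule)), abs=1e-10
                )


class TestChainAndStationary:
    def test_neutral_chain_off_diagonals(self, random_matrix_game):
        N, n = 20, 4
        fm = build_fixation_matrix(random_matrix_game(n), fermi_rule(0.0), N)
        chain = build_chain(fm)
        off = chain.Lambda[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / (N * (n - 1)), atol=1e-15)

    def test_rows_sum_to_one(self, random_matrix_game):
        fm = build_fixation_matrix(random_matrix_game(4), fermi_rule(1.5), 15)
        np.testing.assert_allclose(build_chain(fm).Lambda.sum(axis=1), 1.0, atol=1e-14)

    def test_three_state_tree_theorem(self, rng):
        rho = rng.uniform(0.01, 0.3, (3, 3))
        np.fill_diagonal(rho, np.nan)
        fm = FixationMatrix(rho=rho, log_rho=np.log(rho), beta=1.0)
        chain = build_chain(fm)
        sd = stationary(chain)
        np.testing.assert_allclose(
            sd.x, three_state_tree_stationary(chain.Lambda), atol=1e-12
        )

    def test_neutral_stationary_is_uniform(self, random_matrix_game):
        sd = stationary_for_game(random_matrix_game(5), fermi_rule(1.0), 30, 0.0)
        np.testing.assert_allclose(sd.x, 0.2, atol=1e-12)

    def test_two_state_closed_form(self, random_matrix_game):
        game = random_matrix_game(2)
        rule = fermi_rule(1.2)
        N = 18
        fm = build_fixation_matrix(game, rule, N)
        sd = stationary(build_chain(fm))
        expected = fm.rho[0, 1] / (fm.rho[0, 1] + fm.rho[1, 0])
        assert sd.x[0] == pytest.approx(expected, abs=1e-12)
        # the log-domain two-strategy route agrees
        sd2 = stationary_for_game(game, rule, N, 1.2)
        assert sd2.x[0] == pytest.approx(expected, abs=1e-12)

    def test_solve_and_eig_agree(self, random_matrix_game):
        fm = build_fixation_matrix(random_matrix_game(4), fermi_rule(0.7), 20)
        chain = build_chain(fm)
        x_solve = stationary(chain, method="solve").x
        x_eig = stationary(chain, method="eig").x
        np.testing.assert_allclose(x_solve, x_eig, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        for n in (3, 4):
            game = MatrixGame(rng.uniform(size=(n, n)))
            perm = rng.permutation(n)
            x = stationary_for_game(game, fermi_rule(0.9), 16, 0.9).x
            x_perm = stationary_for_game(game.permuted(perm), fermi_rule(0.9), 16, 0.9).x
            np.testing.assert_allclose(x_perm, x[perm], atol=1e-11)

    def test_payoff_shift_invariance(self, rng):
        a = rng.uniform(size=(3, 3))
        for rule in (fermi_rule(1.0), erf_rule(1.0)):
            x1 = stationary_for_game(MatrixGame(a), rule, 14, 1.0).x
            x2 = stationary_for_game(MatrixGame(a + 3.3), rule, 14, 1.0).x
            np.testing.assert_allclose(x1, x2, atol=1e-11)

    def test_reducible_chain_flagged(self):
        rho = np.array([[np.nan, 0.0, 0.0], [0.2, np.nan, 0.1], [0.3, 0.2, np.nan]])
        with np.errstate(divide="ignore"):
            fm = FixationMatrix(rho=rho, log_rho=np.log(rho), beta=np.inf)
        sd = stationary(build_chain(fm))
        assert "reducible" in sd.flags
        assert sd.x[0] == 0.0  # strategy 1 cannot be entered


class TestWeakSelection:
    def test_neutral_game_has_no_ranking(self):
        game = MatrixGame(np.full((3, 3), 1.0))
        w = weak_selection_ranking(game, fermi_rule(1.0), 20)
        assert np.all(w.derivatives == 0)
        assert w.tie_groups == (frozenset({0, 1, 2}),)

    def test_derivatives_sum_to_zero(self, rng):
        for _ in range(100):
            game = MatrixGame(rng.uniform(size=(3, 3)))
            w = weak_selection_ranking(game, fermi_rule(1.0), 25)
            assert abs(w.derivatives.sum()) < 1e-8

    def test_ordering_matches_small_beta_evaluation(self, rng):
        for _ in range(10):
            game = MatrixGame(rng.uniform(size=(3, 3)))
            w = weak_selection_ranking(game, fermi_rule(1.0), 40)
            x = stationary_for_game(game, fermi_rule(1.0), 40, 1e-3).x
            assert w.order == tuple(int(i) for i in np.argsort(-x, kind="stable"))


class TestStrongSelection:
    def test_uniformly_advantaged_mutant_fixates(self):
        # payoff differences positive at every state: rho_inf must be 1
        a = np.array([[2.0, 2.0], [0.0, 0.0]])
        s = strong_selection_limit(MatrixGame(a), fermi_rule(1.0), 20)
        assert s.rho_inf[0, 1] == 1.0
        assert s.rho_inf[1, 0] == 0.0

    def test_current_flows_to_risk_dominant_strategy(self):
        # coordination game; strategy 2 is risk dominant (2 + 2 > 3 + 0).
        # Both invaders face a barrier (rho_inf = 0 each way), but the
        # probability current, hence the stationary mass, tips to the
        # risk-dominant strategy as selection grows.
        a = np.array([[3.0, 0.0], [2.0, 2.0]])
        game = MatrixGame(a)
        s = strong_selection_limit(game, fermi_rule(1.0), 100)
        assert s.rho_inf[1, 0] == 0.0
        assert s.rho_inf[0, 1] == 0.0
        x = stationary_for_game(game, fermi_rule(1.0), 100, 200.0).x
        assert x[1] > 0.99

    def test_classifier_agrees_with_large_beta_numerics(self, rng):
        rule = fermi_rule(1.0)
        N = 20
        for _ in range(25):
            game = MatrixGame(rng.uniform(size=(2, 2)))
            s = strong_selection_limit(game, rule, N)
            prof = matrix_pair_profile(game, 0, 1, N)
            rho = fixation_probability(prof, rule.with_beta(500.0)).rho
            limit = s.rho_inf[0, 1]
            assert abs(rho - limit) < 1e-6 or rho < 1e-6

    def test_generic_rule_path_matches_exact_path(self, rng):
        from selrank import custom_rule
        from selrank.update_rules import fermi, log_fermi

        game = MatrixGame(rng.uniform(size=(2, 2)))
        exact = strong_selection_limit(game, fermi_rule(1.0), 12)
        # same function, but flagged non-log-linear: takes the beta ladder
        generic = strong_selection_limit(
            game, custom_rule(fermi, log_fermi, beta=1.0), 12
        )
        np.testing.assert_allclose(generic.rho_inf, exact.rho_inf, atol=1e-6)
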