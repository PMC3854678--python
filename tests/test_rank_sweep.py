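"""Abundance sweeps, overflow-adaptive grids, crossing detection, and the
randomized game searches."""

import numpy as np
import pytest

from selrank import (
    AbundanceCurve,
    BetaGrid,
    FitnessMap,
    MatrixGame,
    MultiplayerPayoffTable,
    adaptive_beta_max,
    detect_crossings,
    erf_rule,
    fermi_rule,
    find_rule_sensitive_game,
    find_intermediate_crossing_game,
    rank_change_report,
    sweep,
)
from selrank.rank_sweep import (
    DegenerateGameError,
    abundance_evaluator,
    study_beta_max,
)
from selrank.update_rules import custom_rule, fermi, log_fermi


class TestBetaGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            BetaGrid(np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            BetaGrid(np.array([0.0, 1.0]))

    def test_refined_preserves_endpoints(self):
        g = BetaGrid.log(1e-2, 10.0, 50)
        r = g.refined(10)
        assert r.values.size == 491
        assert r.values[0] == pytest.approx(1e-2)
        assert r.values[-1] == pytest.approx(10.0)


class TestAdaptiveBetaMax:
    def test_neutral_game_never_overflows(self):
        game = MatrixGame(np.full((3, 3), 1.0))
        assert adaptive_beta_max(game, erf_rule(1.0), 20, cap=1e3) == 1e3

    def test_log_space_fermi_is_unbounded(self, random_matrix_game):
        # regression: log-space evaluation must never overflow for the
        # Fermi rule, whatever the game
        assert adaptive_beta_max(random_matrix_game(3), fermi_rule(1.0), 50) == 1e3

    def test_log_space_erf_reaches_cap(self, random_matrix_game):
        game = MatrixGame(random_matrix_game(2).payoffs * 5)
        fine = adaptive_beta_max(game, erf_rule(1.0), 30, cap=1e3)
        assert fine == 1e3

    def test_bounded_rule_agrees_with_fine_bisection(self, rng):
        # linear Moran fitness turns negative at finite beta, so the
        # bound is non-trivial; compare against a 10x finer scan
        game = MatrixGame(rng.uniform(-1.0, 1.0, (2, 2)))
        fmap = FitnessMap("linear", 1.0)
        bmax = adaptive_beta_max(game, fmap, 12, cap=1e3)
        assert bmax < 1e3
        from selrank.embedded_chain import _pair_profiles
        from selrank.rank_sweep import _probe

        profiles = _pair_profiles(game, 12)
        # fine geometric scan at 0.1% resolution around the bound
        for factor in np.geomspace(1.011, 1.2, 40):
            assert not _probe(game, fmap, 12, bmax * factor, profiles)
        assert _probe(game, fmap, 12, bmax / 1.011, profiles)

    def test_degenerate_game_error(self):
        game = MatrixGame(np.array([[1e9, 1e9], [-1e9, -1e9]]))
        with pytest.raises(DegenerateGameError):
            adaptive_beta_max(game, FitnessMap("linear", 1.0), 10, cap=1e3)


class TestStudyBetaMax:
    def test_closed_form_matches_probe_route(self, rng):
        # the same Fermi function routed as a generic rule exercises the
        # doubling/bisection path; both must land on the same bound
        game = MatrixGame(rng.uniform(size=(3, 3)))
        exact = study_beta_max(game, fermi_rule(1.0), 50)
        probed = study_beta_max(game, custom_rule(fermi, log_fermi, 1.0), 50)
        assert probed == pytest.approx(exact, rel=0.02)

    def test_neutral_game_hits_cap(self):
        game = MatrixGame(np.zeros((2, 2)))
        assert study_beta_max(game, fermi_rule(1.0), 40) == 1e3


class TestSweep:
    def test_continuity_at_zero_selection(self, random_matrix_game):
        game = random_matrix_game(3)
        curve = sweep(game, fermi_rule(1.0), 30, BetaGrid(np.array([1e-8, 1e-7])))
        assert np.max(np.abs(curve.x[0] - 1 / 3)) < 1e-6

    def test_rows_on_simplex(self, random_matrix_game):
        curve = sweep(random_matrix_game(4), fermi_rule(1.0), 25, BetaGrid.log(1e-3, 50, 60))
        assert np.all(curve.x >= 0)
        np.testing.assert_allclose(curve.x.sum(axis=1), 1.0, atol=1e-10)

    def test_label_permutation_permutes_columns(self, rng):
        game = MatrixGame(rng.uniform(size=(3, 3)))
        grid = BetaGrid.log(1e-2, 20, 40)
        perm = np.array([2, 0, 1])
        c1 = sweep(game, fermi_rule(1.0), 20, grid)
        c2 = sweep(game.permuted(perm), fermi_rule(1.0), 20, grid)
        np.testing.assert_allclose(c2.x, c1.x[:, perm], atol=1e-11)

    def test_batch_and_pairwise_paths_agree(self, rng):
        game = MatrixGame(rng.uniform(size=(3, 3)))
        grid = BetaGrid.log(1e-3, 30, 200)
        for rule in (fermi_rule(1.0), erf_rule(1.0)):
            c_batch = sweep(game, rule, 40, grid, batch=True)
            c_pair = sweep(game, rule, 40, grid, batch=False)
            np.testing.assert_allclose(c_batch.x, c_pair.x, atol=1e-10)


def synthetic_curve(betas, diffs):
    """Two-strategy curve with x_0 - x_1 = diffs."""
    x = np.empty((betas.size, 2))
    x[:, 0] = 0.5 + np.asarray(diffs) / 2
    x[:, 1] = 1.0 - x[:, 0]
    return AbundanceCurve(grid=BetaGrid(betas), x=x)


class TestDetectCrossings:
    def test_identical_curves_produce_no_events(self):
        game = MatrixGame(np.full((3, 3), 2.0))
        _, rep = rank_change_report(game, fermi_rule(1.0), 20, refine=False)
        assert rep.total_count == 0

    def test_sign_change_detected_and_located(self):
        betas = np.geomspace(0.01, 10.0, 30)
        diffs = np.where(betas < 1.0, 0.2, -0.2)
        rep = detect_crossings(synthetic_curve(betas, diffs))
        assert rep.total_count == 1
        e = rep.events[0]
        assert e.bracket[0] < 1.0 < e.bracket[1]
        assert e.direction == 1  # strategy 1 overtakes

    def test_tangency_not_counted(self):
        betas = np.geomspace(0.01, 10.0, 51)
        diffs = 0.1 * (np.log(betas) ** 2)  # touches 0 at beta = 1
        rep = detect_crossings(synthetic_curve(betas, diffs), tol=1e-10)
        assert rep.total_count == 0

    def test_near_tie_flagged_degenerate_not_counted(self):
        betas = np.geomspace(0.01, 10.0, 20)
        diffs = np.full(20, 1e-14)
        diffs[10:] = -1e-14
        rep = detect_crossings(synthetic_curve(betas, diffs), tol=1e-10)
        assert rep.total_count == 0
        assert rep.degenerate_flags

    def test_two_strategy_two_player_games_never_cross(self, rng):
        # ranking invariance for 2x2 imitation dynamics, both rules
        for _ in range(100):
            game = MatrixGame(rng.uniform(size=(2, 2)))
            for rule in (fermi_rule(1.0), erf_rule(1.0)):
                _, rep = rank_change_report(game, rule, 50, refine=False)
                assert rep.total_count == 0

    def test_refinement_brackets_verified(self, rng):
        # find a game with a crossing, refine, and re-verify the sign
        # change around beta_star with fresh stationary solves
        for seed in range(100):
            g = MatrixGame(np.random.default_rng(seed).uniform(size=(3, 3)))
            curve, rep = rank_change_report(g, fermi_rule(1.0), 50, refine=True)
            if rep.total_count == 0:
                continue
            ev = abundance_evaluator(g, fermi_rule(1.0), 50)
            for e in rep.events:
                assert e.bracket[0] < e.beta_star < e.bracket[1]
                i, j = e.pair
                lo = ev(e.beta_star * 0.999)
                hi = ev(e.beta_star * 1.001)
                assert np.sign(lo[i] - lo[j]) != np.sign(hi[i] - hi[j])
            return
        pytest.fail("no crossing game found in 100 seeds")

    def test_count_invariant_under_relabeling_and_shift(self, rng):
        for seed in range(40):
            g = MatrixGame(np.random.default_rng(seed).uniform(size=(3, 3)))
            _, rep = rank_change_report(g, fermi_rule(1.0), 30, refine=False)
            if rep.total_count == 0:
                continue
            perm = rng.permutation(3)
            _, rep_p = rank_change_report(
                g.permuted(perm), fermi_rule(1.0), 30, refine=False
            )
            _, rep_s = rank_change_report(
                MatrixGame(g.payoffs + 11.0), fermi_rule(1.0), 30, refine=False
            )
            assert rep_p.total_count == rep.total_count
            assert rep_s.total_count == rep.total_count
            return
        pytest.fail("no crossing game found")

    def test_dense_grid_confirms_counts(self):
        agree = 0
        for seed in range(30):
            g = MatrixGame(np.random.default_rng(seed).uniform(size=(3, 3)))
            curve, rep = rank_change_report(g, fermi_rule(1.0), 50, refine=False)
            dense = curve.grid.refined(10)
            rep_dense = detect_crossings(sweep(g, fermi_rule(1.0), 50, dense))
            agree += rep.total_count == rep_dense.total_count
        assert agree >= 29


class TestSearches:
    def test_rule_sensitive_search_finds_and_self_verifies(self):
        rng = np.random.default_rng(7)
        res = find_rule_sensitive_game(rng, d=3, attempts=2000, N=50)
        assert res.found
        table = res.game
        # self-verification on a 10x denser grid
        for rule, expect_events in ((fermi_rule(1.0), False), (erf_rule(1.0), True)):
            bmax = study_beta_max(table, rule, res.N)
            dense = BetaGrid.log(1e-3, bmax, 2000)
            rep = detect_crossings(sweep(table, rule, res.N, dense))
            assert (rep.total_count >= 1) == expect_events

    def test_rule_sensitive_search_reproducible(self):
        r1 = find_rule_sensitive_game(np.random.default_rng(7), attempts=2000)
        r2 = find_rule_sensitive_game(np.random.default_rng(7), attempts=2000)
        assert r1.attempts_used == r2.attempts_used
        np.testing.assert_array_equal(r1.game.a, r2.game.a)

    def test_rule_sensitive_search_empty_for_two_player_games(self):
        rng = np.random.default_rng(5)
        res = find_rule_sensitive_game(rng, d=2, attempts=300, N=50)
        assert not res.found

    def test_intermediate_search_finds_and_self_verifies(self):
        rng = np.random.default_rng(11)
        res = find_intermediate_crossing_game(rng, n=3, attempts=2000, N=100)
        assert res.found
        game = res.game
        rule = fermi_rule(1.0)
        bmax = study_beta_max(game, rule, res.N)
        dense = BetaGrid.log(1e-3, bmax, 2000)
        curve = sweep(game, rule, res.N, dense)
        rep = detect_crossings(curve)
        assert rep.total_count >= 2
        # ordering at both ends of the dense grid equals the weak ranking
        from selrank import weak_selection_ranking

        weak = weak_selection_ranking(game, rule, res.N)
        end = tuple(int(i) for i in np.argsort(-curve.x[-1], kind="stable"))
        assert end == weak.order
        # crossings of different pairs happen at distinct locations
        stars = [e.beta_star for e in rep.events]
        assert len(set(np.round(np.log(stars), 3))) == len(stars)

    def test_intermediate_search_reproducible(self):
        r1 = find_intermediate_crossing_game(np.random.default_rng(11), attempts=2000)
        r2 = find_intermediate_crossing_game(np.random.default_rng(11), attempts=2000)
        assert r1.attempts_used == r2.attempts_used
        np.testing.assert_array_equal(r1.game.payoffs, r2.game.payoffs)
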