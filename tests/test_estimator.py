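"""Coordinate-descent estimation: steps, full fits, model selection."""

import warnings

import numpy as np
import pytest

from ultrafa import (
    FitConfig,
    UFAParams,
    brute_force_fit,
    fit,
    fit_pdfa,
    generate_sigma,
    generate_structure,
    implied_correlation,
    initialize,
    perturb,
    recovery_report,
    select_q,
    update_assignment,
    update_hierarchy,
    update_loadings,
    update_psi,
)
from ultrafa.estimator import _evaluate, _r_logdet, _state_from_params
from ultrafa.model import PSI_FLOOR


def objective(params: UFAParams, r: np.ndarray) -> float:
    idx, tree = _state_from_params(params)
    return _evaluate(r, idx, tree, _r_logdet(r))[2]


class TestInitialize:
    def test_seeded_runs_are_identical(self, planted_12_3):
        _, sigma = planted_12_3
        p1 = initialize(sigma, 3, rng=42)
        p2 = initialize(sigma, 3, rng=42)
        assert p1.hierarchy == p2.hierarchy
        np.testing.assert_array_equal(p1.increments, p2.increments)

    def test_psi_is_one_minus_communality(self, planted_12_3):
        _, sigma = planted_12_3
        p = initialize(sigma, 3, rng=0)
        np.testing.assert_allclose(p.psi, 1.0 - p.communalities(), atol=1e-12)
        assert np.all(p.psi > 0) and np.all(p.psi <= 1)

    def test_true_partition_attains_zero_discrepancy(self, planted_12_3):
        truth, sigma = planted_12_3
        p = initialize(sigma, 3, assignment=truth.hierarchy.assignment)
        assert objective(p, sigma.values) < 1e-10

    @pytest.mark.parametrize("q", [1, 13])
    def test_invalid_q_rejected(self, planted_12_3, q):
        with pytest.raises(ValueError):
            initialize(planted_12_3[1], q)


class TestUpdateAssignment:
    def test_restores_planted_partition_after_misassignment(self, planted_12_3):
        truth, sigma = planted_12_3
        wrong = truth.hierarchy.assignment.copy()
        movable = np.nonzero(np.bincount(wrong)[wrong] > 1)[0][0]
        wrong[movable] = wrong[movable] % 3 + 1
        p = initialize(sigma, 3, assignment=wrong)
        p2 = update_assignment(p, sigma)
        from ultrafa import adjusted_rand

        assert adjusted_rand(p2.hierarchy.assignment, truth.hierarchy.assignment) == 1.0

    def test_optimal_assignment_is_a_fixed_point(self, planted_12_3):
        truth, sigma = planted_12_3
        p = initialize(sigma, 3, assignment=truth.hierarchy.assignment)
        p2 = update_assignment(p, sigma)
        np.testing.assert_array_equal(p2.hierarchy.assignment,
                                      p.hierarchy.assignment)

    def test_approximate_mode_never_increases_discrepancy(self, rng):
        for k in range(20):
            truth = generate_structure(10, 3, rng)
            r = perturb(generate_sigma(truth), 0.2, rng)
            p = initialize(r, 3, rng=k)
            before = objective(p, r.values)
            after = objective(update_assignment(p, r, exact=False), r.values)
            assert after <= before + 1e-12

    def test_never_increases_discrepancy(self, rng):
        for k in range(40):
            truth = generate_structure(10, 3, rng)
            r = perturb(generate_sigma(truth), 0.2, rng)
            p = initialize(r, 3, rng=k)
            before = objective(p, r.values)
            after = objective(update_assignment(p, r), r.values)
            assert after <= before + 1e-12


class TestUpdateHierarchy:
    def test_q2_single_forced_merge(self, rng):
        truth = generate_structure(8, 2, rng)
        sigma = generate_sigma(truth)
        p = initialize(sigma, 2, rng=0)
        assert update_hierarchy(p, sigma).hierarchy.merges == ((1, 2),)

    def test_first_merge_joins_most_correlated_groups(self, planted_12_3):
        truth, sigma = planted_12_3
        p = initialize(sigma, 3, assignment=truth.hierarchy.assignment)
        p2 = update_hierarchy(p, sigma)
        # the greedy first merge must pick the pair with the largest between level
        from ultrafa import extract_levels

        levels = extract_levels(sigma, truth.hierarchy)
        first = p2.hierarchy.merges[0]
        pair_level = {}
        for a in range(1, 4):
            for b in range(a + 1, 4):
                mask_a = truth.hierarchy.assignment == a
                mask_b = truth.hierarchy.assignment == b
                pair_level[(a, b)] = sigma.values[np.ix_(mask_a, mask_b)].mean()
        assert pair_level[first] == max(pair_level.values())

    def test_matches_brute_force_trees_on_exact_inputs(self, rng):
        for seed in range(5):
            truth = generate_structure(9, 3, rng=300 + seed)
            sigma = generate_sigma(truth)
            p = initialize(sigma, 3, assignment=truth.hierarchy.assignment)
            p2 = update_hierarchy(p, sigma)
            f_greedy = objective(p2, sigma.values)
            f_best, _ = brute_force_fit(sigma, 3)
            assert f_greedy == pytest.approx(f_best, abs=1e-8)


class TestUpdateLoadings:
    def test_exact_input_recovers_generating_levels(self, planted_12_3):
        truth, sigma = planted_12_3
        p = initialize(sigma, 3, assignment=truth.hierarchy.assignment)
        p2 = update_loadings(p, sigma)
        true_levels = truth.levels()
        est = p2.canonical().levels()
        truth_c = truth.canonical().levels()
        np.testing.assert_allclose(est.within, truth_c.within, atol=1e-10)
        np.testing.assert_allclose(est.between, truth_c.between, atol=1e-10)

    def test_projection_always_yields_valid_levels(self, rng):
        for _ in range(100)[:100]:
            j_n = int(rng.integers(6, 15))
            q = int(rng.integers(2, 5))
            from ultrafa import psd_repair

            r = rng.uniform(0, 1, size=(j_n, j_n))
            r = 0.5 * (r + r.T)
            np.fill_diagonal(r, 1.0)
            r = psd_repair(r, ridge=1e-6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = initialize(np.eye(j_n), q, rng=int(rng.integers(2 ** 31)))
                p2 = update_loadings(p, r)
            assert p2.levels().validate(p2.hierarchy) == []

    def test_equal_cross_block_means_flatten_the_tree(self):
        # three groups with equal pairwise between correlation: all merge
        # increments below the root collapse to zero
        from ultrafa import Hierarchy, UltrametricValues, compose_ultrametric

        h = Hierarchy([1, 1, 2, 2, 3, 3], [(1, 2), (3, 4)])
        values = UltrametricValues([0.7, 0.7, 0.7], [0.3, 0.3])
        sigma = compose_ultrametric(h, values)
        p = initialize(sigma, 3, assignment=h.assignment)
        p2 = update_loadings(p, sigma)
        np.testing.assert_allclose(p2.levels().between, [0.3, 0.3], atol=1e-12)
        assert p2.increments[3] == pytest.approx(0.0, abs=1e-12)  # first merge
        assert p2.increments[4] == pytest.approx(0.3, abs=1e-12)  # root carries it all


class TestUpdatePsi:
    def test_psi_is_complement_of_path_sum(self, planted_12_3):
        truth, _ = planted_12_3
        p2 = update_psi(truth)
        np.testing.assert_allclose(p2.psi, 1.0 - truth.communalities(), atol=1e-12)

    def test_heywood_floor_and_warning(self, two_group_hierarchy):
        p = UFAParams(two_group_hierarchy, [0.7, 0.6, 0.3], [1e-6, 1e-6, 0.1, 0.1])
        with pytest.warns(UserWarning, match="Heywood"):
            p2 = update_psi(p)
        assert np.all(p2.psi >= PSI_FLOOR)


class TestFit:
    def test_exact_recovery_on_planted_structure(self, planted_12_3):
        truth, sigma = planted_12_3
        res = fit(sigma, FitConfig(q=3, n_starts=10, seed=1))
        assert res.discrepancy < 1e-8
        report = recovery_report(truth, res.params)
        assert report.perfect_tree
        assert report.rmse < 1e-8

    def test_monotone_trace_and_determinism(self, planted_12_3):
        truth, sigma = planted_12_3
        r = perturb(sigma, 0.1, rng=3)
        res1 = fit(r, FitConfig(q=3, n_starts=5, seed=11))
        res2 = fit(r, FitConfig(q=3, n_starts=5, seed=11))
        assert res1.discrepancy == res2.discrepancy
        assert res1.params.hierarchy == res2.params.hierarchy
        assert all(a >= b - 1e-12 for a, b in zip(res1.trace, res1.trace[1:]))

    def test_more_starts_never_worse(self, planted_12_3):
        _, sigma = planted_12_3
        r = perturb(sigma, 0.05, rng=5)
        f1 = fit(r, FitConfig(q=3, n_starts=1, seed=2)).discrepancy
        f50 = fit(r, FitConfig(q=3, n_starts=50, seed=2)).discrepancy
        assert f50 <= f1 + 1e-12

    def test_label_switching_invariance(self, planted_12_3):
        _, sigma = planted_12_3
        res = fit(sigma, FitConfig(q=3, n_starts=5, seed=4))
        canon = res.params.canonical()
        np.testing.assert_allclose(
            implied_correlation(res.params).values,
            implied_correlation(canon).values,
            atol=1e-12,
        )

    def test_few_iterations_on_low_noise_input(self, planted_12_3):
        _, sigma = planted_12_3
        r = perturb(sigma, 0.05, rng=9)
        res = fit(r, FitConfig(q=3, n_starts=10, seed=0))
        assert res.converged
        assert res.n_iterations < 10

    def test_non_psd_input_repaired_with_warning(self):
        # near-perfect correlations with one zero pair violate the triangle
        # inequality, so the matrix is indefinite
        bad = np.full((6, 6), 0.95)
        np.fill_diagonal(bad, 1.0)
        bad[0, 5] = bad[5, 0] = 0.0
        assert np.linalg.eigvalsh(bad)[0] < 0
        with pytest.warns(UserWarning, match="repair"):
            fit(bad, FitConfig(q=3, n_starts=2, seed=0))
        with pytest.raises(ValueError):
            fit(bad, FitConfig(q=3, n_starts=2, seed=0, strict=True))

    def test_negative_correlations_rejected_unless_allowed(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = -0.3
        with pytest.raises(ValueError, match="negative"):
            fit(r, FitConfig(q=2, n_starts=2, seed=0))
        with pytest.warns(UserWarning, match="negative"):
            fit(r, FitConfig(q=2, n_starts=2, seed=0, allow_negative=True))

    def test_oracle_equivalence_small_problems(self):
        for j_n, q, seed in [(6, 2, 0), (7, 3, 1), (8, 3, 2)]:
            truth = generate_structure(j_n, q, rng=50 + seed)
            sigma = generate_sigma(truth)
            f_fit = fit(sigma, FitConfig(q=q, n_starts=10, seed=seed)).discrepancy
            f_oracle, _ = brute_force_fit(sigma, q)
            assert f_fit == pytest.approx(f_oracle, abs=1e-8)


class TestPDFA:
    def test_pdfa_never_beats_ufa(self, rng):
        for k in range(10):
            truth = generate_structure(10, 3, rng)
            r = perturb(generate_sigma(truth), 0.15, rng)
            cfg = FitConfig(q=3, n_starts=5, seed=k)
            assert fit_pdfa(r, cfg).discrepancy >= fit(r, cfg).discrepancy - 1e-10

    def test_block_diagonal_truth_gives_zero_between(self, rng):
        from ultrafa import Hierarchy, UltrametricValues, compose_ultrametric

        h = Hierarchy([1, 1, 1, 2, 2, 2, 3, 3, 3], [(1, 2), (3, 4)])
        values = UltrametricValues([0.7, 0.6, 0.5], [0.0, 0.0])
        sigma = compose_ultrametric(h, values)
        cfg = FitConfig(q=3, n_starts=10, seed=0)
        res_ufa = fit(sigma, cfg)
        res_pdfa = fit_pdfa(sigma, cfg)
        assert abs(res_ufa.discrepancy - res_pdfa.discrepancy) < 1e-8
        assert np.all(res_ufa.params.levels().between < 1e-8)

    def test_constrained_fit_keeps_pdfa_partition(self, planted_12_3):
        _, sigma = planted_12_3
        r = perturb(sigma, 0.15, rng=8)
        cfg = FitConfig(q=3, n_starts=10, seed=3)
        pdfa = fit_pdfa(r, cfg)
        constrained = fit(r, FitConfig(q=3, n_starts=10, seed=3, constrained=True))
        np.testing.assert_array_equal(
            constrained.params.hierarchy.assignment,
            pdfa.params.hierarchy.assignment,
        )
        assert constrained.diagnostics["pdfa_discrepancy"] == pytest.approx(
            pdfa.discrepancy
        )


class TestSelectQ:
    def test_recovers_generating_q_at_low_noise(self):
        truth = generate_structure(16, 4, rng=21)
        r = perturb(generate_sigma(truth), 0.05, rng=22)
        sel = select_q(r, range(2, 7), FitConfig(q=2, n_starts=10, seed=1, n=200))
        assert sel.chosen_q == 4
        assert set(sel.table["Q"]) == {2, 3, 4, 5, 6}

    def test_all_three_optima_reported(self, planted_12_3):
        _, sigma = planted_12_3
        r = perturb(sigma, 0.1, rng=2)
        sel = select_q(r, [2, 3], FitConfig(q=2, n_starts=5, seed=0, n=100))
        assert set(sel.best) == {"aic", "bic", "agfi"}

    def test_requires_n(self, planted_12_3):
        with pytest.raises(ValueError, match="n"):
            select_q(planted_12_3[1], [2, 3], FitConfig(q=2, n_starts=2, seed=0))
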