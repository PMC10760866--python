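"""Model 1: transfer kernel, replication mechanics, dilution, fitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dadsim import lattice_model as lm


# ---------------------------------------------------------------- kernel

class TestTransferKernel:
    def test_zero_distance_unit_prefactor(self):
        # At x=0 and 4*D*T = 1/pi the Gaussian weight is exactly 1.
        k = lm.build_transfer_kernel(np.zeros((1, 1)), 1.0 / (4 * np.pi), 1.0)
        assert k.weights[0, 0] == pytest.approx(1.0)

    def test_two_row_kernel_matches_hand_evaluation(self):
        # R=2, DT=0.25: w(0)/[w(0)+w(1)] = 1 / (1 + e^{-1}).
        k = lm.build_transfer_kernel(lm.lattice_distances(2), 0.25, 1.0)
        expected = 1.0 / (1.0 + np.exp(-1.0))
        assert k.probabilities[0, 0] == pytest.approx(expected, abs=1e-12)
        assert k.probabilities[1, 1] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n_rows,dt", [(3, 0.1), (9, 0.5), (20, 1.2), (20, 0.07)])
    def test_rows_sum_to_one(self, n_rows, dt):
        k = lm.build_transfer_kernel(lm.lattice_distances(n_rows), dt, 1.0)
        assert np.abs(k.probabilities.sum(axis=1) - 1.0).max() < 1e-12
        assert (k.probabilities >= 0).all()

    def test_weights_symmetric_for_symmetric_distances(self):
        k = lm.build_transfer_kernel(lm.lattice_distances(7), 0.3, 1.0)
        np.testing.assert_allclose(k.weights, k.weights.T)

    def test_vanishing_diffusion_gives_identity(self):
        k = lm.build_transfer_kernel(lm.lattice_distances(5), 1e-8, 1.0)
        np.testing.assert_allclose(k.probabilities, np.eye(5), atol=1e-12)

    def test_only_product_dt_matters(self):
        x = lm.lattice_distances(6)
        a = lm.build_transfer_kernel(x, 0.8, 0.5)
        b = lm.build_transfer_kernel(x, 0.4, 1.0)
        np.testing.assert_allclose(a.probabilities, b.probabilities)

    @pytest.mark.parametrize("bad", [
        np.ones((2, 3)),                       # not square
        -np.ones((2, 2)) + np.eye(2),          # negative off-diagonal
        np.array([[0.0, 1.0], [2.0, 0.0]]),    # asymmetric
        np.ones((2, 2)),                       # nonzero diagonal
    ])
    def test_invalid_distances_rejected(self, bad):
        with pytest.raises(ValueError):
            lm.build_transfer_kernel(bad, 1.0, 1.0)

    @pytest.mark.parametrize("d,t", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_invalid_parameters_rejected(self, d, t):
        with pytest.raises(ValueError):
            lm.build_transfer_kernel(lm.lattice_distances(3), d, t)

    @given(n_rows=st.integers(2, 12),
           log_dt=st.floats(-3, 1))
    @settings(max_examples=30, deadline=None)
    def test_row_stochastic_property(self, n_rows, log_dt):
        k = lm.build_transfer_kernel(lm.lattice_distances(n_rows), 10.0 ** log_dt)
        assert np.abs(k.probabilities.sum(axis=1) - 1.0).max() < 1e-12


# ------------------------------------------------------------- replication

class TestReplication:
    def test_identity_kernel_preserves_positions(self, rng):
        parent = lm.ChromatinLattice.initialize(6, 10, 2)
        kernel = lm.build_transfer_kernel(lm.lattice_distances(6), 1e-9)
        d1, d2 = lm.replicate_once(parent, kernel, rng)
        merged = d1.grid.astype(int) + d2.grid.astype(int)
        np.testing.assert_array_equal(merged, parent.grid)

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_per_column_conservation(self, seed):
        rng = np.random.default_rng(seed)
        parent = lm.ChromatinLattice.initialize(9, 20, 4)
        kernel = lm.build_transfer_kernel(lm.lattice_distances(9), 0.5)
        d1, d2 = lm.replicate_once(parent, kernel, rng)
        for grid_state in (lm.HISTONE, lm.TAGGED_HISTONE):
            parent_counts = (parent.grid == grid_state).sum(axis=0)
            daughter_counts = ((d1.grid == grid_state).sum(axis=0)
                               + (d2.grid == grid_state).sum(axis=0))
            np.testing.assert_array_equal(daughter_counts, parent_counts)

    def test_dimension_mismatch_rejected(self, rng):
        parent = lm.ChromatinLattice.initialize(4, 5, 0)
        kernel = lm.build_transfer_kernel(lm.lattice_distances(5), 0.5)
        with pytest.raises(ValueError):
            lm.replicate_once(parent, kernel, rng)

    def test_single_column_matches_exhaustive_enumeration(self):
        """R=2, one column, both rows occupied: empirical placement law vs
        brute-force enumeration of orders and restricted resampling."""
        dt = 0.25
        kernel = lm.build_transfer_kernel(lm.lattice_distances(2), dt)
        k = kernel.probabilities

        # Enumerate: histones A (row 0) and B (row 1), processed in a
        # uniformly random order; the first samples a site from the product
        # measure (1/2 daughter x kernel row); the second samples from the
        # same measure restricted to the three free sites, renormalized
        # (pure rejection sampling conditions on avoiding the occupied
        # site).  Sites are (daughter, row) flattened as d*2 + r.
        def site_probs(row):
            return {d * 2 + r: 0.5 * k[row, r] for d in (0, 1) for r in (0, 1)}

        exact = {}
        for order in ((0, 1), (1, 0)):
            first, second = order
            p_first = site_probs(first)
            p_second_all = site_probs(second)
            for s1, p1 in p_first.items():
                rest = {s: p for s, p in p_second_all.items() if s != s1}
                z = sum(rest.values())
                for s2, p2 in rest.items():
                    key = (s1, s2) if first == 0 else (s2, s1)
                    exact[key] = exact.get(key, 0.0) + 0.5 * p1 * (p2 / z)

        n_trials = 100_000
        rng = np.random.default_rng(99)
        counts = {}
        parent = lm.ChromatinLattice(
            grid=np.array([[lm.HISTONE], [lm.TAGGED_HISTONE]]), tagged_row=1
        )
        for _ in range(n_trials):
            d1, d2 = lm.replicate_once(parent, kernel, rng)
            stacked = np.concatenate([d1.grid[:, 0], d2.grid[:, 0]])
            s_a = int(np.flatnonzero(stacked == lm.HISTONE)[0])
            s_b = int(np.flatnonzero(stacked == lm.TAGGED_HISTONE)[0])
            counts[(s_a, s_b)] = counts.get((s_a, s_b), 0) + 1

        assert abs(sum(exact.values()) - 1.0) < 1e-12
        for key, p in exact.items():
            observed = counts.get(key, 0) / n_trials
            se = np.sqrt(p * (1 - p) / n_trials)
            assert abs(observed - p) < 3 * se + 1e-9, (key, observed, p)


class TestFillAndSelect:
    def test_no_empty_sites_after_fill(self, rng):
        parent = lm.ChromatinLattice.initialize(5, 8, 2)
        kernel = lm.build_transfer_kernel(lm.lattice_distances(5), 0.5)
        d1, d2 = lm.replicate_once(parent, kernel, rng)
        chosen = lm.fill_and_select(d1, d2, rng)
        assert (chosen.grid != lm.EMPTY).all()

    def test_selection_reproducible(self):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            parent = lm.ChromatinLattice.initialize(5, 8, 2)
            kernel = lm.build_transfer_kernel(lm.lattice_distances(5), 0.5)
            d1, d2 = lm.replicate_once(parent, kernel, rng)
            out.append(lm.fill_and_select(d1, d2, rng).grid.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_daughter_choice_is_fair(self):
        rng = np.random.default_rng(3)
        n = 10_000
        picks = 0
        for _ in range(n):
            d1 = lm.ChromatinLattice(np.full((1, 1), lm.HISTONE), 0)
            d2 = lm.ChromatinLattice(np.full((1, 1), lm.TAGGED_HISTONE), 0)
            chosen = lm.fill_and_select(d1, d2, rng)
            picks += int(chosen.grid[0, 0] == lm.HISTONE)
        se = np.sqrt(0.25 / n)
        assert abs(picks / n - 0.5) < 3 * se


# ---------------------------------------------------------------- dilution

class TestDilution:
    def test_generation_zero_is_one(self):
        curve = lm.simulate_dilution(5, 10, 2, 0.3, 3, 10, seed=0)
        assert curve.mean_fraction[0] == 1.0

    def test_halving_law_without_diffusion(self):
        # With an identity kernel the tagged row survives intact into the
        # chosen daughter with probability 1/2 per cycle: E f(g) = 2^-g.
        curve = lm.simulate_dilution(9, 50, 4, 1e-9, 3, 500, seed=11)
        expected = 0.5 ** curve.generations
        se = curve.sd / np.sqrt(curve.n_replicates)
        assert np.all(np.abs(curve.mean_fraction - expected) <= 3 * se + 1e-12)

    def test_simulation_agrees_with_expectation_oracle(self):
        kernel = lm.build_transfer_kernel(lm.lattice_distances(9), 0.5)
        oracle = lm.expected_dilution_oracle(kernel, 4, 6)
        curve = lm.simulate_dilution(9, 50, 4, 0.5, 6, 2000, seed=7)
        se = curve.sd / np.sqrt(curve.n_replicates)
        # Site exclusion biases the simulation upward by a few percent;
        # tolerance is 5% relative plus Monte-Carlo error.
        tol = 0.05 * oracle + 3 * se
        assert np.all(np.abs(curve.mean_fraction - oracle) <= tol)

    def test_reproducible_bit_exact(self):
        a = lm.simulate_dilution(6, 12, 3, 0.4, 4, 20, seed=42)
        b = lm.simulate_dilution(6, 12, 3, 0.4, 4, 20, seed=42)
        np.testing.assert_array_equal(a.mean_fraction, b.mean_fraction)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            lm.simulate_dilution(0, 10, 0, 0.5, 3, 5, seed=0)


class TestExpectationOracle:
    def test_initial_value(self):
        kernel = lm.build_transfer_kernel(lm.lattice_distances(4), 0.5)
        assert lm.expected_dilution_oracle(kernel, 1, 0)[0] == 1.0

    def test_identity_kernel_halving(self):
        kernel = lm.build_transfer_kernel(lm.lattice_distances(4), 1e-9)
        out = lm.expected_dilution_oracle(kernel, 2, 3)
        np.testing.assert_allclose(out, [1.0, 0.5, 0.25, 0.125], atol=1e-9)

    def test_matches_explicit_matrix_power(self):
        # Independent reconstruction: build the 3x3 kernel by hand and
        # propagate the expected tagged-count vector two generations.
        dt = 0.25
        x = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        w = np.exp(-(x ** 2) / (4 * dt)) / np.sqrt(4 * np.pi * dt)
        p = w / w.sum(axis=1, keepdims=True)
        v = np.array([0.0, 1.0, 0.0])
        for _ in range(2):
            v = 0.5 * p.T @ v
        kernel = lm.build_transfer_kernel(x, dt)
        out = lm.expected_dilution_oracle(kernel, 1, 2)
        assert out[2] == pytest.approx(v[1], rel=1e-12)

    def test_non_increasing_and_faster_decay_with_dt(self):
        prev = None
        for dt in (0.05, 0.2, 0.8, 3.0):
            kernel = lm.build_transfer_kernel(lm.lattice_distances(9), dt)
            out = lm.expected_dilution_oracle(kernel, 4, 6)
            assert np.all(np.diff(out) <= 1e-15)
            if prev is not None:
                assert np.all(out <= prev + 1e-12)
            prev = out


# ----------------------------------------------------------------- fitting

class TestFitDiffusionConstant:
    def test_recovers_oracle_generated_curve(self):
        from dadsim.synthetic_data import synth_dilution_curve

        observed = synth_dilution_curve(1.2, 9, 50, 4, 6, noise_sd=0.0, seed=0)
        result = lm.fit_diffusion_constant(observed, 9, 50, 4,
                                           search_interval=(1e-3, 10.0))
        assert result.diffusion_constant == pytest.approx(1.2, rel=0.10)

    def test_halving_curve_hits_lower_edge(self):
        curve = lm.DilutionCurve(
            generations=np.arange(7),
            mean_fraction=0.5 ** np.arange(7),
            sd=np.zeros(7),
            n_replicates=1,
        )
        result = lm.fit_diffusion_constant(curve, 9, 50, 4,
                                           search_interval=(1e-3, 10.0))
        assert result.diffusion_constant == pytest.approx(1e-3)

    def test_recovers_simulated_curve(self):
        observed = lm.simulate_dilution(9, 50, 4, 0.07, 6, 500, seed=21)
        result = lm.fit_diffusion_constant(observed, 9, 50, 4,
                                           search_interval=(1e-3, 10.0))
        assert result.diffusion_constant == pytest.approx(0.07, rel=0.25)

    def test_short_curve_rejected(self):
        curve = lm.DilutionCurve(generations=[0, 1], mean_fraction=[1.0, 0.5],
                                 sd=[0, 0], n_replicates=1)
        with pytest.raises(ValueError):
            lm.fit_diffusion_constant(curve, 9, 50, 4)


class TestDadSizeEstimate:
    def test_headline_value(self):
        # D = 10 um^2/s for ~1 s of diffusion: sqrt(60) = 7.75 um, i.e.
        # ~8 um at one significant figure.
        assert lm.dad_size_estimate(10.0, 1.0) == pytest.approx(np.sqrt(60.0))
        assert round(lm.dad_size_estimate(10.0, 1.0)) == 8

    def test_algebraic_identity(self):
        assert lm.dad_size_estimate(1.0 / 6.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("d,t", [(6.0, 0.0), (0.0, 1.0), (-1.0, 1.0)])
    def test_non_positive_inputs_rejected(self, d, t):
        with pytest.raises(ValueError):
            lm.dad_size_estimate(d, t)
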