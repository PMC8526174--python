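"""SER cellular automaton: update rules, rasters and counting matrices."""

import numpy as np
import pytest

from netdyn.ser import (
    E,
    R,
    S,
    SERParams,
    coactivation_matrix,
    sequential_matrix,
    ser_ensemble_fc,
    ser_init,
    ser_run,
    ser_step,
)


def ring(n):
    A = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1
    return A


class TestInit:
    def test_excited_count_rounds_half_up(self, rng):
        x = ser_init(60, 0.06, rng)  # round(3.6) = 4
        assert (x == E).sum() == 4

    def test_excited_count_exact_fraction(self, rng):
        x = ser_init(100, 0.06, rng)
        assert (x == E).sum() == 6

    def test_susceptible_refractory_equiprobable(self, rng):
        counts_s, counts_r = [], []
        for _ in range(1000):
            x = ser_init(60, 0.06, rng)
            counts_s.append((x == S).sum())
            counts_r.append((x == R).sum())
        # 56 non-excited nodes split S/R with p = 1/2 each
        assert np.mean(counts_s) == pytest.approx(28, abs=0.7)
        assert np.mean(counts_r) == pytest.approx(28, abs=0.7)

    def test_at_least_one_excited(self, rng):
        x = ser_init(5, 0.01, rng)
        assert (x == E).sum() == 1

    def test_empty_graph_rejected(self, rng):
        with pytest.raises(ValueError):
            ser_init(0, 0.06, rng)


class TestStep:
    def test_excited_becomes_refractory(self, rng):
        A = ring(4)
        x = np.array([E, S, S, S], dtype=np.int8)
        out = ser_step(x, A, SERParams(f=0.0, p=0.0), rng)
        assert out[0] == R

    def test_susceptible_excited_by_neighbour(self, rng):
        A = ring(4)
        x = np.array([E, S, S, S], dtype=np.int8)
        out = ser_step(x, A, SERParams(f=0.0, p=0.0), rng)
        assert out[1] == E and out[3] == E  # both ring neighbours of node 0
        assert out[2] == S  # not adjacent to the excited node

    def test_refractory_recovery_degenerate_probabilities(self, rng):
        A = ring(4)
        x = np.array([R, R, R, R], dtype=np.int8)
        assert (ser_step(x, A, SERParams(f=0.0, p=1.0), rng) == S).all()
        assert (ser_step(x, A, SERParams(f=0.0, p=0.0), rng) == R).all()

    def test_spontaneous_excitation_only_from_susceptible(self, rng):
        A = ring(4)
        x = np.array([S, R, S, R], dtype=np.int8)
        out = ser_step(x, A, SERParams(f=1.0, p=0.0), rng)
        assert out[0] == E and out[2] == E
        assert out[1] == R and out[3] == R  # f never excites refractory nodes


def run_deterministic_wave():
    """Ring of 5, single seed, p=1, f=0: the excitation wave hand trace."""
    A = ring(5)
    params = SERParams(f=0.0, p=1.0, t_max=4, n_runs=1)
    x = np.array([E, S, S, S, S], dtype=np.int8)
    raster = np.zeros((5, 5), dtype=np.int8)
    raster[:, 0] = x == E
    rng = np.random.default_rng(0)
    for t in range(1, 5):
        x = ser_step(x, A, params, rng)
        raster[:, t] = x == E
    return raster


class TestRun:
    def test_deterministic_wave_each_node_fires_once(self):
        # t1: both seed neighbours; t2: the remaining two; t3: extinct
        raster = run_deterministic_wave()
        assert (raster.sum(axis=1) == 1).all()
        assert raster[:, 3].sum() == 0 and raster[:, 4].sum() == 0
        assert set(np.flatnonzero(raster[:, 1])) == {1, 4}
        assert set(np.flatnonzero(raster[:, 2])) == {2, 3}

    def test_no_spontaneous_source_stays_silent(self, rng):
        A = ring(6)
        params = SERParams(f=0.0, p=1.0, t_max=8, n_runs=1)
        # manual all-S start: step the automaton directly
        x = np.full(6, S, dtype=np.int8)
        for _ in range(8):
            x = ser_step(x, A, params, rng)
            assert (x != E).all()

    def test_forced_excitation_cycles_with_period_three(self, rng):
        # f=1, p=1 from all-S: each update applies exactly one transition,
        # so the lockstep cycle is E -> R -> S -> E ... (period 3)
        A = ring(6)
        params = SERParams(f=1.0, p=1.0, t_max=6, n_runs=1)
        x = np.full(6, S, dtype=np.int8)
        expected = [E, R, S, E, R, S]
        for want in expected:
            x = ser_step(x, A, params, rng)
            assert (x == want).all()

    def test_run_shape_and_initial_column(self, modular_graph, rng):
        params = SERParams(t_max=10, n_runs=1)
        raster = ser_run(modular_graph, params, rng)
        assert raster.shape == (60, 11)
        assert raster[:, 0].sum() == 4  # round(0.06 * 60)

    def test_excited_always_refractory_next_step(self, modular_graph):
        # simulate with state tracking: every excitation is followed by R
        params = SERParams(f=0.01, p=0.3, t_max=15, n_runs=1)
        rng = np.random.default_rng(99)
        x = ser_init(60, 0.06, rng)
        for _ in range(15):
            prev = x
            x = ser_step(x, modular_graph, params, rng)
            assert (x[prev == E] == R).all()


class TestCountingMatrices:
    def test_coactivation_small_example(self):
        raster = np.array([[1, 0, 1], [1, 1, 0]])
        C = coactivation_matrix(raster)
        assert C[0, 1] == 1
        assert C[0, 0] == 2 and C[1, 1] == 2
        assert np.array_equal(C, C.T)

    def test_identical_rows_count_excitations(self):
        raster = np.tile(np.array([[1, 0, 1, 1]]), (2, 1))
        assert coactivation_matrix(raster)[0, 1] == 3

    def test_sequential_small_example(self):
        raster = np.array([[1, 0, 1], [1, 1, 0]])
        Sm = sequential_matrix(raster)
        # S_01 = c0(1)c1(0) + c0(2)c1(1) = 0 + 1
        assert Sm[0, 1] == 1
        # S_10 = c1(1)c0(0) + c1(2)c0(1) = 1 + 0
        assert Sm[1, 0] == 1

    def test_zero_raster_zero_matrices(self):
        raster = np.zeros((4, 6), dtype=int)
        assert coactivation_matrix(raster).sum() == 0
        assert sequential_matrix(raster).sum() == 0

    def test_wave_coactivation_pairs(self):
        raster = run_deterministic_wave()
        C = coactivation_matrix(raster)
        off = C - np.diag(np.diag(C))
        nz = {(i, j) for i, j in zip(*np.nonzero(off))}
        assert nz == {(1, 4), (4, 1), (2, 3), (3, 2)}

    def test_matrices_match_bruteforce_loops(self, rng):
        raster = (rng.random((8, 12)) < 0.3).astype(int)
        C = coactivation_matrix(raster)
        Sm = sequential_matrix(raster)
        n, T = raster.shape
        for i in range(n):
            for j in range(n):
                c_exp = sum(raster[i, t] * raster[j, t] for t in range(T))
                s_exp = sum(raster[i, t] * raster[j, t - 1] for t in range(1, T))
                assert C[i, j] == c_exp
                assert Sm[i, j] == s_exp

    def test_sequential_wave_orientation_matches_bruteforce(self):
        raster = run_deterministic_wave()
        Sm = sequential_matrix(raster)
        n, T = raster.shape
        for i in range(n):
            for j in range(n):
                expected = sum(
                    raster[i, t] * raster[j, t - 1] for t in range(1, T)
                )
                assert Sm[i, j] == expected
        # followers row, predecessors column: node 1 fired right after node 0
        assert Sm[1, 0] == 1 and Sm[0, 1] == 0


class TestEnsemble:
    def test_single_run_reduction(self, modular_graph):
        params = SERParams(t_max=5, n_runs=1)
        fc = ser_ensemble_fc(modular_graph, params, np.random.default_rng(5))
        raster = ser_run(modular_graph, params, np.random.default_rng(5))
        assert np.array_equal(fc.C, coactivation_matrix(raster))
        assert np.array_equal(fc.Sm, sequential_matrix(raster))

    def test_identical_seed_streams_double(self, modular_graph):
        params = SERParams(t_max=5, n_runs=1)
        one = ser_ensemble_fc(modular_graph, params, np.random.default_rng(6))
        two = ser_ensemble_fc(modular_graph, params, np.random.default_rng(6))
        assert np.array_equal(one.C + two.C, 2 * one.C)

    def test_counts_bounded_by_time_and_runs(self, modular_graph):
        params = SERParams(t_max=6, n_runs=20, f=0.05, p=0.5)
        fc = ser_ensemble_fc(modular_graph, params, np.random.default_rng(7))
        assert fc.C.max() <= (params.t_max + 1) * params.n_runs
        assert fc.Sm.max() <= params.t_max * params.n_runs
        assert fc.C.min() >= 0 and fc.Sm.min() >= 0

    def test_normalization_flag_rescales_only(self, modular_graph):
        raw = ser_ensemble_fc(
            modular_graph, SERParams(t_max=5, n_runs=10), np.random.default_rng(8)
        )
        norm = ser_ensemble_fc(
            modular_graph,
            SERParams(t_max=5, n_runs=10, normalized=True),
            np.random.default_rng(8),
        )
        assert np.allclose(norm.C, raw.C / 10)
        assert np.allclose(norm.Sm, raw.Sm / 10)
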