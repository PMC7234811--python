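"""Markov-model statistics: estimation, stationary, coarse-graining, MFPT,
bootstrap; oracles are the generating matrices, hand linear algebra, and
direct Monte-Carlo chain simulation."""

import numpy as np
import pandas as pd
import pytest

from kinbind import generate_discrete_trajectories
from kinbind.exceptions import (
    DisconnectedStateWarning,
    InsufficientDataError,
    InvalidStateError,
    ReducibleChainWarning,
)
from kinbind.msm import (
    bootstrap,
    coarse_grain,
    estimate_transition_matrix,
    lump,
    mfpt,
    mfpt_matrix,
    stationary,
)

T2 = np.array([[0.9, 0.1], [0.3, 0.7]])
T3 = np.array([[0.80, 0.15, 0.05],
               [0.10, 0.70, 0.20],
               [0.05, 0.25, 0.70]])


class TestEstimation:
    def test_constant_sequence_single_state(self):
        T = estimate_transition_matrix([[0, 0, 0, 0]])
        assert T.matrix.shape == (1, 1)
        assert T.matrix[0, 0] == 1.0

    def test_deterministic_alternation(self):
        T = estimate_transition_matrix([[0, 1, 0, 1, 0, 1]])
        assert np.array_equal(T.matrix, [[0.0, 1.0], [1.0, 0.0]])

    def test_long_trajectories_recover_generating_matrix(self):
        trajs = generate_discrete_trajectories(T3, 5, 40_000, seed=2)
        T = estimate_transition_matrix(trajs)
        assert np.max(np.abs(T.matrix - T3)) < 0.02

    def test_unvisited_state_gets_self_transition_and_warning(self):
        with pytest.warns(DisconnectedStateWarning):
            T = estimate_transition_matrix([[0, 1, 0, 1]], n_states=3)
        assert T.matrix[2, 2] == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_transition_matrix([])


class TestStationary:
    def test_symmetric_two_state(self):
        T = estimate_transition_matrix([[0, 1, 0, 1, 1, 0]])
        pi = stationary(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert np.allclose(pi, [0.5, 0.5])

    def test_hand_solved_balance(self):
        # 0.1 pi_1 = 0.3 pi_2  ->  pi = (0.75, 0.25)
        pi = stationary(T2)
        assert np.allclose(pi, [0.75, 0.25], atol=1e-12)

    def test_fixed_point_property(self):
        pi = stationary(T3)
        assert np.max(np.abs(pi @ T3 - pi)) < 1e-10
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identity_chain_warns_and_returns_empirical(self):
        T = estimate_transition_matrix([[0, 0, 0], [1, 1, 1, 1]], n_states=2)
        with pytest.warns(ReducibleChainWarning):
            pi = stationary(T)
        # empirical frequencies from the counts: 2 vs 3 observed transitions
        assert np.allclose(pi, [2 / 5, 3 / 5])


class TestCoarseGraining:
    def _helicity(self, har, nes):
        return pd.DataFrame({"microstate": np.arange(len(har)),
                             "har_helicity": har, "nes_helicity": nes})

    def test_quadrant_labels(self):
        a = coarse_grain(self._helicity([0.9, 0.1, 0.9, 0.1],
                                        [0.9, 0.9, 0.1, 0.1]))
        assert list(a.labels) == ["HLH", "CLH", "HLC", "CLC"]

    def test_uniform_pi_gives_quarter_populations(self):
        a = coarse_grain(self._helicity([0.9, 0.1, 0.9, 0.1],
                                        [0.9, 0.9, 0.1, 0.1]))
        pops = lump(np.full(4, 0.25), a)
        assert all(v == pytest.approx(0.25) for v in pops.values())
        assert sum(pops.values()) == pytest.approx(1.0)

    def test_populations_invariant_to_microstate_relabeling(self):
        har = [0.9, 0.1, 0.9, 0.1]
        nes = [0.9, 0.9, 0.1, 0.1]
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        a = coarse_grain(self._helicity(har, nes))
        perm = np.array([2, 0, 3, 1])
        a2 = coarse_grain(self._helicity([har[i] for i in perm],
                                         [nes[i] for i in perm]))
        p1 = lump(pi, a)
        p2 = lump(pi[perm], a2)
        assert p1 == pytest.approx(p2)

    def test_invalid_helicity_rejected(self):
        with pytest.raises(InvalidStateError):
            coarse_grain(self._helicity([1.5], [0.2]))


class TestMfpt:
    def _tm(self, M, lag_time=1.0):
        from kinbind.msm import TransitionMatrix

        return TransitionMatrix(matrix=np.asarray(M, float),
                                counts=np.ones_like(M, dtype=np.int64),
                                lag_time=lag_time)

    def test_geometric_waiting_time(self):
        # two-state chain, escape probability p: MFPT = lag/p
        T = self._tm(T2, lag_time=15.0)
        assert mfpt(T, [0], [1]) == pytest.approx(150.0, rel=1e-12)

    def test_three_state_matches_monte_carlo(self):
        T = self._tm(T3)
        predicted = mfpt(T, [0], [2])
        # oracle: direct chain simulation of first-passage 0 -> 2
        rng = np.random.default_rng(123)
        cum = np.cumsum(T3, axis=1)
        n_sim = 200_000
        u = rng.random(size=n_sim * 200).reshape(n_sim, 200)
        times = np.empty(n_sim)
        for i in range(n_sim):
            s, t = 0, 0
            while s != 2:
                s = int(np.searchsorted(cum[s], u[i, t % 200]))
                if t % 200 == 199:
                    u[i] = rng.random(200)
                t += 1
            times[i] = t
        mc = times.mean()
        assert predicted == pytest.approx(mc, rel=0.02)

    def test_unreachable_target_is_infinite(self):
        M = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert mfpt(self._tm(M), [0], [1]) == np.inf

    def test_mfpt_matrix_diagonal_zero_and_floor(self):
        T = self._tm(T3, lag_time=2.0)
        hel = pd.DataFrame({"microstate": [0, 1, 2],
                            "har_helicity": [0.9, 0.1, 0.1],
                            "nes_helicity": [0.9, 0.9, 0.1]})
        a = coarse_grain(hel)
        M = mfpt_matrix(T, a)
        assert np.allclose(np.diag(M.to_numpy()), 0.0)
        off = M.to_numpy()[~np.eye(len(M), dtype=bool)]
        assert np.all(off >= T.lag_time)


class TestBootstrap:
    def _assignment(self, n_states):
        hel = pd.DataFrame({
            "microstate": np.arange(n_states),
            "har_helicity": np.linspace(0.1, 0.9, n_states),
            "nes_helicity": np.linspace(0.9, 0.1, n_states),
        })
        return coarse_grain(hel)

    def test_identical_trajectories_zero_sd(self):
        traj = generate_discrete_trajectories(T2, 1, 3000, seed=5)[0]
        a = self._assignment(2)
        s = bootstrap([traj, traj.copy(), traj.copy()], 1, a, n_rounds=20,
                      seed=0)
        assert np.allclose(s.populations["sd"], 0.0)
        assert np.allclose(s.mfpt_sd.to_numpy(), 0.0)

    def test_single_round_flags_undefined_sd(self):
        trajs = generate_discrete_trajectories(T2, 3, 2000, seed=6)
        s = bootstrap(trajs, 1, self._assignment(2), n_rounds=1, seed=0)
        assert s.populations["sd"].isna().all()

    def test_mean_population_near_generating_stationary(self):
        trajs = generate_discrete_trajectories(T2, 8, 5000, seed=7)
        a = self._assignment(2)
        s = bootstrap(trajs, 1, a, n_rounds=60, seed=3)
        true_pops = lump(stationary(T2), a)
        for macro, true_pop in true_pops.items():
            row = s.populations.loc[macro]
            assert abs(row["mean"] - true_pop) < 2 * max(row["sd"], 1e-3) + 0.02

    def test_seed_reproducibility(self):
        trajs = generate_discrete_trajectories(T3, 6, 2000, seed=8)
        a = self._assignment(3)
        s1 = bootstrap(trajs, 1, a, n_rounds=25, seed=11)
        s2 = bootstrap(trajs, 1, a, n_rounds=25, seed=11)
        pd.testing.assert_frame_equal(s1.populations, s2.populations)
        pd.testing.assert_frame_equal(s1.mfpt_mean, s2.mfpt_mean)

    def test_needs_two_trajectories(self):
        with pytest.raises(InsufficientDataError):
            bootstrap([np.zeros(10, int)], 1, self._assignment(1), seed=0)
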