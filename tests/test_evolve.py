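"""Breeder-equation updates, simulation determinism, summaries."""

import numpy as np
import pytest
from _quadrature import quadrature_delta_mean

from rnevolve import (
    EnvironmentModel,
    FitnessSpec,
    PopulationState,
    ReactionNormSpec,
    SimulationConfig,
    Trajectory,
    breeder_update,
    equilibrium_summary,
    sample_individuals,
    simulate,
)


def linear_state(gaa=0.5, gbb=0.045, gcc=0.5, mean=(0.0, 0.0, 0.0)):
    G = np.diag([gaa, gbb, gcc])
    return PopulationState(
        mean=np.array(mean), G_aug=G, P_aug=G.copy(), resid_cov=[[0.5]]
    )


def linear_config(state, seed=0, T=10, n=200, mu_u=1.0, mu_theta=1.0):
    return SimulationConfig(
        spec=ReactionNormSpec.linear(1),
        state=state,
        fitness=FitnessSpec(omega_sq=10.0),
        environment=EnvironmentModel(
            mu_u=[mu_u], mu_theta=[mu_theta],
            joint_cov=np.array([[0.4, 0.2], [0.2, 1.6]]),
        ),
        n_individuals=n,
        n_generations=T,
        seed=seed,
    )


class TestSampleIndividuals:
    def test_degenerate_population_sits_at_mean(self):
        spec = ReactionNormSpec.linear(1)
        state = PopulationState(
            mean=[1.0, 2.0, 3.0], G_aug=np.zeros((3, 3)),
            P_aug=np.zeros((3, 3)), resid_cov=np.zeros((1, 1)),
        )
        z, e = sample_individuals(state, spec, 50, np.random.default_rng(0))
        np.testing.assert_array_equal(z, np.tile([1.0, 2.0, 3.0], (50, 1)))
        np.testing.assert_array_equal(e, np.zeros((50, 1)))

    def test_sample_covariance_converges(self):
        spec = ReactionNormSpec.linear(1)
        state = linear_state()
        z, e = sample_individuals(state, spec, 200_000, np.random.default_rng(1))
        np.testing.assert_allclose(
            np.cov(z, rowvar=False), state.P_aug, atol=0.01
        )
        assert np.var(e) == pytest.approx(0.5, rel=0.05)

    def test_fixed_seed_reproduces_sample(self):
        spec = ReactionNormSpec.linear(1)
        state = linear_state()
        z1, e1 = sample_individuals(state, spec, 100, np.random.default_rng(5))
        z2, e2 = sample_individuals(state, spec, 100, np.random.default_rng(5))
        np.testing.assert_array_equal(z1, z2)
        np.testing.assert_array_equal(e1, e2)


class TestBreederUpdate:
    def test_flat_fitness_landscape_leaves_mean(self):
        state = linear_state()
        new, step = breeder_update(
            state, ReactionNormSpec.linear(1), FitnessSpec(omega_sq=1e12),
            np.array([1.0]), np.array([0.0]), 50_000, np.random.default_rng(2),
        )
        assert np.all(np.abs(step.delta_mean) < 1e-6)
        np.testing.assert_allclose(new.mean, state.mean, atol=1e-6)

    def test_delta_is_exactly_g_times_gradient(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        G = A @ A.T * 0.05
        state = PopulationState(
            mean=np.zeros(3), G_aug=G, P_aug=G + np.eye(3) * 0.1,
            resid_cov=[[0.5]],
        )
        _, step = breeder_update(
            state, ReactionNormSpec.linear(1), FitnessSpec(omega_sq=5.0),
            np.array([0.5]), np.array([1.0]), 1000, rng,
        )
        np.testing.assert_array_equal(step.delta_mean, state.G_aug @ step.gradient)

    def test_pinned_reference_stays_exactly_constant(self):
        # zero reference variance: undriven integrator, no update at all
        state = linear_state(gcc=0.0, mean=(0.0, 0.3, 0.7))
        new, step = breeder_update(
            state, ReactionNormSpec.linear(1), FitnessSpec(omega_sq=10.0),
            np.array([1.0]), np.array([2.0]), 5000, np.random.default_rng(4),
        )
        assert step.delta_mean[2] == 0.0
        assert new.mean[2] == 0.7

    def test_fully_degenerate_population_sees_no_selection(self):
        spec = ReactionNormSpec.linear(1)
        state = PopulationState(
            mean=[0.0, 1.0, 0.0], G_aug=np.zeros((3, 3)),
            P_aug=np.zeros((3, 3)), resid_cov=np.zeros((1, 1)),
        )
        new, step = breeder_update(
            state, spec, FitnessSpec(omega_sq=1.0),
            np.array([3.0]), np.array([0.0]), 100, np.random.default_rng(0),
        )
        np.testing.assert_array_equal(step.delta_mean, np.zeros(3))

    def test_collinear_traits_raise_informative_error(self):
        spec = ReactionNormSpec.linear(1)
        P = np.ones((3, 3))  # rank one but positive diagonal
        state = PopulationState(
            mean=np.zeros(3), G_aug=np.zeros((3, 3)), P_aug=P,
            resid_cov=[[0.5]],
        )
        with pytest.raises(np.linalg.LinAlgError, match="zero-variance or collinear"):
            breeder_update(
                state, spec, FitnessSpec(omega_sq=1.0),
                np.array([1.0]), np.array([0.0]), 100, np.random.default_rng(0),
            )


class TestQuadratureOracleAgreement:
    MEAN = np.array([0.3, 0.8, 0.5])
    G = np.diag([0.5, 0.045, 0.5])

    def _mc_delta(self, n, seed, gcc=0.5):
        G = np.diag([0.5, 0.045, gcc])
        state = PopulationState(
            mean=self.MEAN, G_aug=G, P_aug=G.copy(), resid_cov=[[0.5]]
        )
        _, step = breeder_update(
            state, ReactionNormSpec.linear(1), FitnessSpec(omega_sq=10.0),
            np.array([1.2]), np.array([1.0]), n, np.random.default_rng(seed),
        )
        return step.delta_mean

    def test_monte_carlo_error_shrinks_with_sample_size(self):
        dq, _, _ = quadrature_delta_mean(
            self.MEAN, self.G, self.G, 0.5, 1.2, 1.0, 10.0
        )
        errs = {}
        for n in (2_000, 200_000):
            deltas = np.array([self._mc_delta(n, seed) for seed in range(5)])
            errs[n] = np.mean(np.linalg.norm(deltas - dq, axis=1))
        assert errs[200_000] < errs[2_000]

    def test_two_trait_reduction_matches_oracle_without_reference(self):
        # pinned reference (Gcc = 0) reproduces the classic two-trait update
        dq, _, _ = quadrature_delta_mean(
            self.MEAN, np.diag([0.5, 0.045, 0.0]), np.diag([0.5, 0.045, 1.0]),
            0.5, 1.2, 1.0, 10.0, include_c=False,
        )
        deltas = np.array(
            [self._mc_delta(300_000, seed, gcc=0.0) for seed in range(4)]
        )
        np.testing.assert_allclose(deltas.mean(axis=0), dq, atol=4e-4)
        assert np.all(deltas[:, 2] == 0.0)


class TestSimulate:
    def test_zero_generations_keeps_initial_state_only(self):
        traj = simulate(linear_config(linear_state(), T=0))
        assert traj.n_generations == 0
        assert traj.means.shape == (1, 3)
        assert traj.w_bar.size == 0

    def test_same_seed_is_bit_identical(self):
        t1 = simulate(linear_config(linear_state(), seed=9, T=20))
        t2 = simulate(linear_config(linear_state(), seed=9, T=20))
        np.testing.assert_array_equal(t1.means, t2.means)
        np.testing.assert_array_equal(t1.w_bar, t2.w_bar)
        np.testing.assert_array_equal(t1.u, t2.u)

    def test_environment_sequence_independent_of_population_size(self):
        small = simulate(linear_config(linear_state(), seed=9, T=20, n=50))
        big = simulate(linear_config(linear_state(), seed=9, T=20, n=500))
        np.testing.assert_array_equal(small.u, big.u)
        np.testing.assert_array_equal(small.theta, big.theta)

    def test_invalid_state_is_reported_before_running(self):
        state = linear_state()
        state.P_aug = state.P_aug * 0.1  # P < G: negative non-additive part
        with pytest.raises(ValueError, match="P_aug - G_aug"):
            simulate(linear_config(state))

    def test_trajectory_csv_roundtrip(self, tmp_path):
        traj = simulate(linear_config(linear_state(), seed=1, T=15))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert back.trait_names == traj.trait_names
        np.testing.assert_allclose(back.means[1:], traj.means[1:], rtol=1e-12)
        np.testing.assert_allclose(back.w_bar, traj.w_bar, rtol=1e-12)


class TestEquilibriumSummary:
    def _constant_traj(self, value=1.5, T=40):
        return Trajectory(
            trait_names=["z_a_1"],
            means=np.full((T + 1, 1), value),
            w_bar=np.full(T, 0.8),
            beta=np.zeros((T, 1)),
            u=np.zeros((T, 1)),
            theta=np.zeros((T, 1)),
        )

    def test_constant_series_has_zero_standard_error(self):
        eq = equilibrium_summary(self._constant_traj(), (0, 40))
        assert eq.loc["z_a_1", "mean"] == pytest.approx(1.5)
        assert eq.loc["z_a_1", "se"] == 0.0
        assert eq.loc["W_bar", "mean"] == pytest.approx(0.8)

    def test_length_one_window_flags_undefined_se(self):
        with pytest.warns(UserWarning, match="undefined"):
            eq = equilibrium_summary(self._constant_traj(), (3, 4))
        assert np.isnan(eq.loc["z_a_1", "se"])
        assert eq.loc["z_a_1", "mean"] == pytest.approx(1.5)

    @pytest.mark.parametrize("window", [(5, 5), (-1, 10), (10, 60)])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(ValueError):
            equilibrium_summary(self._constant_traj(), window)
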