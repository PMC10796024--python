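import numpy as np
import pytest
from scipy import integrate

from ecoscape.dynamics import GLVSystem
from ecoscape.landscape import (
    BipartiteProjection,
    GaussianComponent,
    StabilityError,
    assemble_mixture,
    barrier_report,
    find_saddle,
    mixture_from_attractors,
    mixture_marginal_moments,
    reduce_bipartite,
    reduced_potential,
    stationary_moments,
)
from ecoscape.networks import BipartiteNetwork


def _component(mean, cov, w=1.0, label="other"):
    return GaussianComponent(np.asarray(mean, float),
                             np.asarray(cov, float), w, label)


class TestStationaryMoments:
    def test_scalar_linear_variance(self):
        """f = -lambda x has stationary variance d / lambda."""
        c = stationary_moments(np.array([0.0]), d=0.02,
                               jacobian=np.array([[-0.5]]))
        assert np.allclose(c.covariance, 0.02 / 0.5)

    def test_identity_decay_isotropic(self):
        c = stationary_moments(np.zeros(5), d=0.01, jacobian=-np.eye(5))
        assert np.allclose(c.covariance, 0.01 * np.eye(5))

    def test_random_stable_system_three_routes(self):
        """Lyapunov solve = covariance-ODE integration = Langevin ensemble."""
        rng = np.random.default_rng(4)
        M = rng.normal(size=(4, 4))
        A = -(M @ M.T) - 0.5 * np.eye(4)
        d = 0.05
        c = stationary_moments(np.zeros(4), d=d, jacobian=A)
        # route 2: integrate dSigma/dt = A S + S A^T + 2 d I to stationarity
        def rhs(t, y):
            S = y.reshape(4, 4)
            dS = A @ S + S @ A.T + 2 * d * np.eye(4)
            return dS.ravel()

        sol = integrate.solve_ivp(rhs, (0, 200.0), np.zeros(16),
                                  rtol=1e-10, atol=1e-12)
        S_ode = sol.y[:, -1].reshape(4, 4)
        assert np.max(np.abs(S_ode - c.covariance)) < 1e-8
        # route 3: Euler-Maruyama ensemble for the linear SDE
        n, dt, steps = 4000, 0.01, 4000
        X = np.zeros((n, 4))
        for _ in range(steps):
            X += X @ A.T * dt + rng.normal(size=(n, 4)) * np.sqrt(2 * d * dt)
        emp = np.cov(X.T)
        se = np.max(np.abs(c.covariance)) / np.sqrt(n)
        assert np.max(np.abs(emp - c.covariance)) < 6 * se + 0.01

    def test_unstable_jacobian_raises(self):
        with pytest.raises(StabilityError):
            stationary_moments(np.zeros(2), d=0.01,
                               jacobian=np.array([[0.1, 0], [0, -1.0]]))

    def test_lyapunov_residual_on_fixture(self, tristable_net,
                                          tristable_params,
                                          tristable_attractors):
        d = 0.01
        sys = GLVSystem(tristable_net, tristable_params)
        for a in tristable_attractors:
            A = sys.jacobian(a.state)
            S = stationary_moments(a, d=d, jacobian=A).covariance
            resid = A @ S + S @ A.T + 2 * d * np.eye(len(S))
            assert np.max(np.abs(resid)) < 1e-8
            assert np.min(np.linalg.eigvalsh(S)) > -1e-10


class TestMixture:
    def test_single_component_mode_density(self):
        cov = np.diag([0.1, 0.2])
        mix = assemble_mixture([_component([1.0, 2.0], cov)], [1.0], d=0.01)
        expect = -np.log((2 * np.pi) ** -1 * np.linalg.det(cov) ** -0.5)
        assert np.isclose(mix.potential(np.array([1.0, 2.0])), expect)

    def test_two_equal_wells_symmetric_minima(self):
        cov = 0.05 * np.eye(2)
        mix = assemble_mixture(
            [_component([-2, 0], cov), _component([2, 0], cov)],
            [0.5, 0.5], d=0.01)
        ua = mix.potential(np.array([-2.0, 0.0]))
        ub = mix.potential(np.array([2.0, 0.0]))
        assert np.isclose(ua, ub)
        assert mix.potential(np.array([0.0, 0.0])) > ua

    def test_density_normalized_by_quadrature(self):
        cov = np.array([[0.3, 0.1], [0.1, 0.2]])
        mix = assemble_mixture(
            [_component([0, 0], cov), _component([1.5, -1.0], 0.1 * np.eye(2))],
            [0.3, 0.7], d=0.01)
        val, _ = integrate.dblquad(
            lambda y, x: mix.density(np.array([x, y])),
            -8, 8, -8, 8, epsabs=1e-6)
        assert abs(val - 1.0) < 1e-4

    def test_unnormalized_weights_rejected(self):
        cov = np.eye(2)
        with pytest.raises(ValueError):
            assemble_mixture([_component([0, 0], cov)], [0.9], d=0.01)


class TestReduction:
    def test_single_component_collapses_to_block(self):
        net = BipartiteNetwork(np.ones((2, 2)))
        cov = np.diag([1.0, 2.0, 3.0, 4.0])
        mix = assemble_mixture([_component([0, 0, 0, 0], cov)], [1.0], d=0.01)
        mu, S = mixture_marginal_moments(mix, slice(0, 2))
        assert np.allclose(S, np.diag([1.0, 2.0]))
        proj = reduce_bipartite(mix, net)
        assert np.allclose(np.abs(proj.w1_P), [0, 1])  # larger-variance plant
        assert np.isclose(np.linalg.norm(proj.w1_A), 1.0)

    def test_identical_components_match_single(self):
        net = BipartiteNetwork(np.ones((2, 2)))
        cov = np.array([[0.5, 0.1, 0, 0], [0.1, 0.4, 0, 0],
                        [0, 0, 0.3, 0.05], [0, 0, 0.05, 0.6]])
        mean = np.array([1.0, 0.5, 0.2, 0.8])
        one = assemble_mixture([_component(mean, cov)], [1.0], d=0.01)
        two = assemble_mixture(
            [_component(mean, cov), _component(mean, cov)], [0.3, 0.7],
            d=0.01)
        for sl in (slice(0, 2), slice(2, 4)):
            mu1, S1 = mixture_marginal_moments(one, sl)
            mu2, S2 = mixture_marginal_moments(two, sl)
            assert np.allclose(mu1, mu2) and np.allclose(S1, S2)

    def test_marginal_moments_match_sampling(self):
        rng = np.random.default_rng(0)
        c1 = _component([0.0, 0.0, 1.0], np.diag([0.2, 0.1, 0.3]))
        c2 = _component([2.0, -1.0, 0.5], np.diag([0.1, 0.4, 0.2]))
        mix = assemble_mixture([c1, c2], [0.4, 0.6], d=0.01)
        n = 10 ** 6
        pick = rng.random(n) < 0.4
        samples = np.where(
            pick[:, None],
            rng.multivariate_normal(c1.mean, c1.covariance, size=n),
            rng.multivariate_normal(c2.mean, c2.covariance, size=n),
        )
        mu, S = mixture_marginal_moments(mix, slice(0, 3))
        emp_mu = samples.mean(axis=0)
        emp_S = np.cov(samples.T)
        assert np.max(np.abs(mu - emp_mu)) < 3 * np.sqrt(np.max(np.diag(S)) / n) + 1e-3
        assert np.max(np.abs(S - emp_S)) < 0.01


class TestReducedPotential:
    def _proj(self):
        return BipartiteProjection(w1_P=np.array([1.0]), w1_A=np.array([1.0]))

    def test_isotropic_bowl_is_quadratic(self):
        net = BipartiteNetwork(np.ones((1, 1)))
        mix = assemble_mixture(
            [_component([1.0, 1.0], 0.1 * np.eye(2))], [1.0], d=0.01)
        red = reduced_potential(mix, self._proj(), grid_size=81)
        # U - U_min should equal (dz^2) / (2 * 0.1)
        i = np.argmin(np.abs(red.z2 - 1.0))
        j = np.argmin(np.abs(red.z1 - 1.0))
        z = red.z1 - 1.0
        expect = z ** 2 / (2 * 0.1)
        got = red.U[i, :] - red.U[i, j]
        assert np.allclose(got, expect, atol=1e-8)

    def test_separated_components_keep_their_minima(self):
        net = BipartiteNetwork(np.ones((1, 1)))
        mix = assemble_mixture(
            [_component([0, 0], 0.01 * np.eye(2)),
             _component([1.0, 1.0], 0.01 * np.eye(2))],
            [0.5, 0.5], d=0.01)
        red = reduced_potential(mix, self._proj(), grid_size=101)
        mins = red.minima_indices()
        assert mins[0] != mins[1]

    def test_fixture_three_basins_ordered(self, tristable_net,
                                          tristable_params,
                                          tristable_attractors,
                                          tristable_projection):
        """Low sits at small (z1, z2), high at large, intermediate between."""
        mix = mixture_from_attractors(tristable_attractors, tristable_net,
                                      tristable_params, d=0.01)
        red = reduced_potential(mix, tristable_projection, grid_size=120)
        pos = {lab: m for lab, m in zip(red.labels, red.means_2d)}
        assert pos["low"][0] < pos["intermediate"][0] < pos["high"][0]
        assert pos["low"][1] <= pos["intermediate"][1] < pos["high"][1]


class TestSaddleAndBarriers:
    def _double_well(self, w1=0.5, sep=2.0, cov=0.05):
        mix = assemble_mixture(
            [_component([-sep / 2, 0], cov * np.eye(2), label="a"),
             _component([sep / 2, 0], cov * np.eye(2), label="b")],
            [w1, 1 - w1], d=0.01)
        proj = BipartiteProjection(np.array([1.0]), np.array([1.0]))
        return reduced_potential(mix, proj, grid_size=161)

    def test_symmetric_saddle_at_midpoint_and_zero_rbh(self):
        red = self._double_well(0.5)
        s = find_saddle(red, 0, 1)
        z1 = red.z1[s.saddle_index[1]]
        assert abs(z1) < (red.z1[1] - red.z1[0]) * 1.5
        rep = barrier_report(red)
        assert rep.BH[(0, 1)] == pytest.approx(rep.BH[(1, 0)], abs=1e-9)
        assert rep.rbh(0, 1) == pytest.approx(0.0, abs=1e-9)

    def test_heavier_basin_is_deeper(self):
        red = self._double_well(0.8)
        rep = barrier_report(red)
        # BH from the heavy basin exceeds BH from the light one
        assert rep.BH[(0, 1)] > rep.BH[(1, 0)]
        assert rep.rbh(1, 0) > 0  # relative feasibility points to heavy side

    def test_saddle_matches_brute_force_minimax(self):
        red = self._double_well(0.7, sep=1.6, cov=0.08)
        s = find_saddle(red, 0, 1)
        fine = self._double_well(0.7, sep=1.6, cov=0.08)
        # brute-force oracle at 4x resolution on the same mixture
        mix = assemble_mixture(
            [_component([-0.8, 0], 0.08 * np.eye(2)),
             _component([0.8, 0], 0.08 * np.eye(2))],
            [0.7, 0.3], d=0.01)
        proj = BipartiteProjection(np.array([1.0]), np.array([1.0]))
        hi = reduced_potential(mix, proj, grid_size=641)
        s_hi = find_saddle(hi, 0, 1)
        step = np.max(np.abs(np.diff(red.U[red.U.shape[0] // 2])))
        assert abs(s.U_saddle - s_hi.U_saddle) <= step + 1e-9

    def test_antisymmetry_exact(self, tristable_net, tristable_params,
                                tristable_attractors, tristable_projection):
        mix = mixture_from_attractors(tristable_attractors, tristable_net,
                                      tristable_params, d=0.01)
        red = reduced_potential(mix, tristable_projection, grid_size=120)
        rep = barrier_report(red)
        for i in range(3):
            for j in range(i + 1, 3):
                assert rep.rbh(i, j) == -rep.rbh(j, i)
                assert rep.BH[(i, j)] >= 0 and rep.BH[(j, i)] >= 0

    def test_monostable_report_rejected(self):
        mix = assemble_mixture(
            [_component([0, 0], 0.1 * np.eye(2))], [1.0], d=0.01)
        proj = BipartiteProjection(np.array([1.0]), np.array([1.0]))
        red = reduced_potential(mix, proj, grid_size=41)
        with pytest.raises(ValueError):
            barrier_report(red)

    def test_merged_basins_flagged(self):
        mix = assemble_mixture(
            [_component([0, 0], 0.5 * np.eye(2)),
             _component([0.05, 0.0], 0.5 * np.eye(2))],
            [0.5, 0.5], d=0.01)
        proj = BipartiteProjection(np.array([1.0]), np.array([1.0]))
        red = reduced_potential(mix, proj, grid_size=81)
        s = find_saddle(red, 0, 1)
        assert s.merged


class TestPermutationInvariance:
    def test_plant_relabeling_permutes_projection(self, tristable_net,
                                                  tristable_params,
                                                  tristable_attractors):
        mix = mixture_from_attractors(tristable_attractors, tristable_net,
                                      tristable_params, d=0.01)
        proj = reduce_bipartite(mix, tristable_net)
        perm = np.random.default_rng(1).permutation(tristable_net.n_plants)
        full = np.concatenate(
            [perm, np.arange(tristable_net.n_pollinators)
             + tristable_net.n_plants])
        net_p = BipartiteNetwork(tristable_net.incidence[perm])
        comps = []
        for c in mix.components:
            comps.append(_component(c.mean[full],
                                    c.covariance[np.ix_(full, full)],
                                    c.weight, c.label))
        mix_p = assemble_mixture(comps, [c.weight for c in comps], d=0.01)
        proj_p = reduce_bipartite(mix_p, net_p)
        assert np.allclose(np.abs(proj_p.w1_P), np.abs(proj.w1_P[perm]),
                           atol=1e-8)
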