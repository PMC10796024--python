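import numpy as np
import pytest
import sympy as sp

from ecoscape.dynamics import (
    GLVSystem,
    classify_state,
    drift,
    find_attractors,
    jacobian,
    phase_diagram,
    removal_census,
    scenario_code,
    Attractor,
)
from ecoscape.networks import (
    BipartiteNetwork,
    ModelParameters,
    generate_random_network,
)


class TestDrift:
    def test_origin_is_fixed_point_without_immigration(self):
        net = generate_random_network(3, 4, 0.5, seed=1)
        p = ModelParameters(mu_P=0.0, mu_A=0.0)
        assert np.allclose(drift(np.zeros(7), net, p), 0.0)

    def test_single_plant_logistic_equilibrium(self):
        net = BipartiteNetwork(np.zeros((1, 0)))
        p = ModelParameters(mu_P=0.0)
        assert abs(drift(np.array([0.3]), net, p)[0]) < 1e-15

    def test_against_symbolic_expansion(self):
        """1 plant + 1 pollinator drift matches an independent symbolic form."""
        net = BipartiteNetwork(np.ones((1, 1)))
        p = ModelParameters(alpha_P=0.3, alpha_A=0.25, beta_intra_P=1.1,
                            beta_intra_A=0.9, kappa=0.8, gamma0=1.3,
                            delta=0.5, h=0.2, mu_P=0.01, mu_A=0.02)
        P, A = sp.symbols("P A", positive=True)
        gam = 1.3  # degree 1 for both species: gamma0 / 1**delta
        dP = sp.Rational(3, 10) * P - sp.Float(1.1) * P**2 \
            + P * gam * A / (1 + sp.Float(0.2) * gam * A) + sp.Float(0.01)
        dA = (sp.Float(0.25) - sp.Float(0.8)) * A - sp.Float(0.9) * A**2 \
            + A * gam * P / (1 + sp.Float(0.2) * gam * P) + sp.Float(0.02)
        for Pv, Av in [(0.1, 0.2), (1.3, 0.7), (2.0, 2.5)]:
            got = drift(np.array([Pv, Av]), net, p)
            want = [float(dP.subs({P: Pv, A: Av})),
                    float(dA.subs({P: Pv, A: Av}))]
            assert np.allclose(got, want, rtol=1e-12)

    def test_nan_input_raises(self):
        net = BipartiteNetwork(np.ones((1, 1)))
        with pytest.raises(ValueError):
            drift(np.array([np.nan, 0.0]), net, ModelParameters())


class TestJacobian:
    def test_matches_finite_differences(self):
        net = generate_random_network(5, 7, 0.4, heterogeneity=1.0, seed=3)
        p = ModelParameters(mu_P=0.001, mu_A=0.001)
        sys = GLVSystem(net, p)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0.05, 2.5, sys.n)
            J = sys.jacobian(x)
            eps = 1e-6
            for k in range(sys.n):
                e = np.zeros(sys.n)
                e[k] = eps
                col = (sys.drift(x + e) - sys.drift(x - e)) / (2 * eps)
                assert np.allclose(J[:, k], col, rtol=1e-6, atol=1e-8)

    def test_decoupled_blocks_zero_without_interactions(self):
        net = BipartiteNetwork(np.zeros((2, 2)))
        p = ModelParameters(beta_inter_P=0.0, beta_inter_A=0.0)
        J = jacobian(np.array([0.5, 0.4, 0.3, 0.2]), net, p)
        off = J - np.diag(np.diag(J))
        assert np.allclose(off, 0.0)

    def test_negative_spectral_abscissa_at_attractors(self, tristable_net,
                                                      tristable_params,
                                                      tristable_attractors):
        for a in tristable_attractors:
            assert np.max(a.jacobian_spectrum.real) < 0


class TestFindAttractors:
    def test_lone_plant_logistic(self):
        net = BipartiteNetwork(np.zeros((1, 0)))
        aset = find_attractors(net, ModelParameters(), n_starts=10, seed=1)
        assert len(aset) == 1
        a = aset.attractors[0]
        assert abs(a.state[0] - 0.3) < 1e-8
        assert a.weight == 1.0

    def test_fixture_is_tristable(self, tristable_attractors):
        labels = sorted(a.label for a in tristable_attractors)
        assert labels == ["high", "intermediate", "low"]
        low = tristable_attractors.by_label("low")
        inter = tristable_attractors.by_label("intermediate")
        assert low.n_alive_pollinators == 0
        assert inter.n_alive_pollinators == 1

    def test_attractor_quality_invariants(self, tristable_net,
                                          tristable_params,
                                          tristable_attractors):
        sys = GLVSystem(tristable_net, tristable_params)
        for a in tristable_attractors:
            assert np.max(np.abs(sys.drift(a.state))) < 1e-8
            assert np.min(a.state) >= 0
        assert abs(sum(a.weight for a in tristable_attractors) - 1.0) < 1e-12

    def test_basin_weights_match_dense_grid(self, toy_net):
        """Monte-Carlo weights agree with a deterministic grid integration."""
        params = ModelParameters(kappa=1.1, gamma0=2.0)
        aset = find_attractors(toy_net, params, n_starts=400, seed=3,
                               sampler="uniform", x_hi=3.0)
        assert len(aset) == 2
        # oracle: relax a dense regular grid of the same sampling box
        sys = GLVSystem(toy_net, params)
        from ecoscape.dynamics import _integrate_batch

        g = np.linspace(0.0, 3.0, 30)
        X0 = np.array([[a, b] for a in g for b in g])
        ends = _integrate_batch(sys, X0, 400.0)
        states = np.array([a.state for a in aset])
        lab = np.argmin(
            np.linalg.norm(ends[:, None, :] - states[None], axis=2), axis=1
        )
        grid_w = np.bincount(lab, minlength=2) / len(lab)
        mc_w = np.array([a.weight for a in aset])
        # binomial error at n_starts=400 plus grid discretization
        assert np.all(np.abs(grid_w - mc_w) < 0.08)

    def test_stable_under_more_starts(self, toy_net):
        params = ModelParameters(kappa=1.15, gamma0=2.0)
        a1 = find_attractors(toy_net, params, n_starts=40, seed=2)
        a2 = find_attractors(toy_net, params, n_starts=80, seed=2)
        assert len(a1) == len(a2)
        s1 = sorted(tuple(np.round(a.state, 5)) for a in a1)
        s2 = sorted(tuple(np.round(a.state, 5)) for a in a2)
        assert np.allclose(s1, s2, atol=1e-3)


class TestClassification:
    def test_all_pollinators_extinct_is_low(self):
        s = np.array([0.3, 0.2, 1e-4, 5e-4])
        assert classify_state(s, [s], n_plants=2) == "low"

    def test_lone_survivor_with_richer_partner_is_intermediate(self):
        inter = np.array([0.4, 0.4, 0.5, 0.0, 0.0, 0.0])
        high = np.array([1.0, 1.0, 0.8, 0.5, 0.6, 0.4])
        assert classify_state(inter, [inter, high], n_plants=2) == "intermediate"
        assert classify_state(high, [inter, high], n_plants=2) == "high"

    def test_single_state_all_alive_is_high(self):
        s = np.array([1.0, 1.0, 0.5, 0.6])
        assert classify_state(s, [s], n_plants=2) == "high"

    @pytest.mark.parametrize("labels,code", [
        (["high"], "H"),
        (["high", "intermediate"], "HI"),
        (["high", "low"], "HL"),
        (["high", "intermediate", "low"], "HIL"),
        (["intermediate", "low"], "IL"),
        (["low"], "L"),
        (["intermediate"], "I"),
        (["high", "intermediate", "intermediate", "low"], "T"),
        (["high", "other"], "other"),
    ])
    def test_scenario_codes(self, labels, code):
        atts = [Attractor(state=np.zeros(1), label=l) for l in labels]
        assert scenario_code(atts) == code


class TestCensusAndPhase:
    def test_census_proportions_and_trend(self):
        base = generate_random_network(10, 24, 0.2, heterogeneity=1.5, seed=4)
        df = removal_census(base, ModelParameters(kappa=0.95),
                            fractions=[0.0, 0.5, 0.9], n_subnets=12, seed=9,
                            n_starts=20, t_max=300)
        sums = df.groupby("fraction")["proportion"].sum()
        assert np.allclose(sums.values, 1.0)
        piv = df.pivot(index="scenario", columns="fraction",
                       values="proportion")
        h = piv.loc["H"].values
        l = piv.loc["L"].values
        slack = 0.2  # binomial error at n=12
        assert h[0] + slack >= h[-1]
        assert l[-1] + slack >= l[0]

    def test_phase_diagram_extremes(self, tristable_net):
        p = ModelParameters()
        df = phase_diagram(tristable_net, p, kappa_grid=[5.0],
                           gamma0_grid=[1.0], n_starts=20, seed=1,
                           t_max=200)
        assert df.iloc[0, 0] == "L"

    def test_phase_diagram_deterministic(self, toy_net):
        p = ModelParameters(gamma0=2.0)
        a = phase_diagram(toy_net, p, [0.7, 1.1], [1.8, 2.2], n_starts=20,
                          seed=3, t_max=300)
        b = phase_diagram(toy_net, p, [0.7, 1.1], [1.8, 2.2], n_starts=20,
                          seed=3, t_max=300)
        assert (a.values == b.values).all()
        assert a.loc[1.1, 2.2] in ("HL", "H")


class TestForwardInvariance:
    def test_trajectories_stay_nonnegative(self, tristable_net,
                                           tristable_params):
        from ecoscape.dynamics import _integrate_batch

        sys = GLVSystem(tristable_net, tristable_params)
        rng = np.random.default_rng(8)
        X0 = rng.uniform(0, 3, size=(20, sys.n))
        X = _integrate_batch(sys, X0, 50.0)
        assert np.min(X) >= 0
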