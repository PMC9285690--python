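"""Rate functions, delay integrator, and dynamic invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import forageweb as fw
from forageweb import ValidationError
from forageweb.ecology import simulate
from forageweb.policies import PolicyPath
from forageweb.scenarios import solve_pelican_density_exponent


class TestRecruitmentRate:
    def test_zero_amplitude_constant(self, params):
        fp = params.anchovy
        t = np.linspace(0, 100, 500)
        assert np.allclose(fw.recruitment_rate(t, fp), fp.r_bar)

    @pytest.mark.parametrize("A", [0.2, 0.4, 0.6])
    def test_period_mean_bias_below_one_percent(self, params, A):
        # the -A^2/4 correction keeps the period mean within 1% of r_bar
        fp = params.copy().anchovy
        fp.A, fp.p, fp.s = A, 25.0, 90.0
        t = np.linspace(0, fp.p, 20001)
        mean = np.trapezoid(fw.recruitment_rate(t, fp), t) / fp.p
        assert abs(mean - fp.r_bar) / fp.r_bar < 0.01

    def test_periodicity(self, params):
        fp = params.copy().sardine
        fp.A = 0.3
        t = np.array([0.0, 3.7, 11.2])
        assert fw.recruitment_rate(t, fp) == pytest.approx(
            fw.recruitment_rate(t + fp.p, fp))

    def test_strictly_positive(self, params):
        fp = params.copy().anchovy
        fp.A = 0.6
        t = np.linspace(0, 100, 2000)
        assert (fw.recruitment_rate(t, fp) > 0).all()


class TestPredation:
    def test_no_predator_no_predation(self, params):
        assert fw.predation_mortality(1e5, 1e5, 0.0, params.halibut) == (0, 0)

    def test_symmetry_with_equal_search_rates(self, params):
        hp = params.halibut
        assert hp.alpha_a == hp.alpha_s
        Pa, Ps = fw.predation_mortality(3e5, 3e5, 2e4, hp)
        assert Pa == pytest.approx(Ps)

    def test_prey_switching_buffering(self, params):
        # P_a falls as the OTHER prey becomes more abundant (shared
        # denominator of the Type-II response)
        hp = params.halibut
        Xs_grid = np.linspace(1e5, 2e6, 40)
        Pa = np.array([fw.predation_mortality(3e5, Xs, 2e4, hp)[0]
                       for Xs in Xs_grid])
        assert (np.diff(Pa) < 0).all()


class TestHalibutRecruitment:
    def test_zero_at_zero(self, params):
        assert fw.halibut_recruitment(0.0, params.halibut) == 0.0

    def test_saturation_limit(self, params):
        hp = params.halibut
        lim = hp.a / hp.b * np.exp(-hp.M_j * hp.tau)
        assert fw.halibut_recruitment(1e12, hp) == pytest.approx(lim, rel=1e-6)

    def test_slope_at_origin(self, params):
        hp = params.halibut
        eps = 1e-6
        slope = fw.halibut_recruitment(eps, hp) / eps
        assert slope == pytest.approx(hp.a * np.exp(-hp.M_j * hp.tau), rel=1e-6)


class TestAsymptoticMass:
    def test_baseline_normalization(self, params):
        hp = params.halibut
        w = fw.halibut_asymptotic_mass(params.anchovy.X0, params.sardine.X0, hp)
        assert w == pytest.approx(hp.w_inf0)

    def test_gamma_zero_constant(self, params):
        hp = params.copy().halibut
        hp.gamma_w = 0.0
        assert fw.halibut_asymptotic_mass(0.0, 0.0, hp) == hp.w_inf0

    def test_monotone_in_prey(self, params):
        hp = params.halibut
        Xa = np.linspace(0, 2e6, 50)
        w = np.array([fw.halibut_asymptotic_mass(x, 4e5, hp) for x in Xa])
        assert (np.diff(w) >= 0).all()


class TestDerivatives:
    def test_zero_state_is_absorbing(self, params):
        state = np.zeros(7)
        (da, _), (ds, _) = fw.forage_derivatives(state, 0.0, (0.0, 0.0), params)
        assert da == 0 and ds == 0
        assert fw.halibut_derivatives(state, 0.0, 0.0, 0.0, params) == (0, 0)

    def test_negative_state_rejected(self, params):
        state = np.zeros(7)
        state[0] = -1.0
        with pytest.raises(ValidationError):
            fw.forage_derivatives(state, 0.0, (0.0, 0.0), params)

    def test_equilibrium_derivatives_vanish(self, params):
        state = params.initial_state()
        (dXa, dNa), (dXs, dNs) = fw.forage_derivatives(state, 0.0,
                                                       (0.0, 0.0), params)
        h = params.halibut
        assert abs(dNa) < 1e-9 * state[1] and abs(dNs) < 1e-9 * state[3]
        assert abs(dXa) < 1e-6 * state[0] and abs(dXs) < 1e-6 * state[2]
        dXh, dNh = fw.halibut_derivatives(state, 0.0, h.X0, 0.0, params)
        assert abs(dXh) < 1e-6 * h.X0 and abs(dNh) < 1e-6 * h.N0
        lagged = {"Xa": state[0], "Xs": state[2], "Nbp": 100.0}
        assert fw.pelican_derivative(state, 0.0, lagged, params) == \
            pytest.approx(0.0, abs=1e-9 * 100)

    def test_mean_mass_bounded_in_long_unfished_run(self, params, nofish_200):
        for (iX, iN, fp) in ((0, 1, params.anchovy), (2, 3, params.sardine)):
            wbar = nofish_200.states[:, iX] / nofish_200.states[:, iN]
            assert (wbar >= fp.w_r - 1e-12).all()
            assert (wbar <= fp.w_inf + 1e-12).all()

    def test_doubling_prey_increases_halibut_equilibrium(self, params):
        lo = params.copy()
        hi = params.copy()
        for sp in (hi.anchovy, hi.sardine):
            sp.X0 *= 2.0
            sp.N0 *= 2.0
        runs = []
        for ps in (lo, hi):
            tr = simulate(ps, PolicyPath.moratorium(), T=120, dt=0.05)
            runs.append(tr.states[tr.t >= 100, 4].mean())
        assert runs[1] > runs[0]


class TestPelicanModel:
    def test_depletion_baseline_and_empty(self, params):
        pp = params.pelican
        assert fw.pelican_depletion(pp.Xa_o, pp.Xs_o, pp) == pytest.approx(1.0)
        assert fw.pelican_depletion(0.0, 0.0, pp) == pytest.approx(pp.Gamma_other)

    def test_depletion_linear_in_prey(self, params):
        pp = params.pelican
        d0 = fw.pelican_depletion(0.0, 4e5, pp)
        d1 = fw.pelican_depletion(1e5, 4e5, pp)
        d2 = fw.pelican_depletion(2e5, 4e5, pp)
        assert d2 - d1 == pytest.approx(d1 - d0)

    def test_depletion_zero_baseline_rejected(self, params):
        pp = params.copy().pelican
        pp.Xa_o = 0.0
        with pytest.raises(ValidationError):
            fw.pelican_depletion(1e5, 1e5, pp)

    def test_prey_response_zero_at_theta1(self, params):
        th = params.pelican.theta_r
        assert fw.prey_response(th[0], th) == 0.0
        assert fw.prey_response(0.5 * th[0], th) == 0.0

    def test_prey_response_saturates_at_one(self, params):
        assert fw.prey_response(1e9, params.pelican.theta_r) == \
            pytest.approx(1.0, abs=1e-6)

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    def test_prey_response_monotone(self, d1, d2):
        th = (0.2, 0.25, 0.8)
        lo, hi = sorted((d1, d2))
        assert fw.prey_response(lo, th) <= fw.prey_response(hi, th) + 1e-12

    def test_prey_response_decoupled_limit(self):
        assert fw.prey_response(0.5, (0.2, 0.0, 0.8)) == 1.0

    def test_prey_response_bad_theta_rejected(self):
        with pytest.raises(ValidationError):
            fw.prey_response(0.5, (0.6, 0.5, 0.8))  # theta1+theta2 >= 1

    def test_reproduction_at_K(self, params):
        pp = params.pelican
        R = fw.pelican_reproduction(pp.K_bp, 1.0, pp)
        assert R == pytest.approx(0.5 * np.exp(-pp.Mbar * pp.tau_bp) * pp.K_bp)

    def test_reproduction_zero_without_prey_response(self, params):
        assert fw.pelican_reproduction(50.0, 0.0, params.pelican) == 0.0

    def test_net_productivity_peaks_at_60pct_K(self, params):
        # z is solved so that R(N) - Mbar N (at saturating prey) peaks at
        # 0.6 K_bp; check by direct numerical maximization
        pp = params.pelican
        N = np.linspace(1.0, 2.0 * pp.K_bp, 20001)
        G = np.array([fw.pelican_reproduction(n, 1.0, pp) for n in N]) \
            - pp.Mbar * N
        assert N[np.argmax(G)] == pytest.approx(0.6 * pp.K_bp, rel=1e-3)

    def test_density_exponent_solver_rejects_flat_productivity(self):
        with pytest.raises(ValidationError):
            solve_pelican_density_exponent(Mbar=0.3, tau_bp=6.0, Phi=1.5)

    def test_mortality_at_abundant_prey(self, params):
        pp = params.pelican
        assert fw.pelican_mortality_rate(1e6, pp) == pytest.approx(pp.Mbar,
                                                                   abs=1e-6)

    def test_mortality_formula_offset(self, params):
        # phi_v = e^-1 adds exactly +1 to the baseline mortality
        pp = params.copy().pelican
        target = np.exp(-1.0)
        from scipy.optimize import brentq
        d = brentq(lambda d: fw.prey_response(d, pp.theta_s) - target,
                   pp.theta_s[0] + 1e-9, 5.0)
        assert fw.pelican_mortality_rate(d, pp) == pytest.approx(pp.Mbar + 1.0)

    def test_mortality_nonincreasing_in_depletion(self, params):
        pp = params.pelican
        d = np.linspace(0.0, 3.0, 200)
        M = np.array([fw.pelican_mortality_rate(x, pp) for x in d])
        assert (np.diff(M) <= 1e-12).all()

    def test_collapse_without_forage(self, params):
        state = params.initial_state()
        state[0] = state[2] = 0.0
        lagged = {"Xa": 0.0, "Xs": 0.0, "Nbp": 100.0}
        assert fw.pelican_derivative(state, 0.0, lagged, params) < 0


class TestSimulate:
    def test_non_negative_states_under_heavy_fishing(self, params):
        tr = simulate(params, PolicyPath.constant_F(2.0), T=60, dt=0.05)
        assert (tr.states >= 0).all()

    def test_step_refinement_converges(self, params):
        sc = fw.make_scenario("OA_all", "synchronous", T=40,
                              close_baselines=False)
        t1 = simulate(sc.params, PolicyPath.open_access(), T=40, dt=0.05)
        t2 = simulate(sc.params, PolicyPath.open_access(), T=40, dt=0.005)
        rel = np.abs(t1.states[-1] - t2.states[-1]) / np.abs(t2.states[-1])
        assert rel.max() < 1e-3

    def test_deterministic_bitwise(self, params):
        a = simulate(params, PolicyPath.open_access(), T=30, dt=0.05)
        b = simulate(params, PolicyPath.open_access(), T=30, dt=0.05)
        assert np.array_equal(a.states, b.states)

    def test_unfished_variability_cycles_with_forcing_period(self, params):
        fo = fw.make_recruitment_forcing("synchronous", params)
        ps = fo.apply(params)
        tr = simulate(ps, PolicyPath.moratorium(), T=150, dt=0.05)
        p = ps.anchovy.p
        # after a transient, successive cycles repeat to within the slow
        # drift left by the approximate bias correction
        t = tr.t
        c1 = tr.states[(t >= 100) & (t < 100 + p), 0]
        c2 = tr.states[(t >= 100 + p) & (t < 100 + 2 * p), 0]
        n = min(len(c1), len(c2))
        assert np.abs(c1[:n] - c2[:n]).max() / c1[:n].max() < 0.10

    def test_open_access_biomass_below_unfished(self, params):
        fo = fw.make_recruitment_forcing("anti_synchronous", params)
        ps = fo.apply(params)
        oa = simulate(ps, PolicyPath.open_access(), T=60, dt=0.05)
        nf = simulate(ps, PolicyPath.moratorium(), T=60, dt=0.05)
        assert (oa.states[:, 0] <= nf.states[:, 0] * (1 + 1e-9)).all()
        assert (oa.states[:, 2] <= nf.states[:, 2] * (1 + 1e-9)).all()

    def test_lagged_state_accessor(self, params):
        tr = simulate(params, PolicyPath.open_access(), T=30, dt=0.05)
        # before t=0 the accessor returns the constant initial history
        assert tr.state(-3.0) == pytest.approx(tr.states[0])
        assert tr.state(10.0)[0] == pytest.approx(
            np.interp(10.0, tr.t, tr.states[:, 0]))

    def test_trajectory_frame_columns(self, params):
        tr = simulate(params, PolicyPath.open_access(), T=5, dt=0.1)
        df = tr.to_frame()
        assert list(df.columns) == ["t", "Xa", "Na", "Xs", "Ns", "Xh", "Nh",
                                    "Nbp", "Ea", "Es", "Eh", "Fa", "Fs", "Fh"]
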