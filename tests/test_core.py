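"""Closed-form solutions and right-hand sides of the compartment model."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from chipbind import (
    BoxState,
    ConfigError,
    SystemConfig,
    SynthesisPattern,
    build_trap_pattern,
    multibox_rhs,
    onebox_bound_analytical,
    onebox_bound_pure_binding,
    onebox_rhs,
)

CAP = 100.0


def onebox_oracle(alpha, kappa, cap, nb0, nu0, t_grid):
    """Independent stiff-safe adaptive integration of the one-box kinetics."""

    def rhs(t, y):
        nu, nb = y
        b = kappa * nu * (cap - nb)
        return [-b + alpha, b]

    sol = solve_ivp(
        rhs, (0.0, t_grid[-1]), [nu0, nb0], t_eval=t_grid,
        method="LSODA", rtol=1e-11, atol=1e-12,
    )
    return sol.y[1]


class TestOneboxAnalytical:
    def test_frozen_oracle_value(self, fig2_config):
        # adaptive-oracle value for the bench parameter pair at t=5000 s
        nb = onebox_bound_analytical(fig2_config, CAP, 0.0, 0.0, 5000.0)
        assert nb == pytest.approx(4.9998947371, rel=1e-8)

    def test_matches_oracle_across_regimes(self, fig2_config):
        t_grid = np.array([50.0, 500.0, 5e3, 5e4, 9e4, 9.9e4, 1.002e5, 1.2e5])
        nb_oracle = onebox_oracle(1e-3, 0.1, CAP, 0.0, 0.0, t_grid)
        nb = onebox_bound_analytical(fig2_config, CAP, 0.0, 0.0, t_grid)
        assert np.allclose(nb, nb_oracle, rtol=1e-8, atol=1e-10)

    def test_initial_condition(self, fig2_config):
        assert onebox_bound_analytical(fig2_config, CAP, 0.0, 0.0, 0.0) == 0.0
        assert onebox_bound_analytical(fig2_config, CAP, 7.0, 3.0, 0.0) == pytest.approx(7.0)

    def test_no_binding_keeps_initial_count(self, fig2_config):
        cfg = fig2_config.replace(kappa_bin=0.0)
        t = np.array([0.0, 10.0, 1e4])
        assert np.allclose(onebox_bound_analytical(cfg, CAP, 5.0, 2.0, t), 5.0)

    def test_zero_capacity_returns_zero(self, fig2_config):
        assert onebox_bound_analytical(fig2_config, 0.0, 0.0, 0.0, 50.0) == 0.0

    def test_zero_synthesis_is_rejected(self, fig2_config):
        cfg = fig2_config.replace(alpha_syn=0.0)
        with pytest.raises(ConfigError, match="undefined"):
            onebox_bound_analytical(cfg, CAP, 0.0, 0.0, 1.0)

    def test_satisfies_the_onebox_ode(self, fig2_config):
        # residual of d(N_b)/dt = kappa * N_u * (cap - N_b), N_u = alpha*t - N_b
        alpha, kappa = 1e-3, 0.1
        f = lambda x: onebox_bound_analytical(fig2_config, CAP, 0.0, 0.0, x)
        for t in (100.0, 1e3, 1e4, 5e4, 9e4, 9.9e4):
            h = 1e-3 * t
            central = lambda hh: (f(t + hh) - f(t - hh)) / (2.0 * hh)
            # Richardson-extrapolated central difference (O(h^4) truncation)
            deriv = (4.0 * central(h / 2.0) - central(h)) / 3.0
            nb = f(t)
            rhs = kappa * (alpha * t - nb) * (CAP - nb)
            assert deriv == pytest.approx(rhs, rel=1e-6)

    def test_equilibrium_is_full_saturation(self, fig2_config):
        # far past saturation, lambda*C_zeta >> 1
        nb = onebox_bound_analytical(fig2_config, CAP, 0.0, 0.0, 1e7)
        assert nb == pytest.approx(CAP, rel=1e-12)

    def test_monotone_and_bounded(self, fig2_config):
        t = np.geomspace(1.0, 1e6, 400)
        nb = onebox_bound_analytical(fig2_config, CAP, 2.0, 1.0, t)
        assert np.all(np.diff(nb) >= -1e-12)
        assert np.all(nb >= 2.0 - 1e-12)
        assert np.all(nb <= CAP + 1e-12)


class TestPureBindingClosedForm:
    @pytest.mark.parametrize(
        "nb0,nu0,cap",
        [(0.0, 30.0, 20.0), (0.0, 10.0, 20.0), (5.0, 15.0, 20.0), (0.0, 20.0, 20.0)],
        ids=["excess-protein", "excess-traps", "preloaded", "exact-balance"],
    )
    def test_matches_oracle(self, nb0, nu0, cap):
        cfg = SystemConfig(0.0, 0.05, 0.0, 0.1, 10, 1)
        t_grid = np.array([0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0])
        nb_oracle = onebox_oracle(0.0, 0.05, cap, nb0, nu0, t_grid)
        nb = onebox_bound_pure_binding(cfg, cap, nb0, nu0, t_grid)
        assert np.allclose(nb, nb_oracle, rtol=1e-7, atol=1e-9)

    def test_long_time_limit(self):
        cfg = SystemConfig(0.0, 0.05, 0.0, 0.1, 10, 1)
        # with excess traps all protein binds; with excess protein traps fill
        assert onebox_bound_pure_binding(cfg, 20.0, 0.0, 8.0, 1e6) == pytest.approx(8.0)
        assert onebox_bound_pure_binding(cfg, 20.0, 0.0, 50.0, 1e6) == pytest.approx(20.0)

    def test_no_unbound_protein_means_stasis(self):
        cfg = SystemConfig(0.0, 0.05, 0.0, 0.1, 10, 1)
        assert onebox_bound_pure_binding(cfg, 20.0, 3.0, 0.0, 100.0) == pytest.approx(3.0)


class TestRhs:
    def test_onebox_examples(self, fig2_config):
        # no unbound protein: synthesis only
        dnu, dnb = onebox_rhs(BoxState([0.0], [0.0]), fig2_config, CAP)
        assert (dnu, dnb) == (pytest.approx(1e-3), 0.0)
        # saturated traps: no binding
        dnu, dnb = onebox_rhs(BoxState([5.0], [CAP]), fig2_config, CAP)
        assert dnb == 0.0
        # direct product kappa*N_u*(cap-N_b)
        dnu, dnb = onebox_rhs(BoxState([10.0], [CAP - 50.0]), fig2_config, CAP)
        assert dnb == pytest.approx(0.1 * 10.0 * 50.0)
        assert dnu + dnb == pytest.approx(fig2_config.alpha_per_t)

    def test_two_box_structure(self):
        """M=2 reproduces the explicitly written two-box equations."""
        cfg = SystemConfig(0.01, 0.002, 0.03, 1.0, 10, 2, rate_units="per_time")
        traps = build_trap_pattern(np.array([40.0, 60.0]), 2)
        sources = SynthesisPattern({1})
        nu = np.array([3.0, 7.0])
        nb = np.array([10.0, 20.0])
        dnu, dnb = multibox_rhs(BoxState(nu, nb), cfg, traps, sources)
        b1 = 0.002 * 3.0 * (40.0 - 10.0)
        b2 = 0.002 * 7.0 * (60.0 - 20.0)
        assert dnb == pytest.approx([b1, b2])
        assert dnu[0] == pytest.approx(0.03 * (7.0 - 3.0) - b1 + 0.01)
        assert dnu[1] == pytest.approx(0.03 * (3.0 - 7.0) - b2)

    def test_flat_profile_has_no_diffusion(self):
        cfg = SystemConfig(0.0, 0.0, 0.2, 1.0, 10, 5, rate_units="per_time")
        traps = build_trap_pattern(0.0, 5)
        state = BoxState(np.full(5, 3.5), np.zeros(5))
        dnu, dnb = multibox_rhs(state, cfg, traps, SynthesisPattern())
        assert np.allclose(dnu, 0.0) and np.allclose(dnb, 0.0)

    def test_pure_synthesis_changes_only_sources(self):
        cfg = SystemConfig(0.4, 0.0, 0.0, 1.0, 10, 6, rate_units="per_time")
        traps = build_trap_pattern(10.0, 6)
        sources = SynthesisPattern({2, 5})
        state = BoxState(np.arange(6.0), np.zeros(6))
        dnu, dnb = multibox_rhs(state, cfg, traps, sources)
        assert np.allclose(dnb, 0.0)
        assert np.allclose(dnu, [0.0, 0.4, 0.0, 0.0, 0.4, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.data(), M=st.integers(1, 12))
    def test_derivative_conservation(self, data, M):
        """Summed derivatives equal alpha_syn * |sources| exactly."""
        nu = np.array(data.draw(st.lists(
            st.floats(0, 1e3, allow_nan=False), min_size=M, max_size=M)))
        caps = np.array(data.draw(st.lists(
            st.floats(0, 100, allow_nan=False), min_size=M, max_size=M)))
        nb = caps * data.draw(st.floats(0, 1))
        srcs = data.draw(st.sets(st.integers(1, M)))
        cfg = SystemConfig(0.37, 0.011, 0.04, 1.0, 10, M, rate_units="per_time")
        dnu, dnb = multibox_rhs(
            BoxState(nu, nb), cfg, build_trap_pattern(caps, M), SynthesisPattern(srcs))
        total = float(np.sum(dnu) + np.sum(dnb))
        expected = 0.37 * len(srcs)
        assert total == pytest.approx(expected, rel=1e-9, abs=1e-7)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data(), M=st.integers(2, 10))
    def test_mirror_symmetry(self, data, M):
        """Mirroring state, traps, and sources mirrors the derivatives."""
        nu = np.array(data.draw(st.lists(
            st.floats(0, 50, allow_nan=False), min_size=M, max_size=M)))
        caps = np.array(data.draw(st.lists(
            st.floats(0, 20, allow_nan=False), min_size=M, max_size=M)))
        nb = caps * 0.5
        srcs = data.draw(st.sets(st.integers(1, M), min_size=1))
        cfg = SystemConfig(0.2, 0.01, 0.07, 1.0, 10, M, rate_units="per_time")
        dnu, dnb = multibox_rhs(
            BoxState(nu, nb), cfg, build_trap_pattern(caps, M), SynthesisPattern(srcs))
        mirrored = SynthesisPattern({M + 1 - i for i in srcs})
        dnu_m, dnb_m = multibox_rhs(
            BoxState(nu[::-1], nb[::-1]), cfg,
            build_trap_pattern(caps[::-1], M), mirrored)
        assert np.allclose(dnu_m, dnu[::-1], rtol=1e-12, atol=1e-12)
        assert np.allclose(dnb_m, dnb[::-1], rtol=1e-12, atol=1e-12)


class TestConfigGuards:
    def test_diffusion_stability_guard(self):
        with pytest.raises(ConfigError, match="stability"):
            SystemConfig(0.0, 0.0, 0.6, 1.0, 10, 2, rate_units="per_time")

    def test_binding_depletion_guard(self):
        cfg = SystemConfig(0.0, 0.2, 0.0, 1.0, 10, 1, rate_units="per_time")
        with pytest.raises(ConfigError, match="depletion"):
            cfg.validate_against_traps(build_trap_pattern(100.0, 1))

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError, match="alpha_syn"):
            SystemConfig(-1.0, 0.0, 0.0, 1.0, 10, 1)

    def test_per_dt_units_rescale_rates(self):
        cfg = SystemConfig(2e-4, 2e-3, 0.045, 2.0, 10, 1, rate_units="per_dt")
        assert cfg.alpha_per_t == pytest.approx(1e-4)
        assert cfg.alpha_step == pytest.approx(2e-4)
        assert cfg.kappa_step == pytest.approx(2e-3)
        assert cfg.D_step == pytest.approx(0.045)

    def test_source_indices_validated(self):
        with pytest.raises(ConfigError, match="out of range"):
            SynthesisPattern({0, 3}).mask(5)
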