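import numpy as np
import pytest
from scipy.integrate import solve_ivp

from clotsim2d.params import default_parameters
from clotsim2d.surface import (
    SurfaceState,
    available_sites,
    platelet_reaction_step,
    se_reaction_step,
)


class TestAvailableSites:
    def test_95pct_available_at_60s(self, kin):
        frac = available_sites(60.0, 1.0, kin.k_act)
        assert frac == pytest.approx(0.95, abs=0.005)

    def test_zero_at_start(self, kin):
        assert available_sites(0.0, kin.N1_max, kin.k_act) == 0.0

    def test_saturates_at_nmax(self, kin):
        assert available_sites(1e6, kin.N1_max, kin.k_act) == pytest.approx(
            kin.N1_max, rel=1e-12
        )

    def test_negative_time_rejected(self, kin):
        with pytest.raises(ValueError):
            available_sites(-1.0, kin.N1_max, kin.k_act)

    def test_monotone_increasing(self, kin):
        t = np.linspace(0, 120, 50)
        n = available_sites(t, kin.N2_max, kin.k_act)
        assert (np.diff(n) > 0).all()


class TestSEReaction:
    def test_all_zero_stays_zero(self, kin):
        c0b, fs1, fe1 = se_reaction_step(np.zeros(3), np.zeros(3), kin, 1e-3)
        assert not c0b.any() and not fs1.any() and not fe1.any()

    def test_fixed_point_matches_analytic(self, kin):
        # with S1 held fixed the scalar ODE has the steady state
        # C0b* = E0 kon S1 / (kon S1 + koff + kcat)
        s1 = np.array([0.17e-6])
        c0b = np.zeros(1)
        for _ in range(20000):
            c0b, _, _ = se_reaction_step(c0b, s1, kin, 1e-3)
        expected = (
            kin.E0 * kin.kC0_on * s1[0]
            / (kin.kC0_on * s1[0] + kin.kC0_off + kin.kC0_cat)
        )
        assert c0b[0] == pytest.approx(expected, rel=1e-6)

    def test_single_euler_step_arithmetic(self, kin):
        # hand-computed one-step update from a fresh surface
        s1 = 0.17e-6
        dt = 1e-3
        bind = kin.kC0_on * s1 * kin.E0  # fmol/cm^2/s
        c0b, fs1, fe1 = se_reaction_step(np.zeros(1), np.array([s1]), kin, dt)
        assert c0b[0] == pytest.approx(dt * bind, rel=1e-12)
        assert fs1[0] == pytest.approx(-bind, rel=1e-12)
        assert fe1[0] == 0.0


class TestPlateletReaction:
    def test_zero_state_zero_fluid_stays_zero(self, kin):
        state = SurfaceState.zeros(0, 4)
        fluid = {k: np.zeros(4) for k in ("S1", "E1", "S2", "E2")}
        new, fluxes = platelet_reaction_step(state, fluid, 10.0, 10.0, kin, 1e-3)
        for name in ("s1b", "e1b", "s2b", "e2b", "c1b", "c2b"):
            assert not getattr(new, name).any()
        for f in fluxes.values():
            assert not f.any()

    def test_no_binding_when_sites_full(self, kin):
        state = SurfaceState.zeros(0, 1)
        n1 = 10.0
        state.s1b[:] = n1  # P1 fully occupied by S1b
        fluid = {k: np.zeros(1) for k in ("S1", "E1", "S2", "E2")}
        fluid["S1"] = np.array([1e-6])
        _, fluxes = platelet_reaction_step(state, fluid, n1, 10.0, kin, 1e-6)
        # no free sites: only unbinding, no uptake from the fluid
        assert fluxes["S1"][0] == pytest.approx(kin.kS1_off * n1)

    def test_single_euler_step_arithmetic(self, kin):
        # fully specified nonzero state; expected update recomputed here
        # with plain arithmetic
        dt = 1e-4
        n1, n2 = 12.0, 9.0
        state = SurfaceState.zeros(0, 1)
        state.s1b[:] = 2.0
        state.e1b[:] = 1.0
        state.s2b[:] = 3.0
        state.e2b[:] = 0.5
        state.c1b[:] = 0.25
        state.c2b[:] = 0.125
        fluid = {
            "S1": np.array([1.0e-7]),
            "E1": np.array([2.0e-9]),
            "S2": np.array([1.0e-6]),
            "E2": np.array([5.0e-9]),
        }
        f1 = n1 - (2.0 + 1.0 + 0.25 + 0.125)
        f2 = n2 - (3.0 + 0.5 + 0.25 + 0.125)
        j_s1 = kin.kS1_on * f1 * 1.0e-7 - kin.kS1_off * 2.0
        j_e1 = kin.kE1_on * f1 * 2.0e-9 - kin.kE1_off * 1.0
        j_s2 = kin.kS2_on * f2 * 1.0e-6 - kin.kS2_off * 3.0
        j_e2 = kin.kE2_on * f2 * 5.0e-9 - kin.kE2_off * 0.5
        form1 = kin.kC1_on_s * 3.0 * 1.0
        form2 = kin.kC2_on_s * 2.0 * 0.5
        new, fluxes = platelet_reaction_step(state, fluid, n1, n2, kin, dt)
        assert new.s1b[0] == pytest.approx(
            2.0 + dt * (j_s1 - form2 + kin.kC2_off * 0.125), rel=1e-12
        )
        assert new.s2b[0] == pytest.approx(
            3.0 + dt * (j_s2 - form1 + kin.kC1_off * 0.25), rel=1e-12
        )
        assert new.c1b[0] == pytest.approx(
            0.25 + dt * (form1 - (kin.kC1_off + kin.kC1_cat) * 0.25), rel=1e-12
        )
        assert new.c2b[0] == pytest.approx(
            0.125 + dt * (form2 - (kin.kC2_off + kin.kC2_cat) * 0.125), rel=1e-12
        )
        assert new.e1b[0] == pytest.approx(
            1.0
            + dt
            * (
                j_e1
                - form1
                + kin.kC1_off * 0.25
                + kin.kC1_cat * 0.25
                + kin.kC2_cat * 0.125
            ),
            rel=1e-12,
        )
        assert new.e2b[0] == pytest.approx(
            0.5
            + dt
            * (
                j_e2
                - form2
                + kin.kC2_off * 0.125
                + kin.kC1_cat * 0.25
                + kin.kC2_cat * 0.125
            ),
            rel=1e-12,
        )
        assert fluxes["S1"][0] == pytest.approx(-j_s1, rel=1e-12)
        assert fluxes["E2"][0] == pytest.approx(-j_e2, rel=1e-12)

    def test_occupancy_bounded_over_time(self, kin):
        # saturating fluid concentrations must not overfill the sites
        state = SurfaceState.zeros(0, 1)
        fluid = {
            "S1": np.array([1e-6]),
            "E1": np.array([1e-7]),
            "S2": np.array([2e-6]),
            "E2": np.array([1e-7]),
        }
        n1, n2 = 23.5, 17.4
        dt = 5e-4
        for _ in range(4000):
            state, _ = platelet_reaction_step(state, fluid, n1, n2, kin, dt)
            state.check(n1, n2, kin.E0)
        assert state.p1_occupancy()[0] <= n1 * (1 + 1e-6)
        assert state.p2_occupancy()[0] <= n2 * (1 + 1e-6)

    def test_matches_stiff_ode_oracle(self, kin):
        """Single-element trajectory vs an independent LSODA integration."""
        fluid = {
            "S1": np.array([0.17e-6]),
            "E1": np.array([1e-9]),
            "S2": np.array([1.4e-6]),
            "E2": np.array([1e-9]),
        }
        n1, n2 = 20.0, 15.0
        t_end = 2.0

        def rhs(t, y):
            s1b, e1b, s2b, e2b, c1b, c2b = y
            f1 = max(n1 - (s1b + e1b + c1b + c2b), 0.0)
            f2 = max(n2 - (s2b + e2b + c1b + c2b), 0.0)
            js1 = kin.kS1_on * f1 * fluid["S1"][0] - kin.kS1_off * s1b
            je1 = kin.kE1_on * f1 * fluid["E1"][0] - kin.kE1_off * e1b
            js2 = kin.kS2_on * f2 * fluid["S2"][0] - kin.kS2_off * s2b
            je2 = kin.kE2_on * f2 * fluid["E2"][0] - kin.kE2_off * e2b
            form1 = kin.kC1_on_s * s2b * e1b
            form2 = kin.kC2_on_s * s1b * e2b
            return [
                js1 - form2 + kin.kC2_off * c2b,
                je1 - form1 + (kin.kC1_off + kin.kC1_cat) * c1b + kin.kC2_cat * c2b,
                js2 - form1 + kin.kC1_off * c1b,
                je2 - form2 + (kin.kC2_off + kin.kC2_cat) * c2b + kin.kC1_cat * c1b,
                form1 - (kin.kC1_off + kin.kC1_cat) * c1b,
                form2 - (kin.kC2_off + kin.kC2_cat) * c2b,
            ]

        sol = solve_ivp(
            rhs, (0, t_end), np.zeros(6), method="LSODA", rtol=1e-10, atol=1e-14
        )
        state = SurfaceState.zeros(0, 1)
        dt = 1e-4
        for _ in range(int(t_end / dt)):
            state, _ = platelet_reaction_step(state, fluid, n1, n2, kin, dt)
        euler = np.array(
            [state.s1b[0], state.e1b[0], state.s2b[0], state.e2b[0],
             state.c1b[0], state.c2b[0]]
        )
        scale = np.abs(sol.y[:, -1]).max()
        assert np.abs(euler - sol.y[:, -1]).max() / scale < 1e-3

    def test_substrate_conserved_without_catalysis(self, kin):
        """Binding/unbinding alone conserves bound + fluid S1 in a box.

        Checked here at the ODE level with an analytically closed pair;
        the full closed-box PDE audit lives in the transport tests.
        """
        from dataclasses import replace

        k = replace(kin, kC0_cat=0.0, kC1_cat=0.0, kC2_cat=0.0)
        state = SurfaceState.zeros(0, 1)
        # track total S1: fluid amount fixed here, so monitor that the
        # complex cycle conserves S1b + C2b
        state.s1b[:] = 5.0
        state.e2b[:] = 3.0
        fluid = {kname: np.zeros(1) for kname in ("S1", "E1", "S2", "E2")}
        k = replace(k, kS1_off=0.0, kE2_off=0.0)
        total0 = state.s1b[0] + state.c2b[0]
        for _ in range(2000):
            state, _ = platelet_reaction_step(state, fluid, 20.0, 20.0, k, 1e-3)
        assert state.s1b[0] + state.c2b[0] == pytest.approx(total0, rel=1e-9)
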