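import numpy as np
import pytest

from clotsim2d.flow import FlowField
from clotsim2d.geometry import Grid2D, PlateletPlug, PlugConfig, rasterize
from clotsim2d.surface import SurfaceState
from clotsim2d.transport import (
    CoagulationFields,
    TransportOperator,
    advance_species,
    apply_AT_inhibition,
    coagulation_step,
    surface_flux_to_source,
)

from conftest import empty_mask


def _uniform_flow(grid, speed):
    return FlowField(
        grid=grid,
        u=np.full((grid.nx + 1, grid.ny), speed),
        v=np.zeros((grid.nx, grid.ny + 1)),
        p=np.zeros((grid.nx, grid.ny)),
    )


class TestTransportOperator:
    def test_uniform_field_is_invariant(self):
        mask = empty_mask(20.0, 10.0, 0.5)
        flow = _uniform_flow(mask.grid, 100.0)
        op = TransportOperator(mask, flow, 50.0, dt=0.01)
        c = np.full((mask.grid.nx, mask.grid.ny), 3.0)
        out = op.step(c, inlet_value=3.0)
        assert np.allclose(out, 3.0, rtol=1e-10)

    def test_point_release_variance_grows_2Dt(self):
        # pure diffusion in a closed box: the discrete second moment of
        # the heat kernel grows at exactly 2*D per unit time
        D = 50.0
        mask = empty_mask(40.0, 40.0, 1.0)
        op = TransportOperator(mask, None, D, dt=1e-3, closed=True)
        c = np.zeros((40, 40))
        c[20, 20] = 1.0
        X, Y = mask.grid.cell_centers()
        x0, y0 = X[20, 20], Y[20, 20]
        n_steps, dt = 100, 1e-3
        for _ in range(n_steps):
            c = op.step(c)
        t = n_steps * dt
        var_x = float((c * (X - x0) ** 2).sum() / c.sum())
        assert var_x == pytest.approx(2 * D * t, rel=0.02)

    def test_advected_blob_mass_conserved(self):
        mask = empty_mask(60.0, 10.0, 1.0)
        flow = _uniform_flow(mask.grid, 200.0)
        op = TransportOperator(mask, flow, 10.0, dt=1e-3)
        c = np.zeros((60, 10))
        c[25:32, 3:7] = 5.0
        total0 = op.total(c)
        for _ in range(20):  # blob stays far from both ends
            c = op.step(c, inlet_value=0.0)
        assert op.total(c) == pytest.approx(total0, rel=1e-8)

    def test_closed_box_conserves_mass_with_diffusion(self):
        mask = empty_mask(10.0, 10.0, 0.5)
        op = TransportOperator(mask, None, 50.0, dt=0.01, closed=True)
        rng = np.random.default_rng(0)
        c = rng.random((20, 20))
        total0 = op.total(c)
        for _ in range(50):
            c = op.step(c)
        assert op.total(c) == pytest.approx(total0, rel=1e-10)

    def test_transport_rate_of_uniform_field_is_zero(self):
        mask = empty_mask(20.0, 10.0, 0.5)
        flow = _uniform_flow(mask.grid, 100.0)
        op = TransportOperator(mask, flow, 50.0, dt=0.01)
        c = np.full((mask.grid.nx, mask.grid.ny), 7.0)
        rate = op.transport_rate(c, inlet_value=7.0)
        assert np.abs(rate).max() < 1e-10


class TestATInhibition:
    def test_exact_decay(self):
        e2 = np.array([[100.0]])
        out = apply_AT_inhibition(e2, 0.0336, 1.0)
        assert out[0, 0] == pytest.approx(100.0 * np.exp(-0.0336), rel=1e-12)
        assert out[0, 0] == pytest.approx(96.70, abs=0.01)

    def test_zero_rate_is_identity(self):
        e2 = np.array([[42.0]])
        assert apply_AT_inhibition(e2, 0.0, 1.0)[0, 0] == 42.0

    def test_long_time_limit(self):
        e2 = np.array([[100.0]])
        for _ in range(100):
            e2 = apply_AT_inhibition(e2, 0.5, 1.0)
        assert e2[0, 0] < 1e-15


class TestSurfaceFluxCoupling:
    def test_flux_to_source_scaling(self):
        """1 fmol/cm^2/s over one h-long face adds 10/h nM/s to its cell."""
        grid = Grid2D(4.0, 4.0, 0.5)
        cfg = PlugConfig(gap=0.5, half_width=1.5, height=1.5, center_x=2.0)
        plug = PlateletPlug(np.array([[2.0, 2.0]]), 0.6, cfg)
        mask = rasterize(plug, grid, (0.0, 0.0))
        flux = np.ones(len(mask.iface_cell))
        src = surface_flux_to_source(mask, flux)
        i, j = mask.iface_cell[0]
        expected = 10.0 * mask.iface_length[0] / grid.cell_area
        assert src[i, j] >= expected - 1e-12  # cell may own several faces

    def test_amount_balance_units(self):
        # total fmol/s added to the fluid equals flux x total face area
        grid = Grid2D(4.0, 4.0, 0.25)
        cfg = PlugConfig(gap=0.5, half_width=1.8, height=1.8, center_x=2.0)
        plug = PlateletPlug(np.array([[2.0, 2.0]]), 0.8, cfg)
        mask = rasterize(plug, grid, (0.0, 0.0))
        flux = np.full(len(mask.iface_cell), 2.5)  # fmol/cm^2/s
        src = surface_flux_to_source(mask, flux)  # nM/s
        fmol_per_s = src.sum() * grid.cell_area * 1.0 * 1e-9  # nM um^3 -> fmol
        face_area_cm2 = mask.iface_length.sum() * 1.0 * 1e-8
        assert fmol_per_s == pytest.approx(2.5 * face_area_cm2, rel=1e-12)


class TestCoagulationStep:
    def _mini_system(self, closed=False, se=True):
        grid = Grid2D(8.0, 6.0, 0.25)
        cfg = PlugConfig(gap=0.5, half_width=2.5, height=2.5, center_x=4.0)
        plug = PlateletPlug(np.array([[4.0, 2.5]]), 1.23, cfg)
        strip = (2.0, 6.0) if se else (0.0, 0.0)
        mask = rasterize(plug, grid, strip)
        op = TransportOperator(mask, None, 50.0, dt=0.005, closed=closed)
        return mask, op

    def test_no_reaction_no_enzymes(self, kin):
        from dataclasses import replace

        mask, op = self._mini_system(se=True)
        k = replace(kin, E0=0.0)
        fields = CoagulationFields.initial(mask, k)
        surface = SurfaceState.zeros(len(mask.se_cell), 0)
        # empty interface list: drop platelet coupling entirely
        mask.iface_cell = np.empty((0, 2), dtype=int)
        mask.iface_platelet = np.empty(0, dtype=int)
        mask.iface_length = np.empty(0)
        for step in range(20):
            fields, surface = coagulation_step(
                fields, surface, mask, op, k, step * 0.005, 0.005
            )
        assert not fields.E1.any() and not fields.E2.any()
        assert fields.S1[mask.fluid].min() == pytest.approx(k.S1_0_nM, rel=1e-6)

    def test_closed_box_substrate_conservation(self, kin):
        """Binding only (no catalysis): fluid + bound S1 is conserved."""
        from dataclasses import replace

        mask, op = self._mini_system(closed=True, se=False)
        k = replace(kin, kC0_cat=0.0, kC1_cat=0.0, kC2_cat=0.0, k_AT=0.0)
        fields = CoagulationFields.initial(mask, k)
        surface = SurfaceState.zeros(len(mask.se_cell), len(mask.iface_cell))

        def total_s1_fmol():
            fluid_fmol = fields.S1[mask.fluid].sum() * mask.grid.cell_area * 1e-9
            bound_fmol = (
                (surface.s1b + surface.c2b) * mask.iface_length * 1e-8
            ).sum()
            return fluid_fmol + bound_fmol

        t0 = total_s1_fmol()
        for step in range(100):
            fields, surface = coagulation_step(
                fields, surface, mask, op, k, step * 0.005, 0.005
            )
        assert total_s1_fmol() == pytest.approx(t0, rel=1e-6)

    def test_enzyme_production_onset(self, kin):
        """SE + platelet cascade produces strictly growing E1 and E2."""
        mask, op = self._mini_system(se=True)
        fields = CoagulationFields.initial(mask, kin)
        surface = SurfaceState.zeros(len(mask.se_cell), len(mask.iface_cell))
        e1_totals = []
        for step in range(200):
            fields, surface = coagulation_step(
                fields, surface, mask, op, kin, step * 0.005, 0.005
            )
            if (step + 1) % 50 == 0:
                e1_totals.append(op.total(fields.E1))
        assert e1_totals[0] > 0
        assert all(b > a for a, b in zip(e1_totals, e1_totals[1:]))
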