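"""Fluid-phase species transport and the coupled coagulation step.

Each transported concentration field (nM, cell-centred on fluid cells)
advances by one implicit step per time step:

    (I/dt + A + D) c^{n+1} = c^n/dt + sources

with A the first-order upwind advection operator built from the steady
face velocities and D the five-point diffusion operator with zero-flux
closure at walls, solid faces and the outlet.  Inlet cells are pinned
to the species' plasma value (Dirichlet).  Because the flow is steady
and the diffusivity is shared, the matrix is assembled and factorized
once per scenario and reused for every species and step; the implicit
form removes the advective CFL restriction of the narrow interplatelet
gaps.

Boundary fluxes from surface reactions (fmol cm^-2 s^-1) are converted
to volumetric sources on the interface-adjacent cells via
flux x face length x unit depth / cell volume; unit depth is 1 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from clotsim2d.flow import FlowField
from clotsim2d.geometry import DomainMask
from clotsim2d.params import KineticParams
from clotsim2d.surface import (
    SurfaceState,
    available_sites,
    platelet_reaction_step,
    se_reaction_step,
)

__all__ = [
    "CoagulationFields",
    "TransportOperator",
    "advance_species",
    "apply_AT_inhibition",
    "coagulation_step",
    "surface_flux_to_source",
]

#: Unit depth of the 2D slab, um; makes 2D "amounts" well-defined.
UNIT_DEPTH = 1.0

#: fmol/cm^2/s * um / um^2 -> nM/s  (1e-8 area conversion x 1e9 nM/M)
_FLUX_TO_NM = 10.0


@dataclass
class CoagulationFields:
    """Fluid-phase coagulation concentrations, nM, shape (nx, ny)."""

    S1: np.ndarray
    E1: np.ndarray
    S2: np.ndarray
    E2: np.ndarray

    @classmethod
    def initial(cls, mask: DomainMask, kin: KineticParams) -> "CoagulationFields":
        """Substrates at plasma values on fluid cells, enzymes at zero."""
        fluid = mask.fluid
        shape = mask.labels.shape
        s1 = np.where(fluid, kin.S1_0_nM, 0.0)
        s2 = np.where(fluid, kin.S2_0_nM, 0.0)
        return cls(S1=s1, E1=np.zeros(shape), S2=s2, E2=np.zeros(shape))


class TransportOperator:
    """Pre-factorized implicit advection-diffusion operator.

    Parameters
    ----------
    mask : DomainMask
        Fluid/solid classification of the grid.
    flow : FlowField or None
        Steady face velocities; None means diffusion only.
    diffusivity : float
        um^2/s, shared by all species using this operator.
    dt : float
        Time-step size bound into the factorization, s.
    closed : bool
        If True, no inlet/outlet coupling anywhere (a closed box with
        zero-flux walls); used for conservation audits.
    """

    def __init__(
        self,
        mask: DomainMask,
        flow: FlowField | None,
        diffusivity: float,
        dt: float,
        closed: bool = False,
    ) -> None:
        self.mask = mask
        self.grid = mask.grid
        self.dt = dt
        self.closed = closed
        self.D = diffusivity
        nx, ny, h = self.grid.nx, self.grid.ny, self.grid.h
        fluid = mask.fluid
        n = nx * ny

        if flow is not None:
            u, v = flow.u, flow.v
        else:
            u = np.zeros((nx + 1, ny))
            v = np.zeros((nx, ny + 1))
        self._u, self._v = u, v

        def idx(i, j):
            return i * ny + j

        rows, cols, vals = [], [], []
        inlet_vec = np.zeros(n)  # transport-rate contribution per unit inlet conc
        dh2 = diffusivity / (h * h)

        self._dirichlet = np.zeros((nx, ny), dtype=bool)
        if not closed:
            self._dirichlet[0, :] = fluid[0, :]

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        for i in range(nx):
            for j in range(ny):
                r = idx(i, j)
                if not fluid[i, j] or self._dirichlet[i, j]:
                    continue
                diag = 0.0
                # diffusion across the four faces (fluid-fluid only)
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nx and 0 <= jj < ny and fluid[ii, jj]:
                        diag += dh2
                        add(r, idx(ii, jj), -dh2)
                # upwind advection: west/east faces carry u, south/north carry v
                uw, ue = u[i, j], u[i + 1, j]
                vs, vn = v[i, j], v[i, j + 1]
                # west face: inflow from (i-1, j) if uw > 0, outflow if uw < 0
                if uw > 0:
                    if i > 0:
                        add(r, idx(i - 1, j), -uw / h)
                elif uw < 0:
                    diag += -uw / h
                # east face
                if ue > 0:
                    diag += ue / h
                elif ue < 0:
                    if i + 1 < nx:
                        add(r, idx(i + 1, j), ue / h)
                    # else inflow of outside (zero) concentration
                if vs > 0:
                    if j > 0:
                        add(r, idx(i, j - 1), -vs / h)
                elif vs < 0:
                    diag += -vs / h
                if vn > 0:
                    diag += vn / h
                elif vn < 0:
                    if j + 1 < ny:
                        add(r, idx(i, j + 1), vn / h)
                add(r, r, diag)

        self._L = sp.csr_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
        )

        # system matrix: interior rows I/dt + L; Dirichlet & solid rows I
        interior = fluid & ~self._dirichlet
        diag_I = np.where(interior.ravel(), 1.0 / dt, 0.0)
        fixed = (~interior).ravel().astype(float)
        A = self._L + sp.diags(diag_I) + sp.diags(fixed)
        self._interior = interior
        self._lu = spla.splu(sp.csc_matrix(A))

    def step(
        self,
        c: np.ndarray,
        inlet_value: float = 0.0,
        source: np.ndarray | None = None,
    ) -> np.ndarray:
        """Advance one implicit step; source in nM/s on interior cells."""
        nx, ny = self.grid.nx, self.grid.ny
        rhs = np.zeros(nx * ny)
        interior = self._interior.ravel()
        rhs[interior] = c.ravel()[interior] / self.dt
        if source is not None:
            rhs[interior] += source.ravel()[interior]
        rhs[self._dirichlet.ravel()] = inlet_value
        out = self._lu.solve(rhs)
        out[~self.mask.fluid.ravel()] = 0.0
        return out.reshape(nx, ny)

    def transport_rate(self, c: np.ndarray, inlet_value: float = 0.0) -> np.ndarray:
        """-u.grad(c) + D lap(c) with the solver's stencils, nM/s.

        Dirichlet cells are held at the inlet value for the stencil.
        """
        cc = c.copy()
        cc[self._dirichlet] = inlet_value
        rate = -(self._L @ cc.ravel())
        rate[~self._interior.ravel()] = 0.0
        return rate.reshape(c.shape)

    def total(self, c: np.ndarray) -> float:
        """Domain total of a field, nM um^3 (unit depth)."""
        return float(c[self.mask.fluid].sum() * self.grid.cell_area * UNIT_DEPTH)


def advance_species(
    op: TransportOperator,
    c: np.ndarray,
    inlet_value: float = 0.0,
    source: np.ndarray | None = None,
) -> np.ndarray:
    """One implicit advection-diffusion step of a single species."""
    out = op.step(c, inlet_value=inlet_value, source=source)
    if out.min() < -1.0e-10 * max(abs(inlet_value), out.max(), 1.0):
        raise RuntimeError(f"negative concentration after transport: {out.min():.3e}")
    return out


def apply_AT_inhibition(e2: np.ndarray, k_AT: float, dt: float) -> np.ndarray:
    """Pointwise first-order antithrombin decay, exact over the step."""
    if k_AT < 0:
        raise ValueError("k_AT must be nonnegative")
    return e2 * np.exp(-k_AT * dt)


def surface_flux_to_source(
    mask: DomainMask,
    iface_flux: np.ndarray,
    se_flux: np.ndarray | None = None,
) -> np.ndarray:
    """Scatter boundary fluxes (fmol cm^-2 s^-1, positive into the
    fluid) onto cell-centred volumetric sources, nM/s."""
    grid = mask.grid
    src = np.zeros((grid.nx, grid.ny))
    conv = _FLUX_TO_NM / grid.cell_area  # x face length -> nM/s
    if len(mask.iface_cell):
        np.add.at(
            src,
            (mask.iface_cell[:, 0], mask.iface_cell[:, 1]),
            iface_flux * mask.iface_length * conv,
        )
    if se_flux is not None and len(mask.se_cell):
        np.add.at(
            src,
            (mask.se_cell[:, 0], mask.se_cell[:, 1]),
            se_flux * mask.se_length * conv,
        )
    return src


def coagulation_step(
    fields: CoagulationFields,
    surface: SurfaceState,
    mask: DomainMask,
    op: TransportOperator,
    kin: KineticParams,
    t: float,
    dt: float,
    n_surface_substeps: int = 4,
) -> tuple[CoagulationFields, SurfaceState]:
    """Advance the coupled surface + fluid coagulation system by dt.

    Sequence: evaluate available binding sites at t; advance the SE and
    platelet surface ODEs by forward Euler (sub-stepped for stability),
    accumulating time-averaged boundary fluxes; advance the four fluid
    species with those fluxes as sources; apply antithrombin decay to E2.
    """
    se_c = (mask.se_cell[:, 0], mask.se_cell[:, 1]) if len(mask.se_cell) else None
    if_c = (mask.iface_cell[:, 0], mask.iface_cell[:, 1]) if len(mask.iface_cell) else None

    sub_dt = dt / n_surface_substeps
    acc = {k: 0.0 for k in ("S1", "E1", "S2", "E2")}
    acc_se_s1 = 0.0
    acc_se_e1 = 0.0
    for s in range(n_surface_substeps):
        ts = t + s * sub_dt
        n1_t = available_sites(ts, kin.N1_max, kin.k_act)
        n2_t = available_sites(ts, kin.N2_max, kin.k_act)
        if se_c is not None:
            s1_wall_M = fields.S1[se_c] * 1.0e-9
            surface.c0b, fs1, fe1 = se_reaction_step(surface.c0b, s1_wall_M, kin, sub_dt)
            acc_se_s1 = acc_se_s1 + fs1 / n_surface_substeps
            acc_se_e1 = acc_se_e1 + fe1 / n_surface_substeps
        if if_c is not None and len(surface.s1b):
            fluid_M = {
                "S1": fields.S1[if_c] * 1.0e-9,
                "E1": fields.E1[if_c] * 1.0e-9,
                "S2": fields.S2[if_c] * 1.0e-9,
                "E2": fields.E2[if_c] * 1.0e-9,
            }
            surface, fl = platelet_reaction_step(surface, fluid_M, n1_t, n2_t, kin, sub_dt)
            for k in acc:
                acc[k] = acc[k] + fl[k] / n_surface_substeps

    src_s1 = surface_flux_to_source(mask, acc["S1"] if if_c else np.zeros(0), acc_se_s1 if se_c is not None else None)
    src_e1 = surface_flux_to_source(mask, acc["E1"] if if_c else np.zeros(0), acc_se_e1 if se_c is not None else None)
    src_s2 = surface_flux_to_source(mask, acc["S2"] if if_c else np.zeros(0))
    src_e2 = surface_flux_to_source(mask, acc["E2"] if if_c else np.zeros(0))

    new = CoagulationFields(
        S1=advance_species(op, fields.S1, kin.S1_0_nM if not op.closed else 0.0, src_s1),
        E1=advance_species(op, fields.E1, 0.0, src_e1),
        S2=advance_species(op, fields.S2, kin.S2_0_nM if not op.closed else 0.0, src_s2),
        E2=advance_species(op, fields.E2, 0.0, src_e2),
    )
    new.E2 = apply_AT_inhibition(new.E2, kin.k_AT, dt)
    return new, surface
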