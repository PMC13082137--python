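"""Steady incompressible channel flow around the discrete platelets.

The velocity field is solved on a marker-and-cell (MAC) staggered grid:
u on vertical cell faces, v on horizontal faces, pressure at cell
centres.  Platelets enter through solid-cell masking: velocity unknowns
inside or on the boundary of solid cells are pinned to zero and no-slip
is imposed on the staircase boundary through ghost reflection of the
tangential velocity.  At plug scale the Reynolds number is far below
one, so the steady Stokes system (a single sparse linear solve) is the
default; a Picard-iterated Navier-Stokes mode is available for the open
channel where Re ~ 1.

Boundary conditions: parabolic inlet profile with prescribed wall shear
rate, zero-pressure outflow with zero streamwise velocity gradient,
no-slip on the channel walls and all platelet surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from clotsim2d.geometry import DomainMask, Grid2D
from clotsim2d.params import FluidParams

__all__ = [
    "FlowField",
    "FlowStats",
    "poiseuille_profile",
    "solve_steady_flow",
    "intraplug_stats",
]


@dataclass
class FlowField:
    """Steady velocity (um/s) and pressure on the MAC grid.

    u has shape (nx+1, ny) on vertical faces, v has shape (nx, ny+1) on
    horizontal faces, p has shape (nx, ny) at cell centres.
    """

    grid: Grid2D
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centred velocity components by face averaging."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc

    def speed(self) -> np.ndarray:
        uc, vc = self.cell_velocity()
        return np.hypot(uc, vc)

    def divergence(self) -> np.ndarray:
        """Discrete divergence per cell, 1/s."""
        h = self.grid.h
        return (np.diff(self.u, axis=0) + np.diff(self.v, axis=1)) / h

    def max_centerline_speed(self) -> float:
        """Maximum velocity magnitude along the channel centreline, um/s."""
        s = self.speed()
        jmid = self.grid.ny // 2
        if self.grid.ny % 2 == 0:
            return float(max(s[:, jmid - 1].max(), s[:, jmid].max()))
        return float(s[:, jmid].max())


@dataclass(frozen=True)
class FlowStats:
    """Intraplug transport summary."""

    mean_intraplug_speed: float  # um/s
    peclet: float  # dimensionless, U*g/D
    max_centerline_speed_mm_s: float


def poiseuille_profile(gamma_dot: float, height: float) -> Callable[[np.ndarray], np.ndarray]:
    """Plane Poiseuille inlet profile with wall shear rate gamma_dot.

    u(y) = gamma_dot * y * (H - y) / H, which has gradient gamma_dot at
    both walls and maximum gamma_dot*H/4 at midchannel.  gamma_dot in
    1/s, height in um; the returned callable maps y (um) to u (um/s).
    """
    if gamma_dot < 0:
        raise ValueError("shear rate must be nonnegative")
    if height <= 0:
        raise ValueError("channel height must be positive")

    def u(y):
        return gamma_dot * np.asarray(y) * (height - np.asarray(y)) / height

    return u


def solve_steady_flow(
    mask: DomainMask,
    fluid: FluidParams,
    mode: str = "stokes",
    picard_tol: float = 1.0e-6,
    picard_maxiter: int = 30,
) -> FlowField:
    """Solve the steady flow problem on a masked MAC grid.

    With ``mode='stokes'`` a single sparse solve of the Stokes saddle
    system is performed (exact for creeping flow, and linear in the
    shear rate).  ``mode='navier-stokes'`` adds the inertial term by
    Picard iteration with the advective momentum flux evaluated from
    the previous iterate.
    """
    if mode not in ("stokes", "navier-stokes"):
        raise ValueError(f"unknown flow mode {mode!r}")
    grid = mask.grid
    nx, ny, h = grid.nx, grid.ny, grid.h
    solid = mask.solid
    if not _has_fluid_path(solid):
        raise RuntimeError("no connected fluid path from inlet to outlet")

    if fluid.shear_rate == 0:
        # no-flow case: the zero field satisfies all boundary conditions
        return FlowField(
            grid=grid,
            u=np.zeros((nx + 1, ny)),
            v=np.zeros((nx, ny + 1)),
            p=np.zeros((nx, ny)),
        )

    mu = fluid.viscosity * 1.0e-3  # mPa*s -> Pa*s; with um and um/s, p is in Pa
    profile = poiseuille_profile(fluid.shear_rate, grid.height)
    yu = (np.arange(ny) + 0.5) * h
    u_in = profile(yu)

    nu, nv = (nx + 1) * ny, nx * (ny + 1)
    n_unk = nu + nv + nx * ny

    def iu(i, j):
        return i * ny + j

    def iv(i, j):
        return nu + i * (ny + 1) + j

    def ip(i, j):
        return nu + nv + i * ny + j

    # classify fixed faces
    u_fixed = np.zeros((nx + 1, ny), dtype=bool)
    u_val = np.zeros((nx + 1, ny))
    u_fixed[0, :] = True
    u_val[0, :] = u_in
    for i in range(1, nx + 1):
        for j in range(ny):
            left_solid = solid[i - 1, j] if i - 1 < nx else False
            right_solid = solid[i, j] if i < nx else False
            if left_solid or right_solid:
                u_fixed[i, j] = True

    v_fixed = np.zeros((nx, ny + 1), dtype=bool)
    v_fixed[:, 0] = True
    v_fixed[:, ny] = True
    for i in range(nx):
        for j in range(1, ny):
            if solid[i, j - 1] or solid[i, j]:
                v_fixed[i, j] = True

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b = np.zeros(n_unk)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    inv_h2 = mu / (h * h)
    inv_h = 1.0 / h

    # --- u momentum ---
    for i in range(nx + 1):
        for j in range(ny):
            r = iu(i, j)
            if u_fixed[i, j]:
                add(r, r, 1.0)
                b[r] = u_val[i, j]
                continue
            diag = 0.0
            # west / east (normal direction, neighbours at distance h)
            for di in (-1, 1):
                ii = i + di
                if ii < 0:
                    continue  # cannot happen (i=0 fixed)
                if ii > nx:
                    # outlet ghost: zero streamwise gradient -> ghost = self
                    diag += 0.0
                    continue
                diag -= 1.0
                if not u_fixed[ii, j]:
                    add(r, iu(ii, j), inv_h2)
                elif u_val[ii, j] != 0.0:
                    b[r] -= inv_h2 * u_val[ii, j]
                # fixed-zero neighbour: Dirichlet 0 at distance h, no entry
            # south / north (tangential; walls and solid via ghost reflection)
            for dj in (-1, 1):
                jj = j + dj
                if jj < 0 or jj >= ny or u_fixed[i, jj]:
                    # no-slip boundary halfway: ghost = -self
                    diag -= 2.0
                else:
                    diag -= 1.0
                    add(r, iu(i, jj), inv_h2)
            add(r, r, inv_h2 * diag)
            # pressure gradient -(p_i - p_{i-1})/h ; p at i==nx is outlet 0
            if i < nx:
                add(r, ip(i, j), -inv_h)
            add(r, ip(i - 1, j), inv_h)

    # --- v momentum ---
    for i in range(nx):
        for j in range(ny + 1):
            r = iv(i, j)
            if v_fixed[i, j]:
                add(r, r, 1.0)
                continue
            diag = 0.0
            for dj in (-1, 1):  # normal direction
                jj = j + dj
                diag -= 1.0
                if 0 <= jj <= ny and not v_fixed[i, jj]:
                    add(r, iv(i, jj), inv_h2)
            for di in (-1, 1):  # tangential
                ii = i + di
                if ii < 0:
                    diag -= 2.0  # inlet: v = 0 on the boundary plane
                elif ii >= nx:
                    pass  # outlet: zero-gradient ghost = self
                elif v_fixed[ii, j]:
                    diag -= 2.0
                else:
                    diag -= 1.0
                    add(r, iv(ii, j), inv_h2)
            add(r, r, inv_h2 * diag)
            add(r, ip(i, j), -inv_h)
            add(r, ip(i, j - 1), inv_h)

    # --- continuity / pressure rows ---
    for i in range(nx):
        for j in range(ny):
            r = ip(i, j)
            if solid[i, j]:
                add(r, r, 1.0)
                continue
            for face, sign in (((i, j), -1.0), ((i + 1, j), 1.0)):
                fi, fj = face
                if u_fixed[fi, fj]:
                    b[r] -= sign * inv_h * u_val[fi, fj]
                else:
                    add(r, iu(fi, fj), sign * inv_h)
            for face, sign in (((i, j), -1.0), ((i, j + 1), 1.0)):
                fi, fj = face
                if not v_fixed[fi, fj]:
                    add(r, iv(fi, fj), sign * inv_h)

    A = sp.csc_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n_unk, n_unk))
    )
    lu = spla.splu(A)
    x = lu.solve(b)

    def unpack(x):
        u = x[:nu].reshape(nx + 1, ny).copy()
        v = x[nu : nu + nv].reshape(nx, ny + 1).copy()
        p = x[nu + nv :].reshape(nx, ny).copy()
        u[u_fixed] = u_val[u_fixed]
        v[v_fixed] = 0.0
        return u, v, p

    u, v, p = unpack(x)

    if mode == "navier-stokes" and fluid.shear_rate > 0:
        rho = fluid.density * 1.0e-9  # g/cm^3 -> Pa s^2/um^2 scale for um, um/s
        for _ in range(picard_maxiter):
            b_ns = b.copy()
            adv_u, adv_v = _advection_terms(u, v, h)
            free_u = ~u_fixed
            free_v = ~v_fixed
            bu = b_ns[:nu].reshape(nx + 1, ny)
            bu[free_u] += rho * adv_u[free_u]
            bv = b_ns[nu : nu + nv].reshape(nx, ny + 1)
            bv[free_v] += rho * adv_v[free_v]
            x_new = lu.solve(b_ns)
            u_new, v_new, p = unpack(x_new)
            scale = max(np.abs(u_new).max(), 1.0)
            err = max(np.abs(u_new - u).max(), np.abs(v_new - v).max()) / scale
            u, v = u_new, v_new
            if err < picard_tol:
                break
        else:
            raise RuntimeError(
                f"Navier-Stokes Picard iteration did not converge "
                f"(residual {err:.2e} > {picard_tol:.0e})"
            )

    field = FlowField(grid=grid, u=u, v=v, p=p)
    umax = max(np.abs(u).max(), 1.0e-30)
    div = np.abs(field.divergence())[mask.fluid]
    if div.size and div.max() > 1.0e-8 * umax / h:
        raise RuntimeError(
            f"flow solver failed the divergence contract: "
            f"max |div u| = {div.max():.3e} 1/s"
        )
    return field


def _advection_terms(u: np.ndarray, v: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """(u . grad)u evaluated at the u and v face locations (central)."""
    nxp1, ny = u.shape
    nx = nxp1 - 1
    adv_u = np.zeros_like(u)
    # du/dx at u faces
    dudx = np.zeros_like(u)
    dudx[1:-1, :] = (u[2:, :] - u[:-2, :]) / (2 * h)
    dudx[-1, :] = (u[-1, :] - u[-2, :]) / h
    dudy = np.zeros_like(u)
    dudy[:, 1:-1] = (u[:, 2:] - u[:, :-2]) / (2 * h)
    dudy[:, 0] = (u[:, 1] - (-u[:, 0])) / (2 * h)
    dudy[:, -1] = ((-u[:, -1]) - u[:, -2]) / (2 * h)
    # v interpolated to u faces (interior)
    v_at_u = np.zeros_like(u)
    v_cell = 0.5 * (v[:, :-1] + v[:, 1:])  # (nx, ny)
    v_at_u[1:nx, :] = 0.5 * (v_cell[: nx - 1, :] + v_cell[1:nx, :])
    adv_u = -(u * dudx + v_at_u * dudy)

    adv_v = np.zeros_like(v)
    dvdy = np.zeros_like(v)
    dvdy[:, 1:-1] = (v[:, 2:] - v[:, :-2]) / (2 * h)
    dvdx = np.zeros_like(v)
    dvdx[1:-1, :] = (v[2:, :] - v[:-2, :]) / (2 * h)
    u_cell = 0.5 * (u[:-1, :] + u[1:, :])  # (nx, ny)
    u_at_v = np.zeros_like(v)
    u_at_v[:, 1:ny] = 0.5 * (u_cell[:, : ny - 1] + u_cell[:, 1:ny])
    adv_v = -(u_at_v * dvdx + v * dvdy)
    return adv_u, adv_v


def _has_fluid_path(solid: np.ndarray) -> bool:
    """Flood fill: does a fluid path connect inlet to outlet columns?"""
    from collections import deque

    nx, ny = solid.shape
    seen = np.zeros_like(solid, dtype=bool)
    q = deque((0, j) for j in range(ny) if not solid[0, j])
    for c in q:
        seen[c] = True
    while q:
        i, j = q.popleft()
        if i == nx - 1:
            return True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < nx and 0 <= jj < ny and not solid[ii, jj] and not seen[ii, jj]:
                seen[ii, jj] = True
                q.append((ii, jj))
    return bool(seen[nx - 1, :].any())


def intraplug_stats(
    flow: FlowField,
    region: np.ndarray,
    gap: float,
    diffusivity_cm2_s: float,
) -> FlowStats:
    """Average intraplug speed and Peclet number.

    Pe = U * g / D with U the area-weighted mean speed over the
    intraplug fluid region (um/s), g the interplatelet gap (um) and D
    the solute diffusivity (given in cm^2/s).
    """
    if not np.any(region):
        raise ValueError("empty intraplug region")
    speed = flow.speed()
    mean_speed = float(speed[region].mean())
    d_um2 = diffusivity_cm2_s * 1.0e8
    pe = mean_speed * gap / d_um2
    return FlowStats(
        mean_intraplug_speed=mean_speed,
        peclet=pe,
        max_centerline_speed_mm_s=flow.max_centerline_speed() * 1.0e-3,
    )
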