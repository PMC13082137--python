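"""Fibrin branching polymerization with moment closure and gelation.

Thrombin (E2) converts fibrinogen G into fibrin monomers c10 by
Michaelis-Menten kinetics.  Monomers (two reaction sites each) link
pairwise at rate k_l and branch in triples at rate k_b.  Instead of the
doubly-infinite oligomer ledger, the model evolves a closed set of
moments: total free reaction sites R, total monomers in oligomers
theta, branch concentration B, and the gel-progress variable
Y = M02 - R (the second factorial moment of the free-site distribution
minus R), which diverges exactly at the gel point.  Gelation is
declared at the first time Y exceeds Y_max; gelled cells freeze their
polymer state and retain only monomer transport and production.

Only G and c10 are transported (larger oligomers are stationary), so
the state is stored in the transformed variables Rt = R - 2*c10 and
Tt = theta - c10 whose dynamics are purely local:

    dRt/dt = -k_l R^2 - (k_b/2) R^3 + 2 (2 k_l R + k_b R^2) c10
    dTt/dt = (2 k_l R + k_b R^2) c10
    dB/dt  = (k_b/6) R^3
    dY/dt  = k_l Y^2 + k_b R (R^2/2 + R Y + Y^2)
    dc10/dt|reaction = -(2 k_l R + k_b R^2) c10     (ungelled cells)

with R = Rt + 2*c10.  All concentrations in nM; rate constants are the
internal nM-based views of :class:`~clotsim2d.params.KineticParams`.
Reaction updates use an embedded adaptive substep because Y grows
super-linearly approaching the gel point; recorded gel times are
interpolated within the crossing substep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from clotsim2d.geometry import DomainMask, Grid2D
from clotsim2d.params import KineticParams
from clotsim2d.transport import TransportOperator, UNIT_DEPTH

__all__ = [
    "FibrinState",
    "GelationReport",
    "monomer_production_rate",
    "fibrin_reaction_step",
    "update_gelation",
    "gel_area",
]


@dataclass
class FibrinState:
    """Cell-centred fibrin fields, nM (I dimensionless, t_gel in s)."""

    G: np.ndarray
    c10: np.ndarray
    Rt: np.ndarray  # R - 2*c10
    Tt: np.ndarray  # theta - c10
    B: np.ndarray
    Y: np.ndarray
    I: np.ndarray  # gel indicator, bool
    t_gel: np.ndarray  # NaN where ungelled

    @classmethod
    def initial(cls, mask: DomainMask, kin: KineticParams) -> "FibrinState":
        shape = mask.labels.shape
        g = np.where(mask.fluid, kin.G_0_nM, 0.0)
        z = lambda: np.zeros(shape)
        return cls(
            G=g,
            c10=z(),
            Rt=z(),
            Tt=z(),
            B=z(),
            Y=z(),
            I=np.zeros(shape, dtype=bool),
            t_gel=np.full(shape, np.nan),
        )

    @property
    def R(self) -> np.ndarray:
        """Total free reaction sites, nM."""
        return self.Rt + 2.0 * self.c10

    @property
    def theta(self) -> np.ndarray:
        """Total monomers in oligomers (incl. free monomers), nM."""
        return self.Tt + self.c10


@dataclass
class GelationReport:
    """Summary of where and when the fibrin gel formed."""

    first_gel_time: float  # s, inf if no gel
    first_gel_location: tuple[float, float] | None  # um
    times: list
    gel_area: list  # um^2 per recorded time

    def to_dict(self) -> dict:
        return {
            "first_gel_time_s": None if np.isinf(self.first_gel_time) else self.first_gel_time,
            "first_gel_location_um": self.first_gel_location,
            "times_s": list(self.times),
            "gel_area_um2": list(self.gel_area),
        }


def monomer_production_rate(e2, g, k_cat: float, k_m: float):
    """Michaelis-Menten fibrin monomer production, nM/s.

    rate = k_cat * E2 * G / (K_m + G); inputs E2, G and K_m in nM.
    """
    e2 = np.asarray(e2, dtype=float)
    g = np.asarray(g, dtype=float)
    return k_cat * e2 * g / (k_m + g)


def update_gelation(
    y: np.ndarray,
    y_max: float,
    gel: np.ndarray,
    t_gel: np.ndarray,
    t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Flip ungelled cells with Y >= Y_max to gelled, recording t.

    The indicator never reverts; already-gelled cells are untouched.
    """
    newly = (~gel) & (y >= y_max)
    gel = gel | newly
    t_gel = np.where(newly, t, t_gel)
    return gel, t_gel


def gel_area(gel: np.ndarray, grid: Grid2D) -> float:
    """Total gelled area, um^2."""
    return float(np.count_nonzero(gel) * grid.cell_area)


def _reaction_rates(c10, rt, y, k_l, k_b):
    r = rt + 2.0 * c10
    r2 = r * r
    sink = 2.0 * k_l * r + k_b * r2  # c10 consumption rate coefficient, 1/s
    d_rt = -k_l * r2 - 0.5 * k_b * r2 * r + 2.0 * sink * c10
    d_b = (k_b / 6.0) * r2 * r
    d_y = k_l * y * y + k_b * r * (0.5 * r2 + r * y + y * y)
    return r, sink, d_rt, d_b, d_y


def fibrin_reaction_step(
    state: FibrinState,
    e2: np.ndarray,
    mask: DomainMask,
    op: TransportOperator | None,
    kin: KineticParams,
    t: float,
    dt: float,
    safety: float = 0.2,
) -> FibrinState:
    """Advance the fibrin system by one step of size dt from time t.

    Order: implicit transport of G (inlet at plasma fibrinogen) and a
    semi-implicit Michaelis-Menten sink whose removed fibrinogen is the
    exact monomer production; implicit transport of c10 with that
    production as source; then the local polymerization ODEs on
    ungelled cells with adaptive substepping and in-substep gelation
    detection.  Gelled cells keep transport and production only.
    """
    fluid = mask.fluid
    k_l, k_b = kin.k_l_nM, kin.k_b_nM
    k_cat, k_m = kin.k_cat, kin.K_m_nM

    # fibrinogen transport + conversion
    if op is not None:
        g_star = op.step(state.G, inlet_value=kin.G_0_nM)
    else:
        g_star = state.G.copy()
    denom = 1.0 + dt * k_cat * e2 / (k_m + g_star)
    g_new = np.where(fluid, g_star / denom, 0.0)
    production = (g_star - g_new) / dt  # nM/s, exact mass moved G -> c10

    # monomer transport with production source
    if op is not None:
        c10 = op.step(state.c10, inlet_value=0.0, source=production)
    else:
        c10 = state.c10 + dt * production
    c10 = np.where(fluid, c10, 0.0)

    rt = state.Rt.copy()
    tt = state.Tt.copy()
    b = state.B.copy()
    y = state.Y.copy()
    gel = state.I.copy()
    t_gel = state.t_gel.copy()

    remaining = dt
    t_local = t
    while remaining > 1.0e-14:
        active = fluid & ~gel
        if not np.any(active):
            break
        r, sink, d_rt, d_b, d_y = _reaction_rates(c10, rt, y, k_l, k_b)
        # stability scale: fastest relative change among c10 sink, R decay, Y growth
        lam = np.zeros_like(c10)
        lam[active] = np.maximum.reduce(
            [
                sink[active],
                k_l * r[active] + 0.5 * k_b * r[active] ** 2,
                d_y[active] / (y[active] + 0.02 * kin.Y_max + 1.0),
            ]
        )
        lam_max = lam[active].max() if np.any(active) else 0.0
        sub = remaining if lam_max <= 0 else min(remaining, safety / lam_max)

        y_old = y.copy()
        # semi-implicit (exactly mass-conserving) c10 -> oligomer flux
        moved = np.where(active, c10 * (1.0 - 1.0 / (1.0 + sub * sink)), 0.0)
        c10 = c10 - moved
        tt = tt + moved
        rt = np.where(active, rt + 2.0 * moved + sub * (-k_l * r**2 - 0.5 * k_b * r**3), rt)
        np.clip(rt, 0.0, None, out=rt)
        b = np.where(active, b + sub * d_b, b)
        y = np.where(active, y + sub * d_y, y)

        crossed = active & (y >= kin.Y_max)
        if np.any(crossed):
            frac = np.clip(
                (kin.Y_max - y_old[crossed]) / np.maximum(y[crossed] - y_old[crossed], 1e-300),
                0.0,
                1.0,
            )
            t_gel[crossed] = t_local + frac * sub
            gel[crossed] = True
        t_local += sub
        remaining -= sub

    return FibrinState(G=g_new, c10=c10, Rt=rt, Tt=tt, B=b, Y=y, I=gel, t_gel=t_gel)
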