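"""Surface-bound coagulation chemistry on the SE and platelet interfaces.

The subendothelium (SE) carries the initiating enzyme E0 (a TF:fVIIa
analog), which binds fluid-phase substrate S1 into the complex C0b and
releases enzyme E1 into the fluid.  Each platelet interface element
carries two classes of binding sites: P1 hosts S1/E1 and P2 hosts
S2/E2.  Bound S2b:E1b forms the complex C1b (prothrombinase analog)
which converts its S2b into thrombin analog E2b; bound S1b:E2b forms
C2b (tenase analog) which converts its S1b into E1b — the model's
positive feedback loop.  A complex occupies one P1 and one P2 site.

All surface densities are in fmol/cm^2, all fluid concentrations passed
in here are in molar, and exchange with the fluid is expressed as
boundary fluxes in fmol cm^-2 s^-1, positive INTO the fluid.  Surface
ODEs advance by forward Euler at the caller's (sub-)step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from clotsim2d.params import KineticParams

__all__ = [
    "SurfaceState",
    "available_sites",
    "se_reaction_step",
    "platelet_reaction_step",
]

_NEG_TOL = 1.0e-9


@dataclass
class SurfaceState:
    """Surface densities on SE elements and platelet interface elements.

    c0b is per SE element; the six platelet arrays are per interface
    element.  All in fmol/cm^2.
    """

    c0b: np.ndarray
    s1b: np.ndarray
    e1b: np.ndarray
    s2b: np.ndarray
    e2b: np.ndarray
    c1b: np.ndarray
    c2b: np.ndarray

    @classmethod
    def zeros(cls, n_se: int, n_elements: int) -> "SurfaceState":
        return cls(
            c0b=np.zeros(n_se),
            s1b=np.zeros(n_elements),
            e1b=np.zeros(n_elements),
            s2b=np.zeros(n_elements),
            e2b=np.zeros(n_elements),
            c1b=np.zeros(n_elements),
            c2b=np.zeros(n_elements),
        )

    def p1_occupancy(self) -> np.ndarray:
        """Occupied P1 site density per element, fmol/cm^2."""
        return self.s1b + self.e1b + self.c1b + self.c2b

    def p2_occupancy(self) -> np.ndarray:
        return self.s2b + self.e2b + self.c1b + self.c2b

    def check(self, n1_t: float, n2_t: float, e0: float, tol: float = 1.0e-6) -> None:
        """Assert positivity and site-occupancy bounds."""
        for name in ("c0b", "s1b", "e1b", "s2b", "e2b", "c1b", "c2b"):
            v = getattr(self, name)
            if v.size and v.min() < -tol:
                raise RuntimeError(f"negative surface density in {name}: {v.min():.3e}")
        if self.s1b.size:
            if self.p1_occupancy().max() > n1_t * (1 + tol) + tol:
                raise RuntimeError("P1 occupancy exceeds available sites")
            if self.p2_occupancy().max() > n2_t * (1 + tol) + tol:
                raise RuntimeError("P2 occupancy exceeds available sites")
        if self.c0b.size and self.c0b.max() > e0 * (1 + tol) + tol:
            raise RuntimeError("C0b exceeds total SE enzyme density")


def available_sites(t: float, n_max: float, k_act: float) -> float:
    """Available binding-site density N(t) = Nmax (1 - exp(-k_act t)).

    Platelet activation gradually exposes binding sites; with
    k_act = 0.05 1/s about 95% are available by t = 60 s.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be nonnegative")
    return n_max * -np.expm1(-k_act * np.asarray(t))


def se_reaction_step(
    c0b: np.ndarray,
    s1_M: np.ndarray,
    kin: KineticParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One forward-Euler step of the SE complex C0b.

    dC0b/dt = kC0+ S1 (E0 - C0b) - (kC0- + kC0cat) C0b

    Returns (updated C0b, S1 boundary flux, E1 boundary flux), fluxes in
    fmol cm^-2 s^-1 positive into the fluid and evaluated at the
    pre-update state (consistent with the explicit update).
    """
    bind = kin.kC0_on * s1_M * (kin.E0 - c0b)
    s1_flux = -bind + kin.kC0_off * c0b
    e1_flux = kin.kC0_cat * c0b
    c0b_new = c0b + dt * (bind - (kin.kC0_off + kin.kC0_cat) * c0b)
    if c0b_new.size and c0b_new.min() < -_NEG_TOL:
        warnings.warn("negative C0b clipped; reduce dt")
    np.clip(c0b_new, 0.0, None, out=c0b_new)
    return c0b_new, s1_flux, e1_flux


def platelet_reaction_step(
    state: SurfaceState,
    fluid_M: dict[str, np.ndarray],
    n1_t: float,
    n2_t: float,
    kin: KineticParams,
    dt: float,
) -> tuple[SurfaceState, dict[str, np.ndarray]]:
    """One forward-Euler step of the six platelet-bound densities.

    ``fluid_M`` maps 'S1', 'E1', 'S2', 'E2' to the fluid concentrations
    (molar) in the cell adjacent to each interface element.  Returns the
    updated state and the boundary fluxes (fmol cm^-2 s^-1, positive
    into the fluid) for the four exchanged species.

    Stoichiometry: C1b = S2b:E1b dissociates back to its parts or
    catalyzes S2b -> E2b, releasing E1b; C2b = S1b:E2b catalyzes
    S1b -> E1b, releasing E2b.  Each complex occupies one P1 and one P2
    site.
    """
    s1b, e1b = state.s1b, state.e1b
    s2b, e2b = state.s2b, state.e2b
    c1b, c2b = state.c1b, state.c2b

    free1 = n1_t - (s1b + e1b + c1b + c2b)
    free2 = n2_t - (s2b + e2b + c1b + c2b)
    np.clip(free1, 0.0, None, out=free1)
    np.clip(free2, 0.0, None, out=free2)

    j_s1 = kin.kS1_on * free1 * fluid_M["S1"] - kin.kS1_off * s1b
    j_e1 = kin.kE1_on * free1 * fluid_M["E1"] - kin.kE1_off * e1b
    j_s2 = kin.kS2_on * free2 * fluid_M["S2"] - kin.kS2_off * s2b
    j_e2 = kin.kE2_on * free2 * fluid_M["E2"] - kin.kE2_off * e2b

    f1 = kin.kC1_on_s * s2b * e1b
    r1 = kin.kC1_off * c1b
    cat1 = kin.kC1_cat * c1b
    f2 = kin.kC2_on_s * s1b * e2b
    r2 = kin.kC2_off * c2b
    cat2 = kin.kC2_cat * c2b

    new = SurfaceState(
        c0b=state.c0b,
        s1b=s1b + dt * (j_s1 - f2 + r2),
        e1b=e1b + dt * (j_e1 - f1 + r1 + cat1 + cat2),
        s2b=s2b + dt * (j_s2 - f1 + r1),
        e2b=e2b + dt * (j_e2 - f2 + r2 + cat1 + cat2),
        c1b=c1b + dt * (f1 - r1 - cat1),
        c2b=c2b + dt * (f2 - r2 - cat2),
    )
    for name in ("s1b", "e1b", "s2b", "e2b", "c1b", "c2b"):
        v = getattr(new, name)
        if v.size and v.min() < -1.0e-6 * max(n1_t, n2_t, 1.0):
            raise RuntimeError(
                f"surface ODE instability: {name} went negative "
                f"({v.min():.3e} fmol/cm^2); reduce the time step"
            )
        np.clip(v, 0.0, None, out=v)

    fluxes = {"S1": -j_s1, "E1": -j_e1, "S2": -j_s2, "E2": -j_e2}
    return new, fluxes
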