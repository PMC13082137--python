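"""Central parameter registry with unit bookkeeping.

All model constants live here with their publication units.  The rest of
the package works in a single internal base — lengths in micrometres,
time in seconds, fluid-phase concentrations in nanomolar, surface
densities in fmol/cm^2 — and every rate constant is converted exactly
once, at load time, by :class:`UnitSystem`.

Two derived quantities are computed rather than tabulated:

* the surface equivalents of volumetric (apparent) rate constants for
  reactions between pairs of platelet-bound species, obtained by
  requiring that the volumetric reaction rate in a representative volume
  equal the total rate on the platelet surfaces it contains
  (:func:`volumetric_to_surface_rate`);
* platelet receptor surface densities from receptor copy numbers,
  treating the platelet as a sphere (:func:`receptor_density`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "AVOGADRO",
    "FluidParams",
    "KineticParams",
    "UnitSystem",
    "default_parameters",
    "receptor_density",
    "volumetric_to_surface_rate",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: Surface-to-volume ratio of the representative platelet-packed volume
#: used to map volumetric rate constants onto surface rate constants,
#: back-solved so that a single factor reproduces both published
#: (volumetric, surface) rate pairs.  Units: 1/cm.
DEFAULT_SURFACE_TO_VOLUME = 1.05e4


class UnitSystem:
    """Conversions between publication units and the internal base.

    Internal base: length um, time s, fluid concentration nM, surface
    density fmol/cm^2.  All helpers are exact scale factors, so
    round-trips are identity to floating-point rounding.
    """

    # fluid concentration
    NM_PER_M = 1.0e9
    # 1 M = 1 mol/L = 1e15 fmol / 1e15 um^3 = 1 fmol/um^3
    FMOL_PER_UM3_PER_M = 1.0

    # lengths / areas
    UM_PER_CM = 1.0e4
    UM2_PER_CM2 = 1.0e8

    @staticmethod
    def M_to_nM(c: float) -> float:
        return c * UnitSystem.NM_PER_M

    @staticmethod
    def nM_to_M(c: float) -> float:
        return c / UnitSystem.NM_PER_M

    @staticmethod
    def M_to_fmol_per_um3(c: float) -> float:
        return c * UnitSystem.FMOL_PER_UM3_PER_M

    @staticmethod
    def fmol_per_um3_to_M(c: float) -> float:
        return c / UnitSystem.FMOL_PER_UM3_PER_M

    @staticmethod
    def nM_to_fmol_per_um3(c: float) -> float:
        return c / UnitSystem.NM_PER_M

    @staticmethod
    def fmol_per_um3_to_nM(c: float) -> float:
        return c * UnitSystem.NM_PER_M

    @staticmethod
    def fmol_per_cm2_to_fmol_per_um2(s: float) -> float:
        return s / UnitSystem.UM2_PER_CM2

    @staticmethod
    def fmol_per_um2_to_fmol_per_cm2(s: float) -> float:
        return s * UnitSystem.UM2_PER_CM2

    @staticmethod
    def cm2_per_s_to_um2_per_s(d: float) -> float:
        return d * UnitSystem.UM2_PER_CM2


@dataclass
class FluidParams:
    """Fluid and transport constants.

    density:      g/cm^3
    viscosity:    mPa*s (equivalently cP)
    diffusivity:  cm^2/s, shared by every transported species
    shear_rate:   wall shear rate imposed by the inlet profile, 1/s
    """

    density: float = 1.025
    viscosity: float = 1.2
    diffusivity: float = 5.0e-7
    shear_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0 or self.diffusivity <= 0:
            raise ValueError("density, viscosity and diffusivity must be positive")
        if self.shear_rate < 0:
            raise ValueError("shear_rate must be nonnegative")

    @property
    def diffusivity_um2_s(self) -> float:
        """Diffusivity in the internal base, um^2/s."""
        return UnitSystem.cm2_per_s_to_um2_per_s(self.diffusivity)


@dataclass
class KineticParams:
    """Kinetic constants and initial/inlet concentrations.

    Platelet activation and binding-site pools
    ------------------------------------------
    k_act    platelet activation rate, 1/s (binding-site availability ramp)
    N1_max   total P1 binding-site density on an activated platelet, fmol/cm^2
    N2_max   total P2 binding-site density, fmol/cm^2

    Subendothelium (SE) reaction, S1 + E0 <-> C0b -> E1
    ---------------------------------------------------
    kC0_on   M^-1 s^-1 (volumetric; acts on the SE surface density E0)
    kC0_off  1/s
    kC0_cat  1/s

    Platelet-surface complexes
    --------------------------
    C1b = S2b:E1b (prothrombinase analog), C2b = S1b:E2b (tenase analog).
    kC1_on_s / kC2_on_s are surface rates in cm^2 fmol^-1 s^-1 derived
    from the volumetric kC1_on_v / kC2_on_v; off and cat rates in 1/s.

    Fluid <-> platelet binding
    --------------------------
    kX_on (M^-1 s^-1) and kX_off (1/s) for X in S1, E1, S2, E2.

    Fibrin polymerization
    ---------------------
    k_l    linking rate, M^-1 s^-1
    k_b    branching rate, M^-2 s^-1
    k_cat  fibrinogen -> fibrin monomer turnover by thrombin, 1/s
    K_m    Michaelis constant of that conversion, M
    Y_max  gelation threshold on the gel-progress variable Y, nM

    Inhibition and concentrations
    -----------------------------
    k_AT   first-order thrombin inhibition by antithrombin, 1/s
    E0     SE enzyme surface density, fmol/cm^2
    S1_0, S2_0, G_0   plasma (inlet and initial) concentrations, M
    """

    k_act: float = 0.05
    N1_max: float = 23.5
    N2_max: float = 17.4

    kC0_on: float = 8.95e6
    kC0_off: float = 1.0
    kC0_cat: float = 1.15

    kC1_on_v: float = 1.03e8
    kC1_off: float = 1.0
    kC1_cat: float = 30.0
    kC2_on_v: float = 1.73e7
    kC2_off: float = 1.0
    kC2_cat: float = 0.23

    surface_to_volume: float = DEFAULT_SURFACE_TO_VOLUME

    # fluid <-> surface binding; order-of-magnitude defaults, overridable
    kS1_on: float = 1.0e7
    kS1_off: float = 1.0
    kE1_on: float = 1.0e7
    kE1_off: float = 1.0
    kS2_on: float = 1.0e7
    kS2_off: float = 1.0
    kE2_on: float = 1.0e7
    kE2_off: float = 1.0

    k_AT: float = 0.0336

    k_l: float = 8.2e5
    k_b: float = 1.5e9
    k_cat: float = 84.0
    K_m: float = 7.2e-6
    Y_max: float = 5000.0

    E0: float = 0.02
    S1_0: float = 0.17e-6
    S2_0: float = 1.4e-6
    G_0: float = 5.88e-6

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v}")

    @property
    def kC1_on_s(self) -> float:
        """Surface C1b association rate, cm^2 fmol^-1 s^-1."""
        return volumetric_to_surface_rate(self.kC1_on_v, self.surface_to_volume)

    @property
    def kC2_on_s(self) -> float:
        """Surface C2b association rate, cm^2 fmol^-1 s^-1."""
        return volumetric_to_surface_rate(self.kC2_on_v, self.surface_to_volume)

    # -- internal-base views ------------------------------------------------

    @property
    def K_m_nM(self) -> float:
        return UnitSystem.M_to_nM(self.K_m)

    @property
    def k_l_nM(self) -> float:
        """Linking rate in nM^-1 s^-1."""
        return self.k_l / UnitSystem.NM_PER_M

    @property
    def k_b_nM(self) -> float:
        """Branching rate in nM^-2 s^-1."""
        return self.k_b / UnitSystem.NM_PER_M**2

    @property
    def S1_0_nM(self) -> float:
        return UnitSystem.M_to_nM(self.S1_0)

    @property
    def S2_0_nM(self) -> float:
        return UnitSystem.M_to_nM(self.S2_0)

    @property
    def G_0_nM(self) -> float:
        return UnitSystem.M_to_nM(self.G_0)


@dataclass
class Parameters:
    """Bundle of fluid and kinetic parameters for one scenario."""

    fluid: FluidParams = field(default_factory=FluidParams)
    kinetics: KineticParams = field(default_factory=KineticParams)


def default_parameters() -> Parameters:
    """Return the stock parameter set (publication defaults)."""
    return Parameters()


def volumetric_to_surface_rate(
    k_v: float, surface_to_volume: float = DEFAULT_SURFACE_TO_VOLUME
) -> float:
    """Convert an apparent volumetric rate constant to a surface one.

    A second-order reaction between two platelet-bound species measured
    as if the reactants were dissolved in the bulk carries an apparent
    rate ``k_v`` in M^-1 s^-1.  Requiring the total volumetric rate in a
    representative volume to match the total rate of surface reactions
    on the platelet area it contains gives

        k_s = k_v * 1e-12 * (S/V)

    with ``S/V`` the platelet surface-to-volume ratio in 1/cm and the
    factor 1e-12 converting L/mol into cm^3/fmol.  Result in
    cm^2 fmol^-1 s^-1.
    """
    if k_v < 0 or surface_to_volume < 0:
        raise ValueError("rate constant and surface-to-volume must be nonnegative")
    return k_v * 1.0e-12 * surface_to_volume


def receptor_density(copies_per_platelet: float, platelet_diameter: float) -> float:
    """Receptor surface density in fmol/cm^2 from a copy number.

    The platelet surface is taken as a sphere of the given diameter (um).
    """
    if copies_per_platelet < 0:
        raise ValueError("copies_per_platelet must be nonnegative")
    if platelet_diameter <= 0:
        raise ValueError("platelet_diameter must be positive")
    area_um2 = 4.0 * math.pi * (platelet_diameter / 2.0) ** 2
    area_cm2 = area_um2 / UnitSystem.UM2_PER_CM2
    fmol = copies_per_platelet / AVOGADRO * 1.0e15
    return fmol / area_cm2
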