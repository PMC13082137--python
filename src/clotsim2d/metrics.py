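"""Observables: intraplug totals, point probes, rate fields, gel stats."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from clotsim2d.fibrin import monomer_production_rate
from clotsim2d.geometry import DomainMask, Grid2D
from clotsim2d.params import KineticParams
from clotsim2d.transport import TransportOperator, UNIT_DEPTH

__all__ = ["ProbeSeries", "RateFields", "intraplug_totals", "rate_fields", "probes"]


@dataclass
class ProbeSeries:
    """Time series of field values at a fixed probe location."""

    label: str
    position: tuple[float, float]  # um
    times: list = field(default_factory=list)
    values: dict = field(default_factory=dict)  # field name -> list
    gel_time: float = float("nan")

    def record(self, t: float, sampled: dict[str, float]) -> None:
        self.times.append(t)
        for k, v in sampled.items():
            self.values.setdefault(k, []).append(v)


@dataclass
class RateFields:
    """Fibrin supply diagnostics, nM/s, cell-centred.

    total_supply is computed as production + monomer transport, so the
    supply identity holds exactly by construction.
    """

    fibrinogen_transport: np.ndarray
    monomer_transport: np.ndarray
    monomer_production: np.ndarray
    total_supply: np.ndarray


def intraplug_totals(
    fields: dict[str, np.ndarray],
    region: np.ndarray,
    h: float,
    depth: float = UNIT_DEPTH,
) -> dict[str, float]:
    """Integrals of concentration over the intraplug fluid region.

    Returns, per species, sum(c * h^2 * depth) in nM um^3.
    """
    cell = h * h * depth
    return {k: float(v[region].sum() * cell) for k, v in fields.items()}


def rate_fields(
    g: np.ndarray,
    c10: np.ndarray,
    e2: np.ndarray,
    op: TransportOperator,
    kin: KineticParams,
) -> RateFields:
    """Transport, production and total supply rates of fibrin monomer.

    Transport rates -u.grad(c) + D lap(c) are evaluated with the same
    upwind/five-point stencils the solver uses, so they are consistent
    with the simulated dynamics.
    """
    gt = op.transport_rate(g, inlet_value=kin.G_0_nM)
    ct = op.transport_rate(c10, inlet_value=0.0)
    prod = monomer_production_rate(e2, g, kin.k_cat, kin.K_m_nM)
    prod = np.where(op.mask.fluid, prod, 0.0)
    return RateFields(
        fibrinogen_transport=gt,
        monomer_transport=ct,
        monomer_production=prod,
        total_supply=prod + ct,
    )


def probes(
    fields: dict[str, np.ndarray],
    positions: dict[str, tuple[float, float]],
    mask: DomainMask,
    t_gel: np.ndarray | None = None,
) -> dict[str, ProbeSeries]:
    """Sample fields at named probe positions (nearest fluid cell).

    Raises if a probe position falls inside a platelet.
    """
    out: dict[str, ProbeSeries] = {}
    for label, (x, y) in positions.items():
        i, j = mask.grid.locate(x, y)
        if mask.solid[i, j]:
            raise ValueError(f"probe {label!r} at ({x}, {y}) um lies inside a platelet")
        series = ProbeSeries(label=label, position=(x, y))
        series.record(0.0, {k: float(v[i, j]) for k, v in fields.items()})
        if t_gel is not None:
            series.gel_time = float(t_gel[i, j])
        out[label] = series
    return out


def sample_at(mask: DomainMask, field2d: np.ndarray, x: float, y: float) -> float:
    """Nearest-cell sample of a field at a point."""
    i, j = mask.grid.locate(x, y)
    return float(field2d[i, j])


def default_probe_positions(cfg) -> dict[str, tuple[float, float]]:
    """Three probes on the plug's vertical midline at 25/50/85% height."""
    return {
        "low": (cfg.center_x, 0.25 * cfg.height),
        "middle": (cfg.center_x, 0.50 * cfg.height),
        "high": (cfg.center_x, 0.85 * cfg.height),
    }
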