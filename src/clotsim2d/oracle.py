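"""Brute-force oligomer master equations for validating the moment system.

Tracks the full (truncated) table of oligomer concentrations c_mb for
species C_mb with b branches and m + 2b monomers; a C_mb oligomer
carries b + 2 free reaction sites.  Linking joins two oligomers at rate
k_l per pair of free sites; branching joins three at rate k_b per
ordered site triple with a 1/6 symmetry factor, so that the well-mixed
limits dR/dt = -k_l R^2 - (k_b/2) R^3 and dB/dt = (k_b/6) R^3 are
recovered exactly.  This module is deliberately independent of the
closed moment system in :mod:`clotsim2d.fibrin`: moments here are
obtained by direct summation over the table.

Intended for batch (well-mixed) validation at small concentrations;
truncation overflow mass is tracked and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["OligomerTable", "moment_sums", "truncated_master_step"]


@dataclass
class OligomerTable:
    """Concentrations c[m, b] (nM) for m in [0..m_max], b in [0..b_max].

    Index m = 0 is unused padding (every oligomer has m >= 1).  The
    overflow accumulator records monomer mass lost past the truncation
    bounds.
    """

    c: np.ndarray
    overflow_monomers: float = 0.0

    @classmethod
    def empty(cls, m_max: int = 200, b_max: int = 30) -> "OligomerTable":
        return cls(c=np.zeros((m_max + 1, b_max + 1)))

    @classmethod
    def monomer_bolus(cls, c10: float, m_max: int = 200, b_max: int = 30) -> "OligomerTable":
        t = cls.empty(m_max, b_max)
        t.c[1, 0] = c10
        return t

    @property
    def m_max(self) -> int:
        return self.c.shape[0] - 1

    @property
    def b_max(self) -> int:
        return self.c.shape[1] - 1

    def site_weights(self) -> np.ndarray:
        """(b + 2) per table entry."""
        return np.arange(self.c.shape[1])[None, :] + 2.0

    def monomer_weights(self) -> np.ndarray:
        """(m + 2b) per table entry."""
        m = np.arange(self.c.shape[0])[:, None].astype(float)
        b = np.arange(self.c.shape[1])[None, :].astype(float)
        return m + 2.0 * b


def moment_sums(table: OligomerTable) -> dict[str, float]:
    """Moments by direct summation over the oligomer table.

    Returns R (free sites), theta (monomers in oligomers), B (branches),
    M02 = sum (b+2)(b+1) c_mb, and the mass-average cluster size
    A = (1/theta) sum (m+2b)^2 c_mb (NaN when theta = 0).
    """
    c = table.c
    b = np.arange(c.shape[1])[None, :].astype(float)
    w_sites = b + 2.0
    w_mono = table.monomer_weights()
    r = float((w_sites * c).sum())
    theta = float((w_mono * c).sum())
    bb = float((b * c).sum())
    m02 = float(((b + 2.0) * (b + 1.0) * c).sum())
    a = float((w_mono**2 * c).sum() / theta) if theta > 0 else float("nan")
    return {"R": r, "theta": theta, "B": bb, "M02": m02, "A": a, "Y": m02 - r}


def truncated_master_step(
    table: OligomerTable,
    monomer_source: float,
    k_l: float,
    k_b: float,
    dt: float,
    overflow_tol: float = 0.01,
) -> OligomerTable:
    """One explicit Euler step of the truncated master equations.

    ``monomer_source`` in nM/s feeds c[1, 0]; k_l in nM^-1 s^-1 and k_b
    in nM^-2 s^-1.  Raises if accumulated truncation overflow exceeds
    ``overflow_tol`` of the total monomer mass.
    """
    c = table.c
    w = table.site_weights()
    wc = w * c  # site-weighted concentrations
    r = wc.sum()

    # linking: gain[m,b] = (k_l/2) * sum_{m1+m2=m, b1+b2=b} (b1+2)c1 (b2+2)c2
    pair = fftconvolve(wc, wc)  # shape (2m_max+1, 2b_max+1), index = sums
    np.clip(pair, 0.0, None, out=pair)
    gain_link = 0.5 * k_l * pair
    loss_link = k_l * wc * r

    # branching: gain at (m, b) from triples with sum m+2, b-1
    triple = fftconvolve(pair, wc)
    np.clip(triple, 0.0, None, out=triple)
    gb = (k_b / 6.0) * triple
    loss_branch = 0.5 * k_b * wc * r * r

    dc = np.zeros_like(c)
    mm, bb = c.shape
    dc += gain_link[:mm, :bb]
    # branch product indices: product (m, b) <- triple entry (m+2, b-1)
    dc[:, 1:] += gb[2 : mm + 2, 0 : bb - 1]
    dc -= loss_link + loss_branch
    dc[1, 0] += monomer_source

    # overflow bookkeeping: gain mass falling outside the table
    mw_pair = _monomer_weight_grid(pair.shape)
    mw_trip = _monomer_weight_grid(triple.shape)
    keep_pair = np.zeros(pair.shape, dtype=bool)
    keep_pair[:mm, :bb] = True
    keep_trip = np.zeros(triple.shape, dtype=bool)
    keep_trip[2 : mm + 2, 0 : bb - 1] = True
    ovf = (
        0.5 * k_l * (pair * mw_pair)[~keep_pair].sum()
        + (k_b / 6.0) * (triple * mw_trip)[~keep_trip].sum()
    )

    new_c = c + dt * dc
    np.clip(new_c, 0.0, None, out=new_c)
    new = OligomerTable(c=new_c, overflow_monomers=table.overflow_monomers + dt * float(ovf))

    theta = moment_sums(new)["theta"]
    if theta > 0 and new.overflow_monomers > overflow_tol * (theta + new.overflow_monomers):
        raise RuntimeError(
            "master-equation truncation overflow exceeds tolerance; "
            "increase m_max/b_max"
        )
    return new


def _monomer_weight_grid(shape: tuple[int, int]) -> np.ndarray:
    m = np.arange(shape[0])[:, None].astype(float)
    b = np.arange(shape[1])[None, :].astype(float)
    return m + 2.0 * b


def integrate_batch(
    table: OligomerTable,
    source_fn,
    k_l: float,
    k_b: float,
    t_end: float,
    dt: float,
    record_every: int = 1,
) -> tuple[list[float], list[dict[str, float]]]:
    """Integrate a well-mixed batch, recording moment sums over time."""
    times = [0.0]
    records = [moment_sums(table)]
    n = int(round(t_end / dt))
    for step in range(n):
        t = step * dt
        table = truncated_master_step(table, source_fn(t), k_l, k_b, dt)
        if (step + 1) % record_every == 0:
            times.append((step + 1) * dt)
            records.append(moment_sums(table))
    return times, records
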