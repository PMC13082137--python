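"""Platelet plug geometry: packing, rasterization, microstructure metrics.

The platelet plug is a half-ellipse sitting on the bottom vessel wall,
filled with equal disks (platelets) on a triangular lattice whose
lattice constant is platelet diameter + interplatelet gap.  The packing
is fully deterministic.  Plugs are rasterized onto a uniform Cartesian
cell-centred grid; platelet surfaces become staircase interface
elements whose effective lengths are normal-projected so the total
reactive length of an isolated disk converges to its perimeter pi*d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid2D",
    "PlugConfig",
    "PlateletPlug",
    "DomainMask",
    "PlugMetrics",
    "pack_platelets",
    "rasterize",
    "plug_region_mask",
    "plug_metrics",
]

# cell labels
FLUID = 0
SOLID = 1


@dataclass(frozen=True)
class Grid2D:
    """Uniform Cartesian grid over the channel.

    Origin at the bottom-left inlet corner, x along the flow, y
    wall-normal.  Fields are cell-centred; cell (i, j) has its centre at
    ((i+0.5)h, (j+0.5)h).  Lengths in um.
    """

    length: float
    height: float
    h: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("cell size must be positive")
        if self.length <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be positive")

    @property
    def nx(self) -> int:
        return int(round(self.length / self.h))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.h))

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of shape (nx, ny)."""
        x = (np.arange(self.nx) + 0.5) * self.h
        y = (np.arange(self.ny) + 0.5) * self.h
        return np.meshgrid(x, y, indexing="ij")

    def locate(self, x: float, y: float) -> tuple[int, int]:
        """Cell index containing the point (x, y)."""
        i = min(max(int(x / self.h), 0), self.nx - 1)
        j = min(max(int(y / self.h), 0), self.ny - 1)
        return i, j


@dataclass(frozen=True)
class PlugConfig:
    """Geometric description of a platelet plug.

    gap:        uniform interplatelet (surface-to-surface) spacing, um
    half_width: half-ellipse semi-axis along the wall (a), um
    height:     half-ellipse height (b), um
    diameter:   platelet diameter, um
    clearance:  spacing between the lowest platelet row and the wall, um
    center_x:   x-position of the plug centre, um
    """

    gap: float = 0.5
    half_width: float = 27.0
    height: float = 17.0
    diameter: float = 2.46
    clearance: float = 0.5
    center_x: float = 108.0

    def __post_init__(self) -> None:
        if self.gap <= 0 or self.diameter <= 0:
            raise ValueError("gap and diameter must be positive")
        if self.half_width <= 0 or self.height <= 0:
            raise ValueError("ellipse dimensions must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def ellipse_area(self) -> float:
        """Area of the half-ellipse plug outline, um^2."""
        return math.pi * self.half_width * self.height / 2.0

    def inside_ellipse(self, x, y):
        """Whether points lie inside the half-ellipse (vectorized)."""
        return ((np.asarray(x) - self.center_x) / self.half_width) ** 2 + (
            np.asarray(y) / self.height
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class PlateletPlug:
    """Disk centres (um) with a common radius (um)."""

    centers: np.ndarray  # (n, 2)
    radius: float
    config: PlugConfig

    @property
    def n_platelets(self) -> int:
        return len(self.centers)

    def min_gap(self) -> float:
        """Minimum surface-to-surface distance between any two disks."""
        if self.n_platelets < 2:
            return math.inf
        c = self.centers
        d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        return float(np.sqrt(d2.min()) - 2.0 * self.radius)


@dataclass
class DomainMask:
    """Rasterized classification of the channel.

    labels:          (nx, ny) int array, FLUID or SOLID
    iface_cell:      (n_el, 2) fluid-cell index (i, j) of each platelet
                     interface element
    iface_platelet:  (n_el,) owning platelet id
    iface_length:    (n_el,) effective face length, um (normal-projected)
    se_cell:         (n_se, 2) fluid-cell index of each SE wall element
    se_length:       (n_se,) face length, um
    """

    grid: Grid2D
    labels: np.ndarray
    iface_cell: np.ndarray
    iface_platelet: np.ndarray
    iface_length: np.ndarray
    se_cell: np.ndarray
    se_length: np.ndarray

    @property
    def fluid(self) -> np.ndarray:
        return self.labels == FLUID

    @property
    def solid(self) -> np.ndarray:
        return self.labels == SOLID

    def platelet_interface_length(self, platelet_id: int) -> float:
        return float(self.iface_length[self.iface_platelet == platelet_id].sum())


@dataclass(frozen=True)
class PlugMetrics:
    """Microstructure summary of one plug configuration."""

    n_platelets: int
    area_occupied_pct: float
    free_space_pct: float
    free_space_um2: float
    gap: float


def pack_platelets(cfg: PlugConfig) -> PlateletPlug:
    """Deterministic triangular-lattice packing of disks in the half-ellipse.

    Rows run parallel to the wall with lattice constant d + g and row
    spacing (d+g)*sqrt(3)/2; alternate rows are offset by half a lattice
    constant.  The bottom row sits at y = clearance + d/2.  A disk is
    kept iff it lies entirely inside the half-ellipse, approximated by
    requiring its centre to fall within the ellipse shrunk by one
    radius on each semi-axis.
    """
    r = cfg.radius
    s = cfg.diameter + cfg.gap
    row_dy = s * math.sqrt(3.0) / 2.0
    a_in = cfg.half_width - r
    b_in = cfg.height - r
    if a_in <= 0 or b_in <= 0:
        warnings.warn("plug ellipse too small for a single platelet; empty plug")
        return PlateletPlug(np.empty((0, 2)), r, cfg)

    y0 = cfg.clearance + r
    centers: list[tuple[float, float]] = []
    k = 0
    while True:
        y = y0 + k * row_dy
        if y > b_in:
            break
        # half-width of the shrunk ellipse at this height
        w = a_in * math.sqrt(max(0.0, 1.0 - (y / b_in) ** 2))
        offset = 0.0 if k % 2 == 0 else s / 2.0
        if offset == 0.0:
            n_side = int(math.floor(w / s))
            xs = [cfg.center_x + m * s for m in range(-n_side, n_side + 1)]
        else:
            n_side = int(math.floor(w / s - 0.5)) + 1 if w >= s / 2.0 else 0
            xs = []
            for m in range(n_side):
                xs.append(cfg.center_x + (m + 0.5) * s)
                xs.append(cfg.center_x - (m + 0.5) * s)
        centers.extend((x, y) for x in xs)
        k += 1

    if not centers:
        warnings.warn("plug ellipse too small for a single platelet; empty plug")
        return PlateletPlug(np.empty((0, 2)), r, cfg)
    arr = np.array(sorted(centers, key=lambda c: (c[1], c[0])))
    return PlateletPlug(arr, r, cfg)


def rasterize(
    plug: PlateletPlug,
    grid: Grid2D,
    se_strip: tuple[float, float] | None = None,
) -> DomainMask:
    """Rasterize a plug onto the grid and enumerate surface elements.

    A cell is solid iff its centre lies inside any disk.  Interface
    elements are fluid/solid cell faces; each carries the id of the disk
    containing the solid cell centre and an effective length
    h * |n_disk . n_face| so a disk's total interface length converges
    to its perimeter.  SE elements are the bottom-wall faces of fluid
    cells with x in the se_strip interval.
    """
    if plug.n_platelets > 0:
        g = plug.config.gap
        if grid.h > g / 2.0:
            warnings.warn(
                f"grid spacing h={grid.h} um does not resolve the interplatelet "
                f"gap g={g} um with >= 2 cells"
            )

    nx, ny = grid.nx, grid.ny
    labels = np.full((nx, ny), FLUID, dtype=np.int8)
    owner = np.full((nx, ny), -1, dtype=np.int64)
    X, Y = grid.cell_centers()
    r2 = plug.radius**2
    for pid, (cx, cy) in enumerate(plug.centers):
        i0 = max(int((cx - plug.radius) / grid.h) - 1, 0)
        i1 = min(int((cx + plug.radius) / grid.h) + 2, nx)
        j0 = max(int((cy - plug.radius) / grid.h) - 1, 0)
        j1 = min(int((cy + plug.radius) / grid.h) + 2, ny)
        sub = (X[i0:i1, j0:j1] - cx) ** 2 + (Y[i0:i1, j0:j1] - cy) ** 2 <= r2
        labels[i0:i1, j0:j1][sub] = SOLID
        owner[i0:i1, j0:j1][sub] = pid

    # enumerate fluid faces adjacent to solid cells
    cells: list[tuple[int, int]] = []
    pids: list[int] = []
    lengths: list[float] = []
    solid = labels == SOLID

    def _add(fi, fj, si, sj, face_normal):
        pid = owner[si, sj]
        cx, cy = plug.centers[pid]
        # face midpoint
        if face_normal == "x":
            mx = max(fi, si) * grid.h
            my = (fj + 0.5) * grid.h
            nvec = (1.0, 0.0)
        else:
            mx = (fi + 0.5) * grid.h
            my = max(fj, sj) * grid.h
            nvec = (0.0, 1.0)
        dx, dy = mx - cx, my - cy
        nrm = math.hypot(dx, dy)
        w = 1.0 if nrm == 0 else abs(dx * nvec[0] + dy * nvec[1]) / nrm
        cells.append((fi, fj))
        pids.append(pid)
        lengths.append(grid.h * w)

    sol_i, sol_j = np.nonzero(solid)
    for si, sj in zip(sol_i, sol_j):
        if si > 0 and not solid[si - 1, sj]:
            _add(si - 1, sj, si, sj, "x")
        if si < nx - 1 and not solid[si + 1, sj]:
            _add(si + 1, sj, si, sj, "x")
        if sj > 0 and not solid[si, sj - 1]:
            _add(si, sj - 1, si, sj, "y")
        if sj < ny - 1 and not solid[si, sj + 1]:
            _add(si, sj + 1, si, sj, "y")

    iface_cell = np.array(cells, dtype=np.int64).reshape(-1, 2)
    iface_platelet = np.array(pids, dtype=np.int64)
    iface_length = np.array(lengths, dtype=float)

    # SE strip on the bottom wall
    if se_strip is None:
        cx0 = plug.config.center_x if plug.n_platelets else grid.length / 2.0
        se_strip = (cx0 - 25.0, cx0 + 25.0)
    x0, x1 = se_strip
    xc = (np.arange(nx) + 0.5) * grid.h
    in_strip = (xc >= x0) & (xc <= x1) & ~solid[:, 0]
    se_i = np.nonzero(in_strip)[0]
    se_cell = np.stack([se_i, np.zeros_like(se_i)], axis=1)
    se_length = np.full(len(se_i), grid.h)

    return DomainMask(
        grid=grid,
        labels=labels,
        iface_cell=iface_cell,
        iface_platelet=iface_platelet,
        iface_length=iface_length,
        se_cell=se_cell,
        se_length=se_length,
    )


def plug_region_mask(plug: PlateletPlug, grid: Grid2D, mask: DomainMask | None = None) -> np.ndarray:
    """Boolean (nx, ny) array of intraplug fluid cells.

    Cells whose centres lie inside the half-ellipse outline and are not
    solid; the integration region for all intraplug totals.
    """
    X, Y = grid.cell_centers()
    inside = plug.config.inside_ellipse(X, Y)
    if mask is None:
        mask = rasterize(plug, grid)
    return inside & mask.fluid


def plug_metrics(plug: PlateletPlug, cfg: PlugConfig | None = None) -> PlugMetrics:
    """Analytic (non-rasterized) microstructure metrics of a plug."""
    cfg = cfg or plug.config
    disk_area = plug.n_platelets * math.pi * plug.radius**2
    total = cfg.ellipse_area
    occ = 100.0 * disk_area / total
    free = 100.0 - occ
    return PlugMetrics(
        n_platelets=plug.n_platelets,
        area_occupied_pct=occ,
        free_space_pct=free,
        free_space_um2=total - disk_area,
        gap=cfg.gap,
    )


#: Stock plug configurations (interplatelet gap in um).
STOCK_GAPS = {"dense": 0.1, "medium": 0.5, "loose": 1.0}


def stock_plug(name: str, center_x: float = 108.0) -> PlugConfig:
    """One of the three published plug configurations."""
    if name not in STOCK_GAPS:
        raise ValueError(f"unknown plug configuration {name!r}; options: {sorted(STOCK_GAPS)}")
    return PlugConfig(gap=STOCK_GAPS[name], center_x=center_x)
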