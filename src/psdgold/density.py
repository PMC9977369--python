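"""Gridded 2D receptor density maps.

A Cartesian grid (default 25 x 25 nm) is laid over each pose-normalized PSD
with a grid node pinned at the origin (the PSD center of gravity). Grains are
counted per cell; the region area covered by each cell is computed by exact
polygon clipping. Population maps sum counts and coverage over PSDs and report
the quotient counts/coverage (grains per nm^2) wherever coverage is positive,
which normalizes the average for the variable size and shape of PSDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import box

from .geometry import classify_particles, region_area, NM2_PER_UM2
from .model import PSDRecord

DEFAULT_CELL_SIZE = 25.0  # nm


@dataclass
class DensityMap:
    """Grain counts and region coverage on a Cartesian grid.

    ``counts[iy, ix]`` and ``coverage[iy, ix]`` refer to the half-open cell
    [ (ix0+ix)*s, (ix0+ix+1)*s ) x [ (iy0+iy)*s, (iy0+iy+1)*s ) in nm, where
    ``s`` is the cell size and (ix0, iy0) the integer grid offset. Grid nodes
    therefore sit at integer multiples of ``s`` for every map, so maps from
    different PSDs align cell-for-cell.
    """

    cell_size: float
    ix0: int
    iy0: int
    counts: np.ndarray
    coverage: np.ndarray  # nm^2 of region per cell

    @property
    def origin(self) -> tuple[float, float]:
        """Lower-left corner of cell (0, 0), in nm."""
        return (self.ix0 * self.cell_size, self.iy0 * self.cell_size)

    @property
    def normalized(self) -> np.ndarray:
        """counts/coverage (grains per nm^2) where coverage > 0, else NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.coverage > 0, self.counts / self.coverage, np.nan)
        return out

    def x_edges(self) -> np.ndarray:
        return (self.ix0 + np.arange(self.counts.shape[1] + 1)) * self.cell_size

    def y_edges(self) -> np.ndarray:
        return (self.iy0 + np.arange(self.counts.shape[0] + 1)) * self.cell_size


def _cell_coverage(poly, cell_size: float, ix0: int, iy0: int, nx: int, ny: int) -> np.ndarray:
    """Exact region area within each grid cell, via polygon clipping."""
    shapely.prepare(poly)
    s = cell_size
    cov = np.zeros((ny, nx))
    for iy in range(ny):
        y0 = (iy0 + iy) * s
        for ix in range(nx):
            x0 = (ix0 + ix) * s
            cell = box(x0, y0, x0 + s, y0 + s)
            if not poly.intersects(cell):
                continue
            if poly.contains_properly(cell):
                cov[iy, ix] = s * s
            else:
                cov[iy, ix] = poly.intersection(cell).area
    return cov


def grid_bin(rec: PSDRecord, cell_size: float = DEFAULT_CELL_SIZE) -> DensityMap:
    """Bin the synaptic grains of one (pose-normalized) PSD onto the grid.

    Cells are half-open, [x0, x0+s) x [y0, y0+s): a grain exactly on a shared
    edge goes to the cell with the larger coordinates. The grid extends to
    cover the region's bounding box; the sum of counts equals the synaptic
    grain count and the sum of coverage equals the region area.
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size}")
    poly = rec.region.to_polygon()
    minx, miny, maxx, maxy = poly.bounds
    s = float(cell_size)
    ix0 = int(np.floor(minx / s))
    iy0 = int(np.floor(miny / s))
    nx = int(np.floor(maxx / s)) - ix0 + 1
    ny = int(np.floor(maxy / s)) - iy0 + 1

    coverage = _cell_coverage(poly, s, ix0, iy0, nx, ny)
    counts = np.zeros((ny, nx))
    synaptic, _ = classify_particles(rec)
    for p in synaptic:
        ix = int(np.floor(p.x / s)) - ix0
        iy = int(np.floor(p.y / s)) - iy0
        # boundary grains may floor into a cell just outside the coverage
        # extent; clamp to the grid, the cell is still the nearest one
        ix = min(max(ix, 0), nx - 1)
        iy = min(max(iy, 0), ny - 1)
        counts[iy, ix] += 1
    return DensityMap(cell_size=s, ix0=ix0, iy0=iy0, counts=counts, coverage=coverage)


def average_maps(maps: list[DensityMap]) -> DensityMap:
    """Population map: summed counts and coverage over aligned per-PSD maps.

    The normalized map is the quotient of the sums, i.e. the area-weighted
    mean density per cell in grains/nm^2.
    """
    if not maps:
        raise ValueError("average_maps needs at least one map")
    s = maps[0].cell_size
    for m in maps:
        if m.cell_size != s:
            raise ValueError(f"mismatched cell_size: {m.cell_size} != {s}")
    ix0 = min(m.ix0 for m in maps)
    iy0 = min(m.iy0 for m in maps)
    ix1 = max(m.ix0 + m.counts.shape[1] for m in maps)
    iy1 = max(m.iy0 + m.counts.shape[0] for m in maps)
    counts = np.zeros((iy1 - iy0, ix1 - ix0))
    coverage = np.zeros_like(counts)
    for m in maps:
        ys = slice(m.iy0 - iy0, m.iy0 - iy0 + m.counts.shape[0])
        xs = slice(m.ix0 - ix0, m.ix0 - ix0 + m.counts.shape[1])
        counts[ys, xs] += m.counts
        coverage[ys, xs] += m.coverage
    return DensityMap(cell_size=s, ix0=ix0, iy0=iy0, counts=counts, coverage=coverage)


def export_map_csv(m: DensityMap, prefix) -> list:
    """Write counts/coverage/normalized matrices as CSV with a 2-line header."""
    from pathlib import Path

    paths = []
    header = (
        f"# cell_size_nm={m.cell_size}\n"
        f"# origin_nm=({m.origin[0]},{m.origin[1]})\n"
    )
    for name, arr in [("counts", m.counts), ("coverage", m.coverage),
                      ("normalized", m.normalized)]:
        path = Path(f"{prefix}_{name}.csv")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, arr, delimiter=",")
        paths.append(path)
    return paths


def render_map(m: DensityMap, path, cmap: str = "inferno"):
    """Render the normalized density map as a heat-map image (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(m.x_edges(), m.y_edges(), m.normalized, cmap=cmap)
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    fig.colorbar(im, ax=ax, label="grains / nm$^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
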