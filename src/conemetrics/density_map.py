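"""Adaptive-window Voronoi density matrices.

At each sampled grid point an axis-aligned square window grows (in whole-pixel
side increments) until it contains at least ``k`` cones whose Voronoi domains
are *fully* inside the window (every polygon vertex strictly interior).  The
local density is then

    density = (number of fully contained cells) / (sum of their Voronoi areas)

i.e. the reciprocal mean bounded-cell area — the standard bounded-Voronoi
density convention, exact on a hexagonal lattice (2/(√3·s²)).  Points whose
required window would cross the ROI boundary (optionally padded by an edge
margin, see below) are reported as missing, not edge-corrected.

Because a convex polygon lies inside an axis-aligned open box iff its
axis-aligned bounding box does, per-cone containment reduces to four numbers:
the Chebyshev-style distance from the query point to the farthest corner of
the cell's bounding box.  The smallest qualifying window falls out of an
order statistic of those distances, which is what makes dense grids feasible.

Edge margin: cones near the ROI boundary have distorted Voronoi cells (their
outside neighbors were never observed), so windows approaching the boundary
mix distorted cells into the count.  ``edge_margin_um`` invalidates grid
points whose window comes within that margin of the ROI edge; ~4 lattice
spacings (10 µm at foveal densities) keeps only boundary-clean cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from scipy.spatial import QhullError

from .coords_io import ConeField, ScaleInfo

__all__ = [
    "Tessellation",
    "DensityMatrix",
    "tessellate",
    "density_at",
    "compute_density_matrix",
    "crop_density_matrix",
    "to_angular",
]


@dataclass(frozen=True)
class Tessellation:
    """Voronoi tessellation of a cone field, one cell per cone.

    ``polygon(i)`` returns the cell's vertices in pixel units (None if the
    cell is unbounded); ``areas_um2`` its area (NaN if unbounded);
    ``bounded[i]`` is True iff the cell is finite and every vertex lies
    inside the ROI rectangle.  ``bbox`` stores per-cell
    (xmin, xmax, ymin, ymax) in pixels, ±inf for unbounded cells.
    """

    vertices: np.ndarray
    regions: list
    areas_um2: np.ndarray
    bounded: np.ndarray
    finite: np.ndarray
    bbox: np.ndarray

    def __len__(self) -> int:
        return len(self.regions)

    def polygon(self, i: int):
        if not self.finite[i]:
            return None
        return self.vertices[self.regions[i]]


def tessellate(field: ConeField) -> Tessellation:
    """Voronoi diagram of all cones; errors on degenerate (collinear) input."""
    pts = field.points
    if len(pts) < 4:
        raise ValueError(f"need >= 4 points for a Voronoi tessellation, got {len(pts)}")
    try:
        vor = Voronoi(pts)
    except QhullError as err:
        raise ValueError(f"degenerate point configuration: {err}") from None

    n = len(pts)
    side_px = field.roi_side_px
    regions = [vor.regions[pr] for pr in vor.point_region]
    finite = np.fromiter(
        (len(rg) > 0 and -1 not in rg for rg in regions), dtype=bool, count=n)
    areas = np.full(n, np.nan)
    bounded = np.zeros(n, dtype=bool)
    bbox = np.full((n, 4), np.inf)
    bbox[:, [0, 2]] = -np.inf  # xmin, ymin for unbounded cells

    fidx = np.flatnonzero(finite)
    if fidx.size:
        lens = np.fromiter((len(regions[i]) for i in fidx), dtype=np.intp,
                           count=fidx.size)
        flat = np.fromiter(
            (v for i in fidx for v in regions[i]), dtype=np.intp, count=int(lens.sum()))
        starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
        vx = vor.vertices[flat, 0]
        vy = vor.vertices[flat, 1]
        bbox[fidx, 0] = np.minimum.reduceat(vx, starts)
        bbox[fidx, 1] = np.maximum.reduceat(vx, starts)
        bbox[fidx, 2] = np.minimum.reduceat(vy, starts)
        bbox[fidx, 3] = np.maximum.reduceat(vy, starts)
        # shoelace per polygon: wrap the "next vertex" index within each region
        nxt = np.arange(1, flat.size + 1)
        ends = starts + lens - 1
        nxt[ends] = starts
        cross = vx * vy[nxt] - vy * vx[nxt]
        areas[fidx] = 0.5 * np.abs(np.add.reduceat(cross, starts)) * field.um_per_pixel**2
        bounded[fidx] = (
            (bbox[fidx, 0] >= 0) & (bbox[fidx, 1] <= side_px)
            & (bbox[fidx, 2] >= 0) & (bbox[fidx, 3] <= side_px)
        )

    return Tessellation(vertices=vor.vertices, regions=regions, areas_um2=areas,
                        bounded=bounded, finite=finite, bbox=bbox)


def _chebyshev_radii(bbox: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Half-side of the smallest point-centered square containing each cell.

    ``bbox`` is (M, 4) or an indexed gather of it; ``px, py`` broadcast
    against the leading axes.
    """
    return np.maximum.reduce([
        px - bbox[..., 0], bbox[..., 1] - px,
        py - bbox[..., 2], bbox[..., 3] - py,
    ])


def _accept_window(r: np.ndarray, k: int, inc_px: float):
    """Smallest quantized window for >= k strictly contained cells.

    Returns (half_side, count, contained_mask).  ``r`` is 1-D sorted-or-not
    per-cell radii; the window side is the smallest positive multiple of
    ``inc_px`` strictly greater than twice the k-th smallest radius.
    """
    if len(r) < k:
        return np.inf, 0, None
    hk = np.partition(r, k - 1)[k - 1]
    if not np.isfinite(hk):
        return np.inf, 0, None
    side = (np.floor(2.0 * hk / inc_px) + 1.0) * inc_px
    mask = r < side / 2.0
    return side / 2.0, int(mask.sum()), mask


def density_at(
    point_um,
    field: ConeField,
    tess: Tessellation | None = None,
    k: int = 150,
    increment_px: float = 1.0,
    edge_margin_um: float = 0.0,
):
    """Adaptive-window density at one point.

    Returns ``(density_per_mm2, window_side_um)``; ``(nan, nan)`` if the
    required window would leave the (margin-padded) ROI or cannot be formed.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if tess is None:
        tess = tessellate(field)
    p = np.asarray(point_um, dtype=float) / field.um_per_pixel
    side_px = field.roi_side_px
    if not (0 <= p[0] <= side_px and 0 <= p[1] <= side_px):
        raise ValueError(f"point {tuple(point_um)} outside the ROI")
    r = _chebyshev_radii(tess.bbox, p[0], p[1])
    half, count, mask = _accept_window(r, k, increment_px)
    margin_px = edge_margin_um / field.um_per_pixel
    fit = min(p[0], side_px - p[0], p[1], side_px - p[1]) - margin_px
    if not np.isfinite(half) or half > fit:
        return np.nan, np.nan
    area_um2 = float(np.nansum(tess.areas_um2[mask]))
    return count / area_um2 * 1e6, 2.0 * half * field.um_per_pixel


@dataclass(frozen=True)
class DensityMatrix:
    """Gridded density map over an ROI.

    ``values`` are cones/mm² (NaN where invalid), row index = y, column
    index = x.  ``grid_um`` is the physical spacing between samples
    (common scale × stride); ``origin_um`` the (x, y) position of cell
    (0, 0).  ``window_um`` records each cell's accepted window side.
    """

    values: np.ndarray
    valid: np.ndarray
    window_um: np.ndarray
    grid_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    edge_margin_um: float = 0.0
    units: str = "cones/mm^2"

    @property
    def shape(self):
        return self.values.shape

    def x_um(self) -> np.ndarray:
        return self.origin_um[0] + self.grid_um * np.arange(self.shape[1])

    def y_um(self) -> np.ndarray:
        return self.origin_um[1] + self.grid_um * np.arange(self.shape[0])

    def cell_to_um(self, row: int, col: int) -> tuple[float, float]:
        return (self.origin_um[0] + col * self.grid_um,
                self.origin_um[1] + row * self.grid_um)

    def um_to_cell(self, x_um: float, y_um: float) -> tuple[int, int]:
        return (int(round((y_um - self.origin_um[1]) / self.grid_um)),
                int(round((x_um - self.origin_um[0]) / self.grid_um)))


def compute_density_matrix(
    field: ConeField,
    k: int = 150,
    stride: int = 1,
    edge_margin_um: float = 0.0,
    increment_px: float = 1.0,
    chunk: int = 4096,
) -> DensityMatrix:
    """Evaluate the adaptive-window density on the pixel grid.

    ``stride`` samples every stride-th pixel in x and y.  A k-d tree
    preselects candidate cones per grid point; a conservative bound (any
    excluded cone's cell radius is at least its center distance / √2)
    certifies the result, with an exact full-field fallback for the rare
    points where the bound fails.
    """
    tess = tessellate(field)
    pts = field.points
    n = len(pts)
    side_px = field.roi_side_px
    margin_px = edge_margin_um / field.um_per_pixel

    gx = np.arange(0, int(np.floor(side_px)) + 1, stride, dtype=float)
    gy = gx.copy()
    nx, ny = len(gx), len(gy)

    if n < k:  # infeasible everywhere
        nanmat = np.full((ny, nx), np.nan)
        return DensityMatrix(
            values=nanmat, valid=np.zeros((ny, nx), dtype=bool),
            window_um=nanmat.copy(), grid_um=stride * field.um_per_pixel,
            origin_um=(0.0, 0.0), edge_margin_um=edge_margin_um,
        )

    m = min(n, max(3 * k, k + 64))
    tree = cKDTree(pts)

    values = np.full((ny, nx), np.nan)
    window = np.full((ny, nx), np.nan)

    grid_x, grid_y = np.meshgrid(gx, gy)
    flat = np.column_stack([grid_x.ravel(), grid_y.ravel()])
    areas = tess.areas_um2
    bbox = tess.bbox
    vflat = values.ravel()
    wflat = window.ravel()

    for start in range(0, len(flat), chunk):
        q = flat[start:start + chunk]
        if m < n:
            dist, idx = tree.query(q, k=m)
            cand_bbox = bbox[idx]
            r = _chebyshev_radii(cand_bbox, q[:, [0]], q[:, [1]])
            hk = np.partition(r, k - 1, axis=1)[:, k - 1]
            side = (np.floor(2.0 * hk / increment_px) + 1.0) * increment_px
            half = side / 2.0
            # certification: any cone beyond the m-th neighbor has
            # cell radius >= center distance / sqrt(2) > half
            guard = dist[:, -1] / np.sqrt(2.0)
            safe = np.isfinite(hk) & (half < guard)
        else:
            dist = None
            cand_bbox = np.broadcast_to(bbox, (len(q),) + bbox.shape)
            r = _chebyshev_radii(cand_bbox, q[:, [0]], q[:, [1]])
            hk = np.partition(r, k - 1, axis=1)[:, k - 1]
            side = (np.floor(2.0 * hk / increment_px) + 1.0) * increment_px
            half = side / 2.0
            safe = np.isfinite(hk)
            idx = None

        fit = np.minimum.reduce([q[:, 0], side_px - q[:, 0],
                                 q[:, 1], side_px - q[:, 1]]) - margin_px
        ok = safe & (half <= fit)
        if ok.any():
            contained = r[ok] < half[ok, None]
            counts = contained.sum(axis=1)
            if idx is not None:
                a = areas[idx[ok]]
            else:
                a = np.broadcast_to(areas, contained.shape)
            asum = np.where(contained, a, 0.0).sum(axis=1)
            rows = start + np.flatnonzero(ok)
            vflat[rows] = counts / asum * 1e6
            wflat[rows] = side[ok] * field.um_per_pixel

        # exact fallback for uncertified points that might still fit
        redo = np.flatnonzero(~safe & (fit > 0))
        for j in redo:
            p = q[j]
            rfull = _chebyshev_radii(bbox, p[0], p[1])
            h, count, cmask = _accept_window(rfull, k, increment_px)
            if np.isfinite(h) and h <= fit[j]:
                asum = float(np.nansum(areas[cmask]))
                vflat[start + j] = count / asum * 1e6
                wflat[start + j] = 2.0 * h * field.um_per_pixel

    values = vflat.reshape(ny, nx)
    window = wflat.reshape(ny, nx)
    return DensityMatrix(
        values=values,
        valid=np.isfinite(values),
        window_um=window,
        grid_um=stride * field.um_per_pixel,
        origin_um=(0.0, 0.0),
        edge_margin_um=edge_margin_um,
    )


def crop_density_matrix(
    dm: DensityMatrix,
    side_um: float,
    center_um: tuple[float, float] | None = None,
) -> DensityMatrix:
    """Square crop of a density matrix, revalidated against the crop bounds.

    Cells whose sampling window (plus the matrix's edge margin) does not fit
    inside the crop square are invalidated, so a crop behaves exactly like a
    matrix natively computed on the smaller ROI.
    """
    x = dm.x_um()
    y = dm.y_um()
    if center_um is None:
        center_um = ((x[0] + x[-1]) / 2.0, (y[0] + y[-1]) / 2.0)
    x0, x1 = center_um[0] - side_um / 2.0, center_um[0] + side_um / 2.0
    y0, y1 = center_um[1] - side_um / 2.0, center_um[1] + side_um / 2.0
    cx = np.flatnonzero((x >= x0 - 1e-9) & (x <= x1 + 1e-9))
    cy = np.flatnonzero((y >= y0 - 1e-9) & (y <= y1 + 1e-9))
    if cx.size == 0 or cy.size == 0:
        raise ValueError("crop does not intersect the matrix")
    vals = dm.values[np.ix_(cy, cx)].copy()
    win = dm.window_um[np.ix_(cy, cx)].copy()
    xs, ys = x[cx], y[cy]
    fit = np.minimum(
        np.minimum(xs[None, :] - x0, x1 - xs[None, :]),
        np.minimum(ys[:, None] - y0, y1 - ys[:, None]),
    ) - dm.edge_margin_um
    ok = np.isfinite(vals) & (win / 2.0 <= fit)
    vals[~ok] = np.nan
    win[~ok] = np.nan
    return DensityMatrix(
        values=vals, valid=ok, window_um=win, grid_um=dm.grid_um,
        origin_um=(float(xs[0]), float(ys[0])),
        edge_margin_um=dm.edge_margin_um, units=dm.units,
    )


def to_angular(dm, scale: ScaleInfo):
    """Convert linear density (cones/mm²) to angular density (cones/deg²).

    Works element-wise on a DensityMatrix or on a scalar/array.  The factor is
    (retinal mm per degree)², i.e. ``(um_per_degree / 1000)²``.
    """
    if scale is None or scale.um_per_degree is None:
        raise ValueError("complete ScaleInfo (axial length) required for angular units")
    factor = (scale.um_per_degree / 1000.0) ** 2
    if isinstance(dm, DensityMatrix):
        return replace(dm, values=dm.values * factor, units="cones/deg^2")
    return dm * factor
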