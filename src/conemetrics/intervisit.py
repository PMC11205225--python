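"""Within-subject visit-to-visit comparison of density maps.

The two visits' matrices are aligned by a whole-grid-cell translation that
brings their CDC locations into register (no rotation, scaling, or subpixel
interpolation — at a 0.25-µm grid the registration error is ≤ half a cell).
The difference map is visit 2 − visit 1 over the overlap, cropped to a
300 × 300-µm square centered on the common CDC, valid only where both inputs
are valid.  Horizontal and vertical cross-sections through the CDC are
averaged in contiguous 5-µm bins, and per-bin means are combined across
subjects into composite profiles (mean ± between-subject SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density_map import DensityMatrix
from .foveal_metrics import find_cdc

__all__ = [
    "AlignedPair",
    "DifferenceMap",
    "Profile",
    "align_at_cdc",
    "difference_map",
    "cross_section",
    "composite_profile",
]


@dataclass(frozen=True)
class AlignedPair:
    """Two density matrices registered at their CDCs.

    ``shift_cells`` maps visit-1 grid indices to visit-2 indices:
    ``dm2[i + shift] ↔ dm1[i]``.
    """

    dm1: DensityMatrix
    dm2: DensityMatrix
    shift_cells: tuple[int, int]  # (rows, cols)
    cdc1_um: tuple[float, float]
    cdc2_um: tuple[float, float]
    cdc1_cell: tuple[int, int]


def align_at_cdc(dm1: DensityMatrix, dm2: DensityMatrix, pct: float = 80.0) -> AlignedPair:
    """Whole-cell translation bringing dm2's CDC onto dm1's CDC."""
    if abs(dm1.grid_um - dm2.grid_um) > 1e-9:
        raise ValueError("matrices must share a grid pitch")
    cdc1, _ = find_cdc(dm1, pct)
    cdc2, _ = find_cdc(dm2, pct)
    c1 = ((cdc1[1] - dm1.origin_um[1]) / dm1.grid_um,
          (cdc1[0] - dm1.origin_um[0]) / dm1.grid_um)  # (row, col), fractional
    c2 = ((cdc2[1] - dm2.origin_um[1]) / dm2.grid_um,
          (cdc2[0] - dm2.origin_um[0]) / dm2.grid_um)
    shift = (int(round(c2[0] - c1[0])), int(round(c2[1] - c1[1])))
    ny1, nx1 = dm1.shape
    ny2, nx2 = dm2.shape
    r0 = max(0, -shift[0])
    r1 = min(ny1, ny2 - shift[0])
    c0 = max(0, -shift[1])
    c1_ = min(nx1, nx2 - shift[1])
    if r1 <= r0 or c1_ <= c0:
        raise ValueError("aligned matrices do not overlap")
    return AlignedPair(
        dm1=dm1, dm2=dm2, shift_cells=shift, cdc1_um=cdc1, cdc2_um=cdc2,
        cdc1_cell=(int(round(c1[0])), int(round(c1[1]))),
    )


@dataclass(frozen=True)
class DifferenceMap:
    """CDC-aligned visit2 − visit1 density difference (cones/mm²)."""

    values: np.ndarray
    valid: np.ndarray
    grid_um: float
    cdc_cell: tuple[int, int]  # (row, col) of the common CDC within the map

    @property
    def shape(self):
        return self.values.shape

    def offsets_um(self, axis: str) -> np.ndarray:
        """Signed distance of each column (horizontal) or row (vertical) from the CDC."""
        if axis == "horizontal":
            return (np.arange(self.shape[1]) - self.cdc_cell[1]) * self.grid_um
        if axis == "vertical":
            return (np.arange(self.shape[0]) - self.cdc_cell[0]) * self.grid_um
        raise ValueError("axis must be 'horizontal' or 'vertical'")


def difference_map(pair: AlignedPair, extent_um: float = 300.0) -> DifferenceMap:
    """Subtract the aligned overlap, cropped to ``extent_um`` about the CDC."""
    dm1, dm2 = pair.dm1, pair.dm2
    sr, sc = pair.shift_cells
    ny1, nx1 = dm1.shape
    ny2, nx2 = dm2.shape
    r0 = max(0, -sr)
    r1 = min(ny1, ny2 - sr)
    c0 = max(0, -sc)
    c1 = min(nx1, nx2 - sc)
    diff = dm2.values[r0 + sr:r1 + sr, c0 + sc:c1 + sc] - dm1.values[r0:r1, c0:c1]
    valid = dm2.valid[r0 + sr:r1 + sr, c0 + sc:c1 + sc] & dm1.valid[r0:r1, c0:c1]

    half_cells = int(round(extent_um / 2.0 / dm1.grid_um))
    cr, cc = pair.cdc1_cell[0] - r0, pair.cdc1_cell[1] - c0
    rr0, rr1 = cr - half_cells, cr + half_cells + 1
    cc0, cc1 = cc - half_cells, cc + half_cells + 1
    if rr0 < 0 or cc0 < 0 or rr1 > diff.shape[0] or cc1 > diff.shape[1]:
        warnings.warn(
            f"overlap smaller than the requested {extent_um:g} um extent; cropping to overlap",
            stacklevel=2,
        )
        rr0, cc0 = max(rr0, 0), max(cc0, 0)
        rr1, cc1 = min(rr1, diff.shape[0]), min(cc1, diff.shape[1])
    out = diff[rr0:rr1, cc0:cc1]
    vout = valid[rr0:rr1, cc0:cc1]
    out = np.where(vout, out, np.nan)
    return DifferenceMap(values=out, valid=vout, grid_um=dm1.grid_um,
                         cdc_cell=(cr - rr0, cc - cc0))


@dataclass(frozen=True)
class Profile:
    """Binned meridian profile: mean ± SD difference vs offset from the CDC."""

    bin_centers_um: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    bin_um: float


def cross_section(diff: DifferenceMap, meridian: str, bin_um: float = 5.0) -> Profile:
    """Single row/column through the CDC, tiled into contiguous bins.

    Bins are centered on the CDC: the bin spanning [−bin/2, +bin/2) contains
    the CDC sample; centers are integer multiples of ``bin_um``.
    """
    if meridian == "horizontal":
        line = diff.values[diff.cdc_cell[0], :]
        ok = diff.valid[diff.cdc_cell[0], :]
    elif meridian == "vertical":
        line = diff.values[:, diff.cdc_cell[1]]
        ok = diff.valid[:, diff.cdc_cell[1]]
    else:
        raise ValueError("meridian must be 'horizontal' or 'vertical'")
    offs = diff.offsets_um(meridian)
    line, offs = line[ok], offs[ok]
    idx = np.floor(offs / bin_um + 0.5).astype(int)
    if idx.size == 0:
        return Profile(np.array([]), np.array([]), np.array([]),
                       np.array([], dtype=int), bin_um)
    lo, hi = idx.min(), idx.max()
    centers, means, sds, ns = [], [], [], []
    for b in range(lo, hi + 1):
        sel = idx == b
        if not sel.any():
            continue
        centers.append(b * bin_um)
        means.append(float(np.mean(line[sel])))
        sds.append(float(np.std(line[sel], ddof=1)) if sel.sum() > 1 else 0.0)
        ns.append(int(sel.sum()))
    return Profile(np.array(centers), np.array(means), np.array(sds),
                   np.array(ns, dtype=int), bin_um)


def composite_profile(profiles) -> Profile:
    """Across-subject mean and SD of per-subject bin means.

    Bins are matched by center (all profiles share the CDC-anchored grid);
    each bin's n counts the subjects contributing to it.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    bin_um = profiles[0].bin_um
    if any(abs(p.bin_um - bin_um) > 1e-9 for p in profiles):
        raise ValueError("profiles use different bin widths")
    all_centers = np.unique(np.concatenate([p.bin_centers_um for p in profiles]))
    if not any(
        np.intersect1d(profiles[0].bin_centers_um, p.bin_centers_um).size
        for p in profiles[1:]
    ):
        raise ValueError("profiles have disjoint bin grids")
    means, sds, ns = [], [], []
    for c in all_centers:
        vals = [
            float(p.mean[np.argmin(np.abs(p.bin_centers_um - c))])
            for p in profiles
            if np.any(np.abs(p.bin_centers_um - c) < 1e-9)
        ]
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        ns.append(len(vals))
    return Profile(all_centers, np.array(means), np.array(sds),
                   np.array(ns, dtype=int), bin_um)
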