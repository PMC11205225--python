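"""Reading, writing, and rescaling of cone coordinate files.

Cone positions are exported by marking tools as two-column ``x,y`` tables in
pixel units, origin at the top-left of the region of interest (ROI), x
rightward, y downward.  A small JSON sidecar supplies the spatial scale
(µm/pixel), the ROI side length, and optionally the eye's axial length so
densities can be expressed in angular units.  All analysis downstream works on
physical positions (µm); before analysis every field is rescaled to a common
pixel pitch so window growth happens on one shared grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as _field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ConeField",
    "ScaleInfo",
    "read_cone_field",
    "write_cone_field",
    "rescale_to_common",
    "um_per_degree_from_axial_length",
]

#: Default common scale (µm/pixel) shared by all rescaled fields.
DEFAULT_COMMON_SCALE = 0.25


def um_per_degree_from_axial_length(axial_length_mm: float) -> float:
    """Retinal magnification (µm of retina per degree of visual angle).

    Uses Bennett's adjusted axial-length formula, q = 0.01306·(AL − 1.82)
    mm/deg.  Axial lengths outside the 20–30 mm adult range trigger a warning
    (not an error): the formula extrapolates smoothly but such eyes are
    outside its validated domain.
    """
    axial_length_mm = float(axial_length_mm)
    if not (20.0 <= axial_length_mm <= 30.0):
        warnings.warn(
            f"axial length {axial_length_mm:g} mm outside the 20-30 mm sanity range",
            stacklevel=2,
        )
    return 1000.0 * 0.01306 * (axial_length_mm - 1.82)


@dataclass(frozen=True)
class ScaleInfo:
    """Spatial scale of one imaging session."""

    um_per_pixel: float
    um_per_degree: float
    axial_length_mm: float | None = None

    def __post_init__(self):
        if self.um_per_pixel <= 0 or self.um_per_degree <= 0:
            raise ValueError("scales must be strictly positive")

    @classmethod
    def from_axial_length(cls, axial_length_mm: float, um_per_pixel: float) -> "ScaleInfo":
        return cls(
            um_per_pixel=um_per_pixel,
            um_per_degree=um_per_degree_from_axial_length(axial_length_mm),
            axial_length_mm=axial_length_mm,
        )


@dataclass(frozen=True)
class ConeField:
    """Cone (x, y) coordinates for one square ROI, with scale metadata.

    Parameters
    ----------
    points : (N, 2) float array, pixel units, origin top-left.
    um_per_pixel : spatial scale of the coordinates.
    roi_side_um : side length of the square ROI in µm.
    """

    points: np.ndarray
    um_per_pixel: float
    roi_side_um: float
    subject_id: str = ""
    visit: int = 1
    axial_length_mm: float | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (N, 2), got shape {pts.shape}")
        object.__setattr__(self, "points", pts)
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be > 0")
        if self.roi_side_um <= 0:
            raise ValueError("roi_side_um must be > 0")
        side_px = self.roi_side_um / self.um_per_pixel
        if pts.size and (pts.min() < -1e-9 or pts.max() > side_px + 1e-9):
            bad = pts[(pts[:, 0] < 0) | (pts[:, 0] > side_px)
                      | (pts[:, 1] < 0) | (pts[:, 1] > side_px)]
            raise ValueError(
                f"{len(bad)} point(s) outside the ROI [0, {side_px:g}] px, "
                f"first offender {tuple(bad[0])}"
            )
        # Exact duplicates break Voronoi construction; reject rather than dedupe.
        if pts.size:
            uniq, counts = np.unique(pts, axis=0, return_counts=True)
            if (counts > 1).any():
                dup = uniq[counts > 1][0]
                raise ValueError(f"duplicate cone coordinate at {tuple(dup)}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def roi_side_px(self) -> float:
        return self.roi_side_um / self.um_per_pixel

    @property
    def points_um(self) -> np.ndarray:
        """Coordinates in physical units (µm from the ROI top-left corner)."""
        return self.points * self.um_per_pixel

    def scale_info(self) -> ScaleInfo:
        if self.axial_length_mm is None:
            raise ValueError("axial_length_mm is required for angular units")
        return ScaleInfo.from_axial_length(self.axial_length_mm, self.um_per_pixel)


def read_cone_field(coord_path, metadata_path=None, **overrides) -> ConeField:
    """Read a two-column coordinate CSV plus its JSON metadata sidecar.

    The CSV has no header by default; a single leading non-numeric row is
    auto-detected and skipped.  ``metadata_path`` defaults to the coordinate
    file with a ``.json`` suffix.  Keyword overrides (``um_per_pixel``,
    ``roi_side_um``, ``subject_id``, ``visit``, ``axial_length_mm``) take
    precedence over the sidecar, so a manifest-table workflow can feed scale
    per file without sidecars.
    """
    coord_path = Path(coord_path)
    rows = []
    with open(coord_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for i, line in enumerate(lines):
        cells = [c for c in line.replace("\t", ",").split(",") if c.strip() != ""]
        if len(cells) != 2:
            raise ValueError(f"{coord_path.name}: line {i + 1}: expected 2 columns, got {len(cells)}")
        try:
            rows.append((float(cells[0]), float(cells[1])))
        except ValueError:
            if i == 0:
                continue  # header row
            raise ValueError(
                f"{coord_path.name}: line {i + 1}: non-numeric cell in {cells!r}"
            ) from None
    meta: dict = {}
    if metadata_path is None:
        candidate = coord_path.with_suffix(".json")
        if candidate.exists():
            metadata_path = candidate
    if metadata_path is not None:
        meta = json.loads(Path(metadata_path).read_text())
    meta.update(overrides)
    if "um_per_pixel" not in meta:
        raise ValueError(f"{coord_path.name}: no scale (um_per_pixel) in metadata or overrides")
    if "roi_side_um" not in meta:
        raise ValueError(f"{coord_path.name}: no roi_side_um in metadata or overrides")
    allowed = {"um_per_pixel", "roi_side_um", "subject_id", "visit", "axial_length_mm"}
    meta = {k: v for k, v in meta.items() if k in allowed}
    return ConeField(points=np.array(rows, dtype=float).reshape(-1, 2), **meta)


def write_cone_field(field: ConeField, coord_path, metadata_path=None) -> None:
    """Write coordinates as headerless CSV plus a JSON metadata sidecar."""
    coord_path = Path(coord_path)
    if metadata_path is None:
        metadata_path = coord_path.with_suffix(".json")
    np.savetxt(coord_path, field.points, delimiter=",", fmt="%.17g")
    meta = {
        "um_per_pixel": field.um_per_pixel,
        "roi_side_um": field.roi_side_um,
        "subject_id": field.subject_id,
        "visit": field.visit,
    }
    if field.axial_length_mm is not None:
        meta["axial_length_mm"] = field.axial_length_mm
    Path(metadata_path).write_text(json.dumps(meta, indent=1))


def rescale_to_common(field: ConeField, target_um_per_pixel: float = DEFAULT_COMMON_SCALE) -> ConeField:
    """Re-express pixel coordinates at a common scale; physical positions unchanged."""
    if target_um_per_pixel <= 0:
        raise ValueError("target_um_per_pixel must be > 0")
    if target_um_per_pixel == field.um_per_pixel:
        return field
    factor = field.um_per_pixel / target_um_per_pixel
    return replace(field, points=field.points * factor, um_per_pixel=target_um_per_pixel)
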