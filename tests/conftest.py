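import numpy as np
import pytest
from hypothesis import settings

from conemetrics import ConeField, DensityMatrix
from conemetrics.synthetic_data import MosaicParams, generate_mosaic, hex_spacing_for_density

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_dm(values, grid_um=1.0, origin=(0.0, 0.0), window=None, margin=0.0):
    """Build a DensityMatrix directly from an array (NaN = invalid)."""
    values = np.asarray(values, dtype=float)
    valid = np.isfinite(values)
    if window is None:
        window = np.where(valid, 0.0, np.nan)
    return DensityMatrix(values=values, valid=valid, window_um=np.asarray(window, float),
                         grid_um=grid_um, origin_um=origin, edge_margin_um=margin)


def hex_field(density_per_mm2=190_000.0, roi_um=60.0, um_per_pixel=0.25):
    """Perfect hexagonal lattice clipped to a square ROI (analytic oracle)."""
    s = hex_spacing_for_density(density_per_mm2)
    n1 = int(np.ceil(roi_um / s)) + 2
    n2 = int(np.ceil(roi_um / (s * np.sqrt(3) / 2))) + 2
    i, j = np.meshgrid(np.arange(-n1, n1 + 1), np.arange(-n2, n2 + 1), indexing="ij")
    x = (i + 0.5 * (j % 2)) * s + roi_um / 2
    y = j * (s * np.sqrt(3) / 2) + roi_um / 2
    pts = np.column_stack([x.ravel(), y.ravel()])
    keep = ((pts >= 0) & (pts <= roi_um)).all(axis=1)
    return ConeField(points=pts[keep] / um_per_pixel, um_per_pixel=um_per_pixel,
                     roi_side_um=roi_um), s


@pytest.fixture(scope="session")
def uniform_mosaic():
    """Jittered but statistically uniform mosaic (huge falloff scale)."""
    return generate_mosaic(MosaicParams(
        peak_density=190_000.0, falloff_scale=1e6, roi_side=120.0,
        position_jitter_sd=0.25, seed=11))


@pytest.fixture(scope="session")
def peaked_mosaic():
    params = MosaicParams(
        peak_density=190_000.0, falloff_scale=400.0, roi_side=250.0,
        position_jitter_sd=0.25, peak_offset=(10.0, -6.0), seed=5)
    return params, generate_mosaic(params)
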