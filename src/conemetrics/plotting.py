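"""Matplotlib views of density maps, agreement, and difference profiles."""

from __future__ import annotations

import numpy as np

from .cohort_stats import AgreementResult
from .density_map import DensityMatrix
from .intervisit import Profile


def plot_density_map(dm: DensityMatrix, ax=None, cmap="viridis"):
    """Density matrix as an image in physical coordinates (µm)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x, y = dm.x_um(), dm.y_um()
    h = dm.grid_um / 2.0
    im = ax.imshow(
        dm.values, origin="upper", cmap=cmap,
        extent=(x[0] - h, x[-1] + h, y[-1] + h, y[0] - h),
    )
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.figure.colorbar(im, ax=ax, label=dm.units)
    return ax


def plot_bland_altman(v1, v2, result: AgreementResult, ax=None, units=""):
    """Classic agreement plot: per-subject difference vs mean, with bias and LoA."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    ax.scatter((v1 + v2) / 2.0, v2 - v1, color="k", zorder=3)
    ax.axhline(result.bias, color="C0", label="mean bias")
    for lo in (result.loa_lower, result.loa_upper):
        ax.axhline(lo, color="C0", linestyle="--")
    ax.axhspan(*result.bias_ci, color="C0", alpha=0.15)
    ax.axhspan(*result.loa_lower_ci, color="C0", alpha=0.1)
    ax.axhspan(*result.loa_upper_ci, color="C0", alpha=0.1)
    ax.set_xlabel(f"mean of visits {units}".strip())
    ax.set_ylabel(f"visit 2 − visit 1 {units}".strip())
    return ax


def plot_profile(profile: Profile, ax=None, label=None):
    """Composite difference profile with between-subject SD error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(profile.bin_centers_um, profile.mean, yerr=profile.sd,
                fmt="o-", capsize=2, label=label)
    ax.axhline(0.0, color="k", linestyle="--", linewidth=0.8)
    ax.set_xlabel("offset from CDC (µm)")
    ax.set_ylabel("density difference (cones/mm²)")
    return ax
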