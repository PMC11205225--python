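"""Cohort-level intervisit reproducibility statistics and pipeline driver.

For each metric (PCD and CDC density in linear and angular units, 80th
percentile contour area, PCD–CDC offset) the cohort analysis reports
per-subject percent changes, a Shapiro–Wilk normality test of the intervisit
differences, a paired t-test, Pearson's correlation with a Fisher-z 95% CI,
and a Bland–Altman analysis (mean bias, 95% limits of agreement, and CIs for
all three).  Differences are oriented visit 2 − visit 1 throughout.  Metric
values entering the table are rounded to three significant digits, matching
the uncertainty of the image scale measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dfield

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coords_io import ScaleInfo, rescale_to_common
from .density_map import compute_density_matrix, crop_density_matrix
from .foveal_metrics import extract_metrics, round_sig
from .intervisit import align_at_cdc, composite_profile, cross_section, difference_map

__all__ = [
    "AgreementResult",
    "PipelineConfig",
    "CohortResult",
    "percent_change",
    "bland_altman",
    "pearson_with_ci",
    "paired_t",
    "shapiro_wilk",
    "run_cohort",
    "METRIC_COLUMNS",
]


def percent_change(v1: float, v2: float) -> float:
    """Absolute intervisit change as a percentage of the visit-1 baseline."""
    if v1 <= 0:
        raise ValueError("visit-1 baseline must be > 0")
    return 100.0 * abs(v2 - v1) / v1


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement between paired visits (differences v2 − v1)."""

    bias: float
    bias_ci: tuple[float, float]
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    sd: float
    n: int


def bland_altman(v1, v2) -> AgreementResult:
    """Mean bias and 95% limits of agreement with their 95% CIs.

    LoA = bias ± 1.96·SD(d); the bias CI uses SD/√n and the LoA CIs the
    classic √(3/n)·SD approximation, with t(0.975, n−1) critical values.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("paired samples must have equal length")
    n = v1.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = v2 - v1
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    tcrit = float(sps.t.ppf(0.975, n - 1))
    half_bias = tcrit * sd / np.sqrt(n)
    half_loa = tcrit * sd * np.sqrt(3.0 / n)
    lo = bias - 1.96 * sd
    hi = bias + 1.96 * sd
    return AgreementResult(
        bias=bias,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_lower=lo, loa_upper=hi,
        loa_lower_ci=(lo - half_loa, lo + half_loa),
        loa_upper_ci=(hi - half_loa, hi + half_loa),
        sd=sd, n=n,
    )


def pearson_with_ci(x, y, conf: float = 0.95):
    """Sample Pearson r with a Fisher-z confidence interval.

    Returns ``(r, (lo, hi), p)``; the CI uses atanh(r) ± z·(n−3)^{−1/2}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
    r = min(1.0, max(-1.0, r))
    # two-sided p from the exact t distribution of r under the null
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(tstat), n - 2))
    zcrit = float(sps.norm.ppf(0.5 + conf / 2.0))
    if abs(r) == 1.0:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    return r, ci, p


def paired_t(v1, v2):
    """Paired two-sided t-test on d = v2 − v1; returns ``(t, df, p)``.

    Identical pairs (zero mean, zero variance) are reported as t = 0, p = 1;
    zero variance with a nonzero mean as ±inf, p = 0.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("paired samples must have equal length")
    n = v1.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = v2 - v1
    df = n - 1
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(mean)) * np.inf, df, 0.0
    t = mean / (sd / np.sqrt(n))
    return float(t), df, float(2.0 * sps.t.sf(abs(t), df))


def shapiro_wilk(d):
    """Shapiro–Wilk normality test (Royston's algorithm via scipy)."""
    d = np.asarray(d, dtype=float)
    if not (3 <= d.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(d) == 0:
        raise ValueError("all values equal: normality test undefined")
    w, p = sps.shapiro(d)
    return float(w), float(p)


#: metric column stems in the cohort table; each appears as <stem>_v1 / <stem>_v2
METRIC_COLUMNS = (
    "pcd_mm2", "pcd_deg2", "cdc_mm2", "cdc_deg2", "area_um2", "offset_um",
)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis settings.

    common_scale_um_per_px : shared pixel pitch after rescaling.
    k : target cone count of the adaptive sampling window.
    stride : grid subsampling in pixels (1 = every pixel).
    percentile : isodensity-contour percentile.
    analysis_side_um : central square on which metrics are extracted,
        making 300- and 500-µm ROIs comparable.
    edge_margin_um : boundary exclusion margin of the density engine.
    bin_um : cross-section bin width.
    """

    common_scale_um_per_px: float = 0.25
    k: int = 150
    stride: int = 1
    percentile: float = 80.0
    analysis_side_um: float = 300.0
    edge_margin_um: float = 10.0
    bin_um: float = 5.0
    round_digits: int = 3


@dataclass
class CohortResult:
    """Cohort table, per-metric statistics, and composite difference profiles."""

    table: pd.DataFrame
    agreement: dict
    tests: pd.DataFrame
    profile_horizontal: object
    profile_vertical: object
    excluded: list = _dfield(default_factory=list)

    def metric_pairs(self, stem: str):
        return self.table[f"{stem}_v1"].to_numpy(), self.table[f"{stem}_v2"].to_numpy()


def _metrics_for_field(field, config: PipelineConfig):
    common = rescale_to_common(field, config.common_scale_um_per_px)
    dm = compute_density_matrix(
        common, k=config.k, stride=config.stride,
        edge_margin_um=config.edge_margin_um,
    )
    scale = None
    if field.axial_length_mm is not None:
        scale = ScaleInfo.from_axial_length(
            field.axial_length_mm, config.common_scale_um_per_px)
    fm = extract_metrics(dm, scale=scale, pct=config.percentile,
                         analysis_side_um=config.analysis_side_um)
    return fm, dm


def run_cohort(subjects, config: PipelineConfig | None = None) -> CohortResult:
    """Full pipeline: fields → density matrices → metrics → cohort statistics.

    ``subjects`` iterates objects with ``subject_id``, ``visit1``, ``visit2``
    ConeFields and optional ``interval_years`` (synthetic_data.SubjectVisits
    or any equivalent).  Subjects missing a visit are excluded with a warning.
    Deterministic given its inputs.
    """
    config = config or PipelineConfig()
    rows, profiles_h, profiles_v, excluded = [], [], [], []
    for subj in subjects:
        if getattr(subj, "visit1", None) is None or getattr(subj, "visit2", None) is None:
            excluded.append(subj.subject_id)
            continue
        fm1, dm1 = _metrics_for_field(subj.visit1, config)
        fm2, dm2 = _metrics_for_field(subj.visit2, config)
        # difference maps compare like-for-like analysis crops
        a1 = crop_density_matrix(dm1, config.analysis_side_um) \
            if dm1.x_um()[-1] - dm1.x_um()[0] > config.analysis_side_um + 1e-9 else dm1
        a2 = crop_density_matrix(dm2, config.analysis_side_um) \
            if dm2.x_um()[-1] - dm2.x_um()[0] > config.analysis_side_um + 1e-9 else dm2
        pair = align_at_cdc(a1, a2, pct=config.percentile)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diff = difference_map(pair, extent_um=config.analysis_side_um)
        profiles_h.append(cross_section(diff, "horizontal", config.bin_um))
        profiles_v.append(cross_section(diff, "vertical", config.bin_um))

        rd = config.round_digits
        row = {"subject_id": subj.subject_id,
               "interval_years": getattr(subj, "interval_years", np.nan),
               "axial_length_mm": getattr(subj, "axial_length_mm", np.nan)}
        for stem, fm in (("v1", fm1), ("v2", fm2)):
            row[f"pcd_mm2_{stem}"] = round_sig(fm.pcd_mm2, rd)
            row[f"cdc_mm2_{stem}"] = round_sig(fm.cdc_mm2, rd)
            row[f"area_um2_{stem}"] = round_sig(fm.contour_area_um2, rd)
            row[f"offset_um_{stem}"] = round_sig(fm.offset_um, rd)
            row[f"pcd_deg2_{stem}"] = (
                round_sig(fm.pcd_deg2, rd) if fm.pcd_deg2 is not None else np.nan)
            row[f"cdc_deg2_{stem}"] = (
                round_sig(fm.cdc_deg2, rd) if fm.cdc_deg2 is not None else np.nan)
        rows.append(row)

    if excluded:
        warnings.warn(f"excluded subjects missing a visit: {excluded}", stacklevel=2)
    table = pd.DataFrame(rows)

    agreement, test_rows = {}, []
    for stem in METRIC_COLUMNS:
        v1 = table[f"{stem}_v1"].to_numpy(dtype=float)
        v2 = table[f"{stem}_v2"].to_numpy(dtype=float)
        if np.isnan(v1).all() or np.isnan(v2).all():
            continue
        d = v2 - v1
        agreement[stem] = bland_altman(v1, v2)
        t, df, p = paired_t(v1, v2)
        try:
            w, shapiro_p = shapiro_wilk(d)
        except ValueError:
            w, shapiro_p = np.nan, np.nan
        try:
            r, r_ci, r_p = pearson_with_ci(v1, v2)
        except ValueError:
            r, r_ci, r_p = np.nan, (np.nan, np.nan), np.nan
        # offset can legitimately be 0 at baseline; guard percent change
        pc = np.array([
            percent_change(a, b) if a > 0 else np.nan for a, b in zip(v1, v2)
        ])
        interval = table["interval_years"].to_numpy(dtype=float)
        try:
            r_int, _, r_int_p = pearson_with_ci(interval, np.abs(d))
        except ValueError:
            r_int, r_int_p = np.nan, np.nan
        test_rows.append({
            "metric": stem,
            "mean_v1": float(np.nanmean(v1)), "sd_v1": float(np.nanstd(v1, ddof=1)),
            "mean_v2": float(np.nanmean(v2)), "sd_v2": float(np.nanstd(v2, ddof=1)),
            "t": t, "df": df, "p": p,
            "shapiro_w": w, "shapiro_p": shapiro_p,
            "pearson_r": r, "pearson_ci_lo": r_ci[0], "pearson_ci_hi": r_ci[1],
            "pearson_p": r_p,
            "pct_change_mean": float(np.nanmean(pc)),
            "pct_change_min": float(np.nanmin(pc)),
            "pct_change_max": float(np.nanmax(pc)),
            "interval_r": r_int, "interval_r_p": r_int_p,
        })
    tests = pd.DataFrame(test_rows).set_index("metric")

    return CohortResult(
        table=table,
        agreement=agreement,
        tests=tests,
        profile_horizontal=composite_profile(profiles_h),
        profile_vertical=composite_profile(profiles_v),
        excluded=excluded,
    )
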