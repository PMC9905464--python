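"""Comparison layer: percentage differences, lung shunt fraction, TN ratio,
Bland-Altman agreement, motion-amplitude estimation by mutual-information
translation registration, tumor geometric predictors and the paired
statistical testing suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats
from skimage.registration import phase_cross_correlation

from mocospect.grid import AXIS_CC

# ---------------------------------------------------------------------------
# scalar formulas


def pdd(d_comp: float, d_3d: float) -> float:
    """Percentage dose difference of the compensated arm relative to 3D."""
    if d_3d == 0:
        raise ValueError("PDD undefined for zero reference dose")
    return (d_comp - d_3d) / d_3d * 100.0


def lsf(c_lungs: float, c_liver: float) -> float:
    """Lung shunt fraction in percent."""
    if c_lungs + c_liver <= 0:
        raise ValueError("LSF undefined for zero total counts")
    return c_lungs / (c_lungs + c_liver) * 100.0


def tn_ratio(c_t: float, v_t: float, c_hl: float, v_hl: float) -> float:
    """Tumor-to-normal-liver activity concentration ratio."""
    if min(c_t, v_t, c_hl, v_hl) <= 0:
        raise ValueError("TN ratio requires positive counts and volumes")
    return (c_t / v_t) / (c_hl / v_hl)


def pda(a_comp: float, a_3d: float) -> float:
    """Percentage difference in prescribed activity, same form as PDD."""
    if a_3d == 0:
        raise ValueError("PDA undefined for zero reference activity")
    return (a_comp - a_3d) / a_3d * 100.0


def pve_threshold_volume_ml(resolution_fwhm_mm: float = 7.4, factor: float = 2.5) -> float:
    """Volume of a sphere whose diameter is ``factor`` x the system resolution:
    structures below it are strongly partial-volume affected."""
    r = factor * resolution_fwhm_mm / 2.0
    return 4.0 / 3.0 * np.pi * r**3 / 1000.0


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    diffs: np.ndarray
    means: np.ndarray
    shapiro_p: float | None


def bland_altman(a, b) -> BlandAltman:
    """Agreement analysis of paired series: differences a-b, mean and
    mean +/- 1.96 sd limits; normality of the differences is reported."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    m = (a + b) / 2.0
    sd = float(np.std(d, ddof=1))
    try:
        p = float(stats.shapiro(d).pvalue) if np.ptp(d) > 0 else None
    except Exception:
        p = None
    return BlandAltman(float(d.mean()), float(d.mean() - 1.96 * sd),
                       float(d.mean() + 1.96 * sd), d, m, p)


# ---------------------------------------------------------------------------
# amplitude estimation


class AmplitudeNotEstimable(RuntimeError):
    """Raised when the VOI is too small or the registration fails."""


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px[:, None] * py[None, :])[nz])))


def estimate_translation(
    fixed: np.ndarray,
    moving: np.ndarray,
    mask: np.ndarray,
    spacing_mm,
    bins: int = 32,
    dilate: int = 2,
    min_voxels: int = 20,
) -> np.ndarray:
    """Translation-only registration of ``moving`` onto ``fixed`` restricted
    to the (dilated) mask, maximizing histogram mutual information.

    Returns the 3D translation in mm (content displacement applied to the
    moving image to align it with the fixed image).
    """
    mask = mask.astype(bool)
    if mask.sum() < min_voxels:
        raise AmplitudeNotEstimable("VOI too small for registration")
    if dilate > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    spacing = np.asarray(spacing_mm, dtype=float)

    try:
        shift_vox, _, _ = phase_cross_correlation(
            fixed * mask, moving * mask, upsample_factor=8
        )
    except Exception:
        shift_vox = np.zeros(3)

    fvals = fixed[mask]

    def neg_mi(t_mm):
        warped = ndimage.shift(moving, t_mm / spacing, order=1, mode="constant")
        return -_mutual_information(fvals, warped[mask], bins)

    t0 = shift_vox * spacing
    res = optimize.minimize(
        neg_mi, t0, method="Powell", options={"xtol": 1e-2, "maxiter": 200}
    )
    t = res.x if (res.success or neg_mi(res.x) <= neg_mi(t0)) else t0
    if not np.all(np.isfinite(t)):
        raise AmplitudeNotEstimable("registration failed")
    return np.asarray(t, dtype=float)


def estimate_amplitude(
    recon_inhale: np.ndarray,
    recon_exhale: np.ndarray,
    liver_mask: np.ndarray,
    spacing_mm,
    bins: int = 32,
) -> float:
    """Breathing amplitude: norm of the liver-restricted 3D translation
    between extreme-phase reconstructions."""
    if recon_inhale.shape != recon_exhale.shape:
        raise ValueError("reconstructions must share geometry")
    t = estimate_translation(recon_exhale, recon_inhale, liver_mask, spacing_mm, bins)
    return float(np.linalg.norm(t))


# ---------------------------------------------------------------------------
# tumor geometric predictors


def _border(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def tumor_features(
    lesion: np.ndarray,
    liver: np.ndarray,
    spacing_mm,
    cc_amplitude_mm: float | None = None,
) -> dict:
    """Seven per-lesion predictors of motion susceptibility (plus each
    divided by the lesion volume).

    1. volume (mL); 2./3. min and mean distance of lesion voxels to the
    liver border; 4. min CC gap between the lesion top and the liver top
    over the lesion's axial footprint; 5. lesion CC motion amplitude
    (supplied); 6. distance from the lesion center of mass to the liver
    border; 7. the same restricted to the CC line through the center of mass.
    """
    lesion = lesion.astype(bool)
    liver = liver.astype(bool)
    if not lesion.any() or not liver.any():
        raise ValueError("masks must be nonempty")
    if np.any(lesion & ~liver):
        warnings.warn("lesion extends outside the liver; features still computed")
    spacing = np.asarray(spacing_mm, dtype=float)
    vol_ml = float(lesion.sum()) * float(np.prod(spacing)) / 1000.0

    border = _border(liver)
    dist_to_border = ndimage.distance_transform_edt(~border, sampling=spacing)
    lesion_d = dist_to_border[lesion]
    f2 = float(lesion_d.min())
    f3 = float(lesion_d.mean())

    # 4: per axial column of the lesion footprint, liver-top minus lesion-top
    lesion_top = _top_cc_map(lesion)
    liver_top = _top_cc_map(liver)
    foot = ~np.isnan(lesion_top)
    gaps = (liver_top - lesion_top)[foot & ~np.isnan(liver_top)]
    f4 = float(np.nanmin(gaps)) * spacing[AXIS_CC] if gaps.size else np.nan

    f5 = float(cc_amplitude_mm) if cc_amplitude_mm is not None else np.nan

    com = ndimage.center_of_mass(lesion)
    com_idx = tuple(int(round(c)) for c in com)
    f6 = float(dist_to_border[com_idx])

    col = border[com_idx[0], com_idx[1], :]
    zs = np.nonzero(col)[0]
    if zs.size:
        f7 = float(np.min(np.abs(zs - com[2]))) * spacing[AXIS_CC]
    else:  # no border voxel on the CC line: fall back to the CC offset
        bz = np.nonzero(border)[2]
        f7 = float(np.min(np.abs(bz - com[2]))) * spacing[AXIS_CC]

    feats = {
        "volume_ml": vol_ml,
        "min_border_dist_mm": f2,
        "mean_border_dist_mm": f3,
        "cc_top_gap_mm": f4,
        "cc_amplitude_mm": f5,
        "com_border_dist_mm": f6,
        "com_border_dist_cc_mm": f7,
    }
    for key in list(feats):
        if key != "volume_ml":
            feats[key + "_per_ml"] = feats[key] / vol_ml
    return feats


def _top_cc_map(mask: np.ndarray) -> np.ndarray:
    """Most-cranial occupied CC index per axial (LR, AP) column; NaN if empty."""
    nz = mask.shape[AXIS_CC]
    idx = np.arange(nz)
    any_col = mask.any(axis=AXIS_CC)
    top = np.where(any_col, (mask * idx).max(axis=AXIS_CC), np.nan)
    return top.astype(float)


# ---------------------------------------------------------------------------
# statistics suite


@dataclass
class PairedTestReport:
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    branch: str  # "paired-t" | "wilcoxon"
    statistic: float
    p_value: float
    mean_diff: float
    forced_branch: bool = False


def paired_test(a, b, normality_alpha: float = 0.05) -> PairedTestReport:
    """Shapiro-Wilk gate then paired t (both normal) or paired Wilcoxon."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need paired series of length >= 3")

    def shap(x):
        if np.ptp(x) == 0:
            return None
        return float(stats.shapiro(x).pvalue)

    pa, pb = shap(a), shap(b)
    forced = pa is None or pb is None
    normal = (not forced) and pa >= normality_alpha and pb >= normality_alpha
    d = a - b
    if np.ptp(d) == 0 and np.all(d == 0):
        return PairedTestReport(pa, pb, "wilcoxon", 0.0, 1.0, 0.0, forced_branch=True)
    if normal:
        res = stats.ttest_rel(a, b)
        return PairedTestReport(pa, pb, "paired-t", float(res.statistic),
                                float(res.pvalue), float(d.mean()))
    res = stats.wilcoxon(a, b, zero_method="wilcox")
    return PairedTestReport(pa, pb, "wilcoxon", float(res.statistic),
                            float(res.pvalue), float(d.mean()), forced_branch=forced)


def spearman_screen(target, features: dict[str, np.ndarray]) -> dict[str, tuple]:
    """Raw (uncorrected) Spearman rho and p for each feature against the target."""
    target = np.asarray(target, dtype=float)
    out = {}
    for name, values in features.items():
        v = np.asarray(values, dtype=float)
        ok = np.isfinite(v) & np.isfinite(target)
        if ok.sum() < 3:
            out[name] = (np.nan, np.nan)
            continue
        rho, p = stats.spearmanr(v[ok], target[ok])
        out[name] = (float(rho), float(p))
    return out


def stats_suite(
    series_a, series_b, features: dict[str, np.ndarray] | None = None
) -> dict:
    """Full report: normality, branch taken, paired test, optional Spearman
    screen of predictors against the paired percentage differences."""
    rep = paired_test(series_a, series_b)
    out = {
        "shapiro_p_a": rep.shapiro_p_a,
        "shapiro_p_b": rep.shapiro_p_b,
        "branch": rep.branch,
        "forced_branch": rep.forced_branch,
        "statistic": rep.statistic,
        "p_value": rep.p_value,
        "mean_diff": rep.mean_diff,
    }
    if features:
        a = np.asarray(series_a, dtype=float)
        b = np.asarray(series_b, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            target = (a - b) / b * 100.0
        out["spearman"] = spearman_screen(target, features)
    return out
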