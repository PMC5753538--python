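"""Transmural helix-angle profiles and quantitative quality / summary
statistics: wall-thickness-normalised helix-angle gradient (HAG), per-spoke
linear-fit R^2 and RMSE, transverse-angle standard deviation, the automated
HA-map quality score, repeated-measures SNR and global LV summaries.

The HA-map score is an automated surrogate for the visual rubric: a spoke is
"normal" when its transmural HA profile is credibly linear (R^2 above a
threshold) with the expected slope sign, and the fraction f of normal spokes
maps to a score of 3 (f > 0.95), 2 (f > 0.75), 1 (f >= 0.5) or 0 (failure).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .containers import CardiacCoordinateField, ScalarMaps, TransmuralProfile

__all__ = [
    "extract_profiles",
    "hag_and_fit_stats",
    "ta_std",
    "score_ha_map",
    "snr_repeated_measures",
    "mean_signal_ratio",
    "summarize_lv",
]


def _linfit(x: np.ndarray, y: np.ndarray):
    """OLS line y = a x + b with R^2 (0 for a zero-variance regression) and
    RMSE of the residuals."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ coef
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot <= 1e-30 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / len(y)))
    return float(coef[0]), float(coef[1]), r2, rmse


def extract_profiles(ha_map: np.ndarray, coords: CardiacCoordinateField,
                     n_spokes: int = 72,
                     depth_fractions: np.ndarray | None = None,
                     exclusion: np.ndarray | None = None,
                     min_samples: int = 3) -> list[TransmuralProfile]:
    """Sample transmural HA profiles along equally spaced radial spokes.

    Each spoke runs from the LV centre outward; HA and depth are sampled by
    bilinear interpolation along the ray and the profile is resampled at
    fixed depth fractions (epi = 0% to endo = 100%). Spokes with fewer than
    ``min_samples`` valid samples are dropped with a warning.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    if depth_fractions is None:
        depth_fractions = np.linspace(5.0, 95.0, 19)
    mask = coords.valid & np.isfinite(coords.depth)
    if exclusion is not None:
        mask = mask & ~exclusion
    if not mask.any():
        raise ValueError("no valid myocardium for profile extraction")
    ny, nx = mask.shape
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    rmax = float(np.hypot(rows - cy, cols - cx).max()) + 2.0

    ha_f = np.where(np.isfinite(ha_map), ha_map, 0.0)
    ha_ok = np.isfinite(ha_map) & mask
    depth_f = np.where(np.isfinite(coords.depth), coords.depth, 0.0)

    profiles: list[TransmuralProfile] = []
    n_dropped = 0
    ts = np.arange(0.0, rmax, 0.25)
    for k in range(n_spokes):
        ang = 2.0 * np.pi * k / n_spokes
        xs = cx + ts * np.cos(ang)
        ys = cy + ts * np.sin(ang)
        inside = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
        xs, ys = xs[inside], ys[inside]
        pts = np.vstack([ys, xs])
        ok = ndimage.map_coordinates(ha_ok.astype(float), pts, order=1) > 0.999
        if ok.sum() < min_samples:
            n_dropped += 1
            continue
        ha_s = ndimage.map_coordinates(ha_f, pts, order=1)[ok]
        de_s = ndimage.map_coordinates(depth_f, pts, order=1)[ok] * 100.0
        order = np.argsort(de_s)
        de_s, ha_s = de_s[order], ha_s[order]
        de_u, iu = np.unique(de_s, return_index=True)
        ha_u = ha_s[iu]
        sel = (depth_fractions >= de_u[0]) & (depth_fractions <= de_u[-1])
        if sel.sum() < min_samples:
            n_dropped += 1
            continue
        d_fix = depth_fractions[sel]
        h_fix = np.interp(d_fix, de_u, ha_u)
        slope, intercept, r2, rmse = _linfit(d_fix, h_fix)
        profiles.append(TransmuralProfile(
            spoke=k, depth_pct=d_fix, ha_deg=h_fix, slope=slope,
            intercept=intercept, r2=r2, rmse=rmse))
    if n_dropped:
        warnings.warn(f"{n_dropped}/{n_spokes} spokes dropped "
                      f"(<{min_samples} valid samples)", stacklevel=2)
    return profiles


def hag_and_fit_stats(profiles: list[TransmuralProfile],
                      pooled: bool = False):
    """HAG (deg per % wall depth), mean HA R^2 and mean HA RMSE.

    By default HAG is the mean of per-spoke OLS slopes; ``pooled=True``
    instead fits one line to the pooled samples of all spokes.
    """
    if not profiles:
        raise ValueError("no valid transmural profiles")
    if pooled:
        d = np.concatenate([p.depth_pct for p in profiles])
        h = np.concatenate([p.ha_deg for p in profiles])
        hag = _linfit(d, h)[0]
    else:
        hag = float(np.mean([p.slope for p in profiles]))
    r2 = float(np.mean([p.r2 for p in profiles]))
    rmse = float(np.mean([p.rmse for p in profiles]))
    return hag, r2, rmse


def ta_std(ta_map: np.ndarray, mask: np.ndarray) -> float:
    """Standard deviation (ddof=1) of the transverse angle over the mask,
    flagged (NaN) pixels excluded."""
    vals = ta_map[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need >=2 valid pixels for TA std")
    return float(np.std(vals, ddof=1))


def score_ha_map(profiles: list[TransmuralProfile],
                 r2_threshold: float = 0.3,
                 slope_sign: int = 1):
    """Map the fraction of normal spokes to the 0-3 HA-map quality score.

    Returns ``(score, normal_fraction)``; a score of 0 marks the dataset as
    failed (<50% of spokes normal).
    """
    if not profiles:
        return 0, 0.0
    normal = [(p.r2 >= r2_threshold) and (p.slope * slope_sign > 0)
              for p in profiles]
    f = float(np.mean(normal))
    if f > 0.95:
        score = 3
    elif f > 0.75:
        score = 2
    elif f >= 0.5:
        score = 1
    else:
        score = 0
    return score, f


def snr_repeated_measures(frames: np.ndarray, roi_mask: np.ndarray) -> float:
    """SNR per image by the repeated-measurement method: per-pixel
    mean / standard deviation of the signal over repeats, averaged over the
    ROI. Zero-SD pixels are excluded with a warning rather than returned as
    infinite SNR."""
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 3:
        raise ValueError("need >=3 repeats of the same condition")
    mean = frames.mean(axis=0)
    sd = frames.std(axis=0, ddof=1)
    roi = np.asarray(roi_mask, dtype=bool)
    good = roi & (sd > 0)
    n_zero = int(roi.sum() - good.sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero-SD pixels excluded from SNR ROI",
                      stacklevel=2)
    if not good.any():
        raise ValueError("no pixels with non-zero temporal SD in ROI")
    return float((mean[good] / sd[good]).mean())


def mean_signal_ratio(frames_a: np.ndarray, frames_b: np.ndarray,
                      roi_mask: np.ndarray) -> float:
    """Ratio of mean ROI signal between two series (surrogate for the SNR
    ratio when the noise level is matched)."""
    roi = np.asarray(roi_mask, dtype=bool)
    denom = float(np.asarray(frames_b, dtype=float)[..., roi].mean())
    if denom == 0:
        raise ValueError("zero denominator in mean signal ratio")
    return float(np.asarray(frames_a, dtype=float)[..., roi].mean()) / denom


def summarize_lv(maps: ScalarMaps, mask: np.ndarray,
                 exclusion: np.ndarray | None = None, **extra) -> dict:
    """Global LV summary: means of MD / FA / mode (and any angle maps), the
    *median* for E2A (which is not expected to be normally distributed), plus
    caller-supplied quality statistics.

    ``exclusion`` removes papillary muscle / RV-septum pixels from every
    statistic. Raises if the post-exclusion mask is empty.
    """
    m = mask & maps.valid
    if exclusion is not None:
        m = m & ~exclusion
    if not m.any():
        raise ValueError("empty post-exclusion mask")

    def _mean(a):
        v = a[m]
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else np.nan

    e2a_vals = maps.e2a[m]
    e2a_vals = e2a_vals[np.isfinite(e2a_vals)]
    row = {
        "md": _mean(maps.md),
        "fa": _mean(maps.fa),
        "mode": _mean(maps.mode),
        "e2a_median": float(np.median(e2a_vals)) if e2a_vals.size else np.nan,
        "e2a_mean": float(e2a_vals.mean()) if e2a_vals.size else np.nan,
    }
    row.update(extra)
    return row
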