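"""Myocardial strain from displacement fields and the group statistics:
paired Wilcoxon between sequences, Friedman across cardiac phases with
Bonferroni-corrected pairwise tests, Pearson correlations of DT-CMR
parameter differences with peak strain, and the Spearman score-vs-RR check.

Strain is 2D Green-Lagrange by default, projected onto the end-diastolic
(reference) radial and circumferential directions and averaged over the
myocardium; engineering (infinitesimal) strain is available behind a flag.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CardiacCoordinateField,
    ComparisonResult,
    DisplacementSeries,
    StrainCurve,
)

__all__ = [
    "strain_from_displacements",
    "compare_sequences",
    "compare_phases",
    "correlate_with_strain",
    "correlate_score_rr",
]


def strain_from_displacements(disp: DisplacementSeries,
                              coords: CardiacCoordinateField,
                              mask: np.ndarray | None = None,
                              measure: str = "green") -> StrainCurve:
    """Global radial/circumferential strain curves from a displacement-field
    series.

    Per frame, the displacement gradient gives F = I + grad(u); the
    Green-Lagrange tensor E = (F^T F - I)/2 (or the symmetrized gradient for
    ``measure="engineering"``) is projected onto the reference radial and
    circumferential directions and averaged over the myocardium.
    """
    if measure not in ("green", "engineering"):
        raise ValueError(f"unknown strain measure {measure!r}")
    mask = coords.valid if mask is None else mask
    if disp.disp.shape[1:3] != mask.shape:
        raise ValueError("displacement grid does not match coordinate field")
    h = disp.pixel_spacing_mm
    r2 = coords.radial[..., :2]
    c2 = coords.circumferential[..., :2]

    nt = disp.n_frames
    radial = np.zeros(nt)
    circ = np.zeros(nt)
    for k in range(nt):
        ux = disp.disp[k, ..., 0]
        uy = disp.disp[k, ..., 1]
        dux_dy, dux_dx = np.gradient(ux, h)
        duy_dy, duy_dx = np.gradient(uy, h)
        grad = np.empty(ux.shape + (2, 2))
        grad[..., 0, 0] = dux_dx
        grad[..., 0, 1] = dux_dy
        grad[..., 1, 0] = duy_dx
        grad[..., 1, 1] = duy_dy
        if measure == "green":
            F = grad.copy()
            F[..., 0, 0] += 1.0
            F[..., 1, 1] += 1.0
            detF = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
            n_bad = int((detF[mask] <= 0).sum())
            if n_bad > 0.01 * int(mask.sum()):
                raise ValueError(
                    f"non-invertible deformation gradient at {n_bad} pixels")
            E = 0.5 * (np.einsum("...ki,...kj->...ij", F, F)
                       - np.eye(2))
        else:
            E = 0.5 * (grad + np.swapaxes(grad, -1, -2))
        err = np.einsum("...i,...ij,...j->...", r2, E, r2)
        ecc = np.einsum("...i,...ij,...j->...", c2, E, c2)
        radial[k] = float(err[mask].mean())
        circ[k] = float(ecc[mask].mean())
    time_ms = np.arange(nt) * disp.dt_ms
    return StrainCurve(time_ms=time_ms, radial=radial, circumferential=circ)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def _paired(table: pd.DataFrame, metric: str, by: str, levels: tuple,
            at: dict) -> pd.DataFrame:
    sub = table
    for col, val in at.items():
        sub = sub[sub[col] == val]
    wide = sub.pivot_table(index="subject", columns=by, values=metric,
                           aggfunc="first")
    missing = [l for l in levels if l not in wide.columns]
    if missing:
        raise ValueError(f"no rows for {by}={missing}")
    wide = wide[list(levels)]
    n_before = len(wide)
    wide = wide.dropna()
    if len(wide) < n_before:
        warnings.warn(f"{n_before - len(wide)} subjects dropped "
                      f"(incomplete {by} data)", stacklevel=3)
    return wide


def _wilcoxon(x: np.ndarray, y: np.ndarray):
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(x, y, zero_method="wilcox",
                         method="exact" if len(d) <= 25 else "approx")
    return float(res.statistic), float(res.pvalue)


def compare_sequences(table: pd.DataFrame, metric: str, phase: str,
                      sequences: tuple[str, str] = ("STEAM", "M2SE"),
                      alpha: float = 0.05) -> ComparisonResult:
    """Paired Wilcoxon signed-rank test between the two sequences at one
    cardiac phase. ``table`` needs columns subject/sequence/phase/<metric>."""
    wide = _paired(table, metric, "sequence", sequences, {"phase": phase})
    if len(wide) < 2:
        raise ValueError("fewer than 2 complete subject pairs")
    stat, p = _wilcoxon(wide[sequences[0]].values, wide[sequences[1]].values)
    return ComparisonResult(test=f"wilcoxon[{metric}@{phase}]", n=len(wide),
                            statistic=stat, p_value=p, alpha=alpha)


def compare_phases(table: pd.DataFrame, metric: str, sequence: str,
                   phases: tuple[str, str, str] = ("systole", "sweet_spot",
                                                   "diastole"),
                   alpha: float = 0.05) -> list[ComparisonResult]:
    """Friedman test of the metric across cardiac phases for one sequence;
    when significant, Bonferroni-corrected pairwise Wilcoxon tests follow
    (alpha / 3 for the three phase pairs)."""
    wide = _paired(table, metric, "phase", phases, {"sequence": sequence})
    if len(wide) < 3:
        raise ValueError("fewer than 3 complete subjects for Friedman test")
    cols = [wide[p].values for p in phases]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        fried = ComparisonResult(test=f"friedman[{metric}:{sequence}]",
                                 n=len(wide), statistic=0.0, p_value=1.0,
                                 alpha=alpha)
    else:
        st, p = stats.friedmanchisquare(*cols)
        fried = ComparisonResult(test=f"friedman[{metric}:{sequence}]",
                                 n=len(wide), statistic=float(st),
                                 p_value=float(p), alpha=alpha)
    out = [fried]
    if fried.significant:
        alpha_bonf = alpha / len(list(combinations(phases, 2)))
        for pa, pb in combinations(phases, 2):
            st, p = _wilcoxon(wide[pa].values, wide[pb].values)
            out.append(ComparisonResult(
                test=f"wilcoxon[{metric}:{sequence}:{pa}-{pb}]",
                n=len(wide), statistic=st, p_value=p, alpha=alpha_bonf))
    return out


def correlate_with_strain(metric_difference: np.ndarray,
                          peak_strain: np.ndarray,
                          label: str = "", alpha: float = 0.05) -> ComparisonResult:
    """Pearson correlation of a per-subject DT-CMR metric difference
    (systole - diastole, or STEAM - M2SE at a phase) with peak strain, with
    the regression line and non-simultaneous 95% confidence-band parameters
    for reporting."""
    x = np.asarray(peak_strain, dtype=float)
    y = np.asarray(metric_difference, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >=3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    n = len(x)
    resid = y - (reg.slope * x + reg.intercept)
    s = np.sqrt((resid ** 2).sum() / (n - 2)) if n > 2 else np.nan
    sxx = ((x - x.mean()) ** 2).sum()
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    return ComparisonResult(
        test=f"pearson[{label}]", n=n, statistic=float(r), p_value=float(p),
        alpha=alpha, coefficient=float(r), slope=float(reg.slope),
        intercept=float(reg.intercept),
        extra={"band_s": float(s), "band_sxx": float(sxx),
               "band_tcrit": float(tcrit), "x_mean": float(x.mean())})


def correlate_score_rr(scores: np.ndarray, rr_ms: np.ndarray,
                       alpha: float = 0.05) -> ComparisonResult:
    """Spearman rank correlation between HA-map quality scores and the mean
    RR interval (midrank convention for ties)."""
    s = np.asarray(scores, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if len(s) < 5:
        raise ValueError("need >=5 paired observations")
    if np.all(s == s[0]):
        raise ValueError("constant scores: Spearman undefined")
    rho, p = stats.spearmanr(s, rr)
    return ComparisonResult(test="spearman[score~rr]", n=len(s),
                            statistic=float(rho), p_value=float(p),
                            alpha=alpha, coefficient=float(rho))
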