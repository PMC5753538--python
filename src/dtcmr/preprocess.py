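"""Preprocessing of diffusion-weighted frames and the linear least-squares
tensor fit.

Order of operations mirrors the in-vivo processing chain: hyperintense blood
pixels are nulled, frames are rigidly registered by translation to the series
median image, the original blood intensities are restored, motion-corrupted
frames are rejected against the per-condition median, the STEAM b-values are
corrected for the encoding-beat RR interval, and the tensor is fitted
pixelwise by ordinary least squares of log-signal on the b-matrix, each frame
entering separately (no averaging).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import STEAM, DiffusionImageSeries, TensorField
from .phantom import steam_b_scale

__all__ = [
    "bmatrix_row",
    "null_blood_pixels",
    "restore_blood_pixels",
    "register_frames",
    "reject_frames",
    "correct_b_values",
    "fit_tensor_lls",
]


def bmatrix_row(b: float, g: np.ndarray) -> np.ndarray:
    """Expand (b, g) into the 6-vector multiplying the unique tensor elements
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz): (b gx^2, b gy^2, b gz^2, 2b gx gy,
    2b gx gz, 2b gy gz). The trace of the implied matrix equals b."""
    gx, gy, gz = np.asarray(g, dtype=float)
    return np.array([b * gx * gx, b * gy * gy, b * gz * gz,
                     2 * b * gx * gy, 2 * b * gx * gz, 2 * b * gy * gz])


# ---------------------------------------------------------------------------
# Blood nulling
# ---------------------------------------------------------------------------

def null_blood_pixels(series: DiffusionImageSeries,
                      threshold_factor: float = 2.0):
    """Zero pixels brighter than ``threshold_factor`` times the per-frame
    median myocardial intensity; return the modified series and a restore
    ledger of (frame, row, col, value) for exact restoration after
    registration."""
    myo = series.myocardium
    if not myo.any():
        raise ValueError("empty myocardial mask")
    out = series.copy()
    ledger: list[tuple[int, int, int, float]] = []
    for i in range(series.n_frames):
        med = float(np.median(series.frames[i][myo]))
        hot = series.frames[i] > threshold_factor * med
        for r, c in zip(*np.nonzero(hot)):
            ledger.append((i, int(r), int(c), float(series.frames[i, r, c])))
        out.frames[i][hot] = 0.0
    return out, ledger


def restore_blood_pixels(series: DiffusionImageSeries, ledger,
                         shifts: np.ndarray | None = None) -> DiffusionImageSeries:
    """Return the original nulled intensities after registration.

    ``shifts`` are the per-frame (dx, dy) corrections applied by
    :func:`register_frames`; the restored location follows the frame's
    translation (rounded to the nearest pixel, wrapping like the registration
    itself so integer round trips are exact)."""
    out = series.copy()
    ny, nx = series.shape
    for (i, r, c, v) in ledger:
        if shifts is None:
            rr, cc = r, c
        else:
            dx, dy = shifts[i]
            rr = int(round(r + dy)) % ny
            cc = int(round(c + dx)) % nx
        out.frames[i, rr, cc] = v
    return out


# ---------------------------------------------------------------------------
# Rigid-translation registration
# ---------------------------------------------------------------------------

def _translate(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    if float(dx).is_integer() and float(dy).is_integer():
        return np.roll(img, (int(dy), int(dx)), axis=(0, 1))
    return ndimage.shift(img, (dy, dx), order=1, mode="grid-wrap")


def _xcorr_shift(frame: np.ndarray, ref: np.ndarray, max_shift: int,
                 subpixel: bool) -> tuple[float, float]:
    """Translation (dx, dy) maximizing the normalized cross-correlation of
    ``frame`` with ``ref``, integer search within +/- max_shift followed by
    parabolic subpixel refinement of the correlation peak."""
    a = frame - frame.mean()
    b = ref - ref.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("all-zero frame in registration")
    corr = np.fft.irfft2(np.fft.rfft2(b) * np.conj(np.fft.rfft2(a)),
                         s=frame.shape) / (na * nb)
    corr = np.fft.fftshift(corr)
    cy, cx = np.array(corr.shape) // 2
    win = corr[cy - max_shift: cy + max_shift + 1,
               cx - max_shift: cx + max_shift + 1]
    iy, ix = np.unravel_index(np.argmax(win), win.shape)
    dy = iy - max_shift
    dx = ix - max_shift

    def parab(cm, c0, cp):
        denom = cm - 2 * c0 + cp
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))

    fy = fx = 0.0
    if subpixel and 0 < iy < win.shape[0] - 1:
        fy = parab(win[iy - 1, ix], win[iy, ix], win[iy + 1, ix])
    if subpixel and 0 < ix < win.shape[1] - 1:
        fx = parab(win[iy, ix - 1], win[iy, ix], win[iy, ix + 1])
    return dx + fx, dy + fy


def register_frames(series: DiffusionImageSeries, max_shift: int = 10,
                    subpixel: bool = True, min_shift: float = 0.1):
    """Rigid-translation registration of every frame to the series median
    image. Returns the registered series and the applied (dx, dy) per frame.

    Subpixel estimates below ``min_shift`` pixels (per component) are treated
    as refinement noise and snapped to zero, so already-aligned frames are
    left untouched rather than resampled.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to register")
    ref = np.median(series.frames, axis=0)
    out = series.copy()
    shifts = np.zeros((series.n_frames, 2))
    for i in range(series.n_frames):
        dx, dy = _xcorr_shift(series.frames[i], ref, max_shift, subpixel)
        if abs(dx) < min_shift:
            dx = 0.0
        if abs(dy) < min_shift:
            dy = 0.0
        shifts[i] = (dx, dy)
        if dx != 0.0 or dy != 0.0:
            out.frames[i] = _translate(series.frames[i], dx, dy)
    out.provenance = dict(out.provenance, registration_shifts=shifts)
    return out, shifts


# ---------------------------------------------------------------------------
# Frame rejection
# ---------------------------------------------------------------------------

def _condition_groups(series: DiffusionImageSeries):
    keys = {}
    for i in range(series.n_frames):
        key = (round(float(series.bvals[i]), 6),
               tuple(np.round(series.bvecs[i], 6)))
        keys.setdefault(key, []).append(i)
    return keys


def reject_frames(series: DiffusionImageSeries, min_correlation: float = 0.80,
                  min_frames: int = 7):
    """Drop frames whose correlation with the per-(b, direction) median image
    falls below ``min_correlation`` (automated surrogate for visual motion
    assessment). Singleton conditions cannot be assessed and are kept."""
    rejected = []
    for key, idx in _condition_groups(series).items():
        if len(idx) < 2:
            continue
        med = np.median(series.frames[idx], axis=0)
        mflat = med.ravel() - med.mean()
        nm = np.linalg.norm(mflat)
        for i in idx:
            f = series.frames[i].ravel() - series.frames[i].mean()
            nf = np.linalg.norm(f)
            rho = 0.0 if nf == 0 or nm == 0 else float(f @ mflat / (nf * nm))
            if rho < min_correlation:
                rejected.append(i)
    keep = np.setdiff1d(np.arange(series.n_frames), rejected)
    if keep.size < min_frames:
        raise ValueError(
            f"rejection leaves {keep.size} frames (<{min_frames}): rank-deficient fit")
    out = series.subset(keep)
    out.provenance = dict(out.provenance, rejected_frames=sorted(int(i) for i in rejected))
    return out, sorted(int(i) for i in rejected)


# ---------------------------------------------------------------------------
# Beat-to-beat b-value correction
# ---------------------------------------------------------------------------

def correct_b_values(series: DiffusionImageSeries, nominal_rr_ms: float,
                     delta_ms: float = 2.4) -> DiffusionImageSeries:
    """Rescale each STEAM frame's b-value for its encoding-beat RR interval:
    b' = b (RR - delta/3) / (RR_nominal - delta/3). Non-STEAM series pass
    through unchanged."""
    out = series.copy()
    if series.tag != STEAM:
        return out
    if np.any(series.rr_ms <= delta_ms / 3.0):
        raise ValueError("RR interval <= delta/3: b-correction undefined")
    out.bvals = series.bvals * np.asarray(
        steam_b_scale(series.rr_ms, nominal_rr_ms, delta_ms))
    return out


# ---------------------------------------------------------------------------
# Linear least-squares tensor fit
# ---------------------------------------------------------------------------

_TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def fit_tensor_lls(series: DiffusionImageSeries,
                   mask: np.ndarray | None = None) -> TensorField:
    """Pixelwise ordinary least squares of ln(signal) on [1, -b-matrix row].

    Every frame enters separately (no averaging). Pixels with any
    non-positive signal inside the mask are flagged invalid rather than
    log-clipped.
    """
    mask = series.myocardium if mask is None else mask
    if not mask.any():
        raise ValueError("empty mask")
    n = series.n_frames
    X = np.empty((n, 7))
    X[:, 0] = 1.0
    for i in range(n):
        X[i, 1:] = -bmatrix_row(series.bvals[i], series.bvecs[i])
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design matrix "
                         "(need >=7 frames over >=6 non-coplanar directions)")

    ny, nx = series.shape
    sig = series.frames[:, mask]                       # (n, npix)
    positive = np.all(sig > 0, axis=0)
    Y = np.where(sig > 0, sig, 1.0)
    beta, *_ = np.linalg.lstsq(X, np.log(Y), rcond=None)   # (7, npix)
    resid = np.log(Y) - X @ beta
    rms = np.sqrt(np.mean(resid ** 2, axis=0))

    tensors = np.full((ny, nx, 3, 3), np.nan)
    log_s0 = np.full((ny, nx), np.nan)
    residual = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)

    Dflat = np.zeros((sig.shape[1], 3, 3))
    for k, (i, j) in enumerate(_TENSOR_IDX):
        Dflat[:, i, j] = beta[1 + k]
        Dflat[:, j, i] = beta[1 + k]

    tensors[mask] = Dflat
    log_s0[mask] = beta[0]
    residual[mask] = rms
    vm = np.zeros(sig.shape[1], dtype=bool)
    vm[positive] = True
    valid[mask] = vm
    tensors[mask & ~valid] = np.nan

    return TensorField(tensors=tensors, log_s0=log_s0, residual_rms=residual,
                       valid=valid)
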