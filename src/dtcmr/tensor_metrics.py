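"""Eigen-decomposition of the fitted tensors and the cardiac-coordinate
scalar maps: mean diffusivity, fractional anisotropy, tensor mode, helix
angle, transverse angle and the absolute second-eigenvector angle (E2A).

Angle conventions
-----------------
All angles treat eigenvectors as axial quantities (sign-invariant) and are
folded to (-90, 90] degrees (HA, TA) or [0, 90] (E2A).

* HA: signed angle between the local circumferential direction and the
  projection of the primary eigenvector onto the wall-tangent
  (circumferential-longitudinal) plane, positive toward the longitudinal
  direction.
* TA: signed angle between the circumferential direction and the projection
  of the primary eigenvector onto the short-axis (circumferential-radial)
  plane.
* E2A: absolute elevation of the secondary eigenvector out of the wall
  plane, measured in the cross-myocyte plane (spanned by the radial
  direction and the in-wall direction perpendicular to the projected primary
  eigenvector).  An alternative construction measuring the elevation in the
  plane orthogonal to the full (unprojected) primary eigenvector is
  available via ``plane="e1-orthogonal"``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .containers import (
    CardiacCoordinateField,
    EigenField,
    ScalarMaps,
    TensorField,
)

__all__ = [
    "eig_decompose",
    "scalar_invariants",
    "build_cardiac_coordinates",
    "helix_transverse_angles",
    "e2a_map",
    "compute_scalar_maps",
]

_EPS = 1e-8


def eig_decompose(tf: TensorField) -> EigenField:
    """Eigen-decompose every valid tensor, eigenvalues descending.

    Negative eigenvalues are retained (the linear fit may produce them at
    noisy pixels) but the pixel is flagged in ``nonpositive``.
    """
    ny, nx = tf.valid.shape
    evals = np.full((ny, nx, 3), np.nan)
    evecs = np.full((ny, nx, 3, 3), np.nan)
    D = tf.tensors[tf.valid]
    if D.size and not np.all(np.isfinite(D)):
        raise ValueError("non-finite tensor entries at valid pixels")
    if D.size:
        w, v = np.linalg.eigh(D)               # ascending
        w = w[:, ::-1]
        v = v[:, :, ::-1]                      # columns are eigenvectors
        evals[tf.valid] = w
        evecs[tf.valid] = np.swapaxes(v, -1, -2)   # [..., i, :] = e_(i+1)
    nonpos = np.zeros((ny, nx), dtype=bool)
    nonpos[tf.valid] = (evals[tf.valid] <= 0).any(axis=-1)
    return EigenField(eigenvalues=evals, eigenvectors=evecs,
                      valid=tf.valid.copy(), nonpositive=nonpos)


def scalar_invariants(eigen: EigenField):
    """MD, FA and tensor mode maps from the eigenvalues.

    MD = (l1+l2+l3)/3; FA = sqrt(3/2) ||l - MD|| / ||l||;
    mode = 3 sqrt(6) det(dev / ||dev||) with dev the deviatoric eigenvalues.
    Isotropic pixels get FA = 0 and mode = 0 by convention.
    """
    lam = eigen.eigenvalues
    md = lam.mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = lam - md[..., None]
        dev_norm = np.sqrt((dev ** 2).sum(axis=-1))
        lam_norm = np.sqrt((lam ** 2).sum(axis=-1))
        fa = np.sqrt(1.5) * dev_norm / lam_norm
        fa = np.where(dev_norm < _EPS * np.maximum(lam_norm, _EPS), 0.0, fa)
        mode = 3.0 * np.sqrt(6.0) * np.prod(
            dev / np.maximum(dev_norm, 1e-300)[..., None], axis=-1)
        mode = np.where(dev_norm < _EPS * np.maximum(lam_norm, _EPS), 0.0, mode)
    invalid = ~eigen.valid
    for m in (md, fa, mode):
        m[invalid] = np.nan
    return md, fa, mode


# ---------------------------------------------------------------------------
# Cardiac coordinates from contours
# ---------------------------------------------------------------------------

def _resample_closed(poly: np.ndarray, n: int = 4000) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate contour")
    t = np.linspace(0.0, s[-1], n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def build_cardiac_coordinates(mask: np.ndarray, epi_contour: np.ndarray,
                              endo_contour: np.ndarray,
                              smooth_sigma_px: float = 0.0) -> CardiacCoordinateField:
    """Cardiac coordinate triad and transmural depth from closed contours.

    Contours are (N, 2) arrays of (x, y) pixel coordinates. Depth is the
    normalized distance between the contours (0 on the epicardial contour,
    1 on the endocardial contour). The radial direction is the local wall
    normal, estimated from the gradient of the depth field (signed-distance
    construction), falling back to centroid rays where the gradient is
    degenerate; circumferential = longitudinal x radial.
    """
    from skimage.measure import points_in_poly

    ny, nx = mask.shape
    epi_pts = _resample_closed(epi_contour)
    endo_pts = _resample_closed(endo_contour)
    gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    pix = np.column_stack([gx.ravel(), gy.ravel()])
    # signed distances, positive inside each contour, so the normalized depth
    # s_epi / (s_epi - s_endo) is smooth across both contours (0 on epi,
    # 1 on endo) and its gradient is the transmural direction everywhere
    s_epi = cKDTree(epi_pts).query(pix)[0]
    s_epi *= np.where(points_in_poly(pix, epi_pts), 1.0, -1.0)
    s_endo = cKDTree(endo_pts).query(pix)[0]
    s_endo *= np.where(points_in_poly(pix, endo_pts), 1.0, -1.0)
    denom = (s_epi - s_endo).reshape(ny, nx)
    if np.any(denom <= 0):
        raise ValueError("contours intersect or are nested the wrong way")
    depth_full = s_epi.reshape(ny, nx) / denom

    if smooth_sigma_px > 0:
        depth_s = ndimage.gaussian_filter(depth_full, smooth_sigma_px)
    else:
        depth_s = depth_full
    ddy, ddx = np.gradient(depth_s)
    # depth increases inward (toward endocardium): outward radial = -grad
    rx, ry = -ddx, -ddy
    norm = np.hypot(rx, ry)

    cx, cy = endo_pts.mean(axis=0)
    fx, fy = gx - cx, gy - cy
    fnorm = np.maximum(np.hypot(fx, fy), 1e-12)
    degen = norm < _EPS
    rx = np.where(degen, fx / fnorm, rx / np.maximum(norm, _EPS))
    ry = np.where(degen, fy / fnorm, ry / np.maximum(norm, _EPS))
    # orient consistently outward (away from the cavity centroid)
    flip = (rx * fx + ry * fy) < 0
    rx = np.where(flip, -rx, rx)
    ry = np.where(flip, -ry, ry)

    radial = np.stack([rx, ry, np.zeros_like(rx)], axis=-1)
    longitudinal = np.zeros_like(radial)
    longitudinal[..., 2] = 1.0
    circumferential = np.cross(longitudinal, radial)

    depth = np.where(mask, depth_full, np.nan)
    return CardiacCoordinateField(radial=radial,
                                  circumferential=circumferential,
                                  longitudinal=longitudinal,
                                  depth=depth, valid=mask.copy())


# ---------------------------------------------------------------------------
# Angle maps
# ---------------------------------------------------------------------------

def _fold_deg(a: np.ndarray) -> np.ndarray:
    """Fold a signed angle (deg) into (-90, 90] for axial quantities."""
    a = np.where(a > 90.0, a - 180.0, a)
    a = np.where(a <= -90.0, a + 180.0, a)
    return a


def helix_transverse_angles(eigen: EigenField, coords: CardiacCoordinateField):
    """Helix and transverse angle maps (degrees) from the primary eigenvector.

    Pixels where the relevant projection is degenerate (primary eigenvector
    along the radial, resp. longitudinal, direction) are NaN-flagged.
    """
    e1 = eigen.eigenvectors[..., 0, :]
    c = np.einsum("...i,...i->...", e1, coords.circumferential)
    l = np.einsum("...i,...i->...", e1, coords.longitudinal)
    r = np.einsum("...i,...i->...", e1, coords.radial)

    with np.errstate(invalid="ignore"):
        ha = _fold_deg(np.degrees(np.arctan2(l, c)))
        ta = _fold_deg(np.degrees(np.arctan2(r, c)))
    ha = np.where(np.hypot(c, l) < _EPS, np.nan, ha)
    ta = np.where(np.hypot(c, r) < _EPS, np.nan, ta)
    bad = ~eigen.valid | eigen.nonpositive
    ha = np.where(bad, np.nan, ha)
    ta = np.where(bad, np.nan, ta)
    return ha, ta


def e2a_map(eigen: EigenField, coords: CardiacCoordinateField,
            plane: str = "cross-myocyte") -> np.ndarray:
    """Absolute second-eigenvector angle map (degrees, [0, 90]).

    ``plane="cross-myocyte"`` (default): elevation of e2 measured in the
    plane spanned by the radial direction and the in-wall axis perpendicular
    to the *projected* primary eigenvector. ``plane="e1-orthogonal"``:
    the in-wall axis is taken perpendicular to the full primary eigenvector.
    """
    if plane not in ("cross-myocyte", "e1-orthogonal"):
        raise ValueError(f"unknown E2A plane {plane!r}")
    e1 = eigen.eigenvectors[..., 0, :]
    e2 = eigen.eigenvectors[..., 1, :]
    rad = coords.radial

    if plane == "cross-myocyte":
        c = np.einsum("...i,...i->...", e1, coords.circumferential)
        l = np.einsum("...i,...i->...", e1, coords.longitudinal)
        nrm = np.maximum(np.hypot(c, l), 1e-300)
        e1t = (c[..., None] * coords.circumferential
               + l[..., None] * coords.longitudinal) / nrm[..., None]
        degen_axis = np.hypot(c, l) < _EPS
    else:
        e1t = e1
        degen_axis = np.zeros(e1.shape[:-1], dtype=bool)
    sheet_axis = np.cross(rad, e1t)
    sheet_axis = sheet_axis / np.maximum(
        np.linalg.norm(sheet_axis, axis=-1), 1e-300)[..., None]

    a = np.einsum("...i,...i->...", e2, sheet_axis)   # in-wall component
    b = np.einsum("...i,...i->...", e2, rad)          # radial component
    with np.errstate(invalid="ignore"):
        e2a = np.degrees(np.arctan2(np.abs(b), np.abs(a)))
    e2a = np.where(np.hypot(a, b) < _EPS, np.nan, e2a)
    e2a = np.where(degen_axis, np.nan, e2a)
    bad = ~eigen.valid | eigen.nonpositive
    return np.where(bad, np.nan, e2a)


def compute_scalar_maps(tf: TensorField, coords: CardiacCoordinateField,
                        e2a_plane: str = "cross-myocyte") -> ScalarMaps:
    """Convenience wrapper: eigensystem then all scalar maps."""
    eigen = eig_decompose(tf)
    md, fa, mode = scalar_invariants(eigen)
    ha, ta = helix_transverse_angles(eigen, coords)
    e2a = e2a_map(eigen, coords, plane=e2a_plane)
    # FA/mode/angle summaries exclude non-positive-eigenvalue pixels; MD keeps
    # them (clamping would bias MD downward).
    fa = np.where(eigen.nonpositive, np.nan, fa)
    mode = np.where(eigen.nonpositive, np.nan, mode)
    return ScalarMaps(md=md, fa=fa, mode=mode, ha=ha, ta=ta, e2a=e2a,
                      valid=tf.valid & coords.valid)
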