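"""Shared data containers for the DT-CMR pipeline.

Conventions used throughout the package:

* Images are 2D arrays indexed ``[row, col]``; a pixel coordinate ``(x, y)``
  means ``x`` along columns and ``y`` along rows, 0-based and pixel-centred.
* 3D vectors are ``(x, y, z)`` with ``z`` the slice normal (the geometry is a
  single short-axis slice; the longitudinal direction is the slice normal).
* Diffusivities are in mm^2 s^-1, b-values in s mm^-2, times in ms unless
  stated otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LVPhantomSpec",
    "AcquisitionProtocol",
    "DiffusionImageSeries",
    "DisplacementSeries",
    "TensorField",
    "CardiacCoordinateField",
    "EigenField",
    "ScalarMaps",
    "TransmuralProfile",
    "StrainCurve",
    "ComparisonResult",
    "STEAM",
    "M2SE",
]

STEAM = "STEAM"
M2SE = "M2SE"


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass
class LVPhantomSpec:
    """Geometry, microstructure and signal parameters of the synthetic left
    ventricle (one short-axis slice, annular myocardium).

    Helix angle varies linearly across the wall from ``ha_endo_deg`` at the
    endocardium to ``ha_epi_deg`` at the epicardium (right-handed endocardial
    helix: endo > epi).  The sheetlet elevation |E2A| is uniform at
    ``e2a_deg``.  Eigenvalues are uniform over the wall.
    """

    grid_size: int = 64
    pixel_spacing_mm: float = 1.5
    centre: tuple[float, float] = (31.5, 31.5)  # (x, y) pixels
    r_endo_mm: float = 12.0
    r_epi_mm: float = 24.0
    ha_endo_deg: float = 60.0
    ha_epi_deg: float = -60.0
    e2a_deg: float = 60.0
    eigenvalues: tuple[float, float, float] = (1.6e-3, 0.8e-3, 0.5e-3)
    blood_multiplier: float = 3.0
    noise_sigma: float = 0.0
    s0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r_epi_mm > self.r_endo_mm > 0):
            raise ValueError("require epicardial radius > endocardial radius > 0")
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if not self.ha_endo_deg > self.ha_epi_deg:
            raise ValueError("helix angle must decrease endo -> epi")
        if self.grid_size < 8:
            raise ValueError("grid too small")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")

    def replace(self, **kw) -> "LVPhantomSpec":
        return dataclasses.replace(self, **kw)


def _default_directions() -> np.ndarray:
    """Six non-coplanar unit encoding directions (dual-gradient scheme)."""
    g = np.array(
        [
            [1.0, 1.0, 0.0],
            [1.0, -1.0, 0.0],
            [1.0, 0.0, 1.0],
            [1.0, 0.0, -1.0],
            [0.0, 1.0, 1.0],
            [0.0, 1.0, -1.0],
        ]
    )
    return g / np.linalg.norm(g, axis=1, keepdims=True)


@dataclass
class AcquisitionProtocol:
    """Diffusion acquisition protocol for one sequence.

    STEAM encodes across two cardiac cycles (TR = 2 RR, diffusion time ~RR)
    with 8 b_main averages; the motion-compensated spin echo (M2SE) encodes
    within one cycle (TR = 1 RR) with 16 b_main averages.
    """

    tag: str = STEAM
    b_ref: float = 150.0
    b_main: float = 450.0
    directions: np.ndarray = field(default_factory=_default_directions)
    averages_main: int = 8
    averages_ref: int = 1
    tr_rr: int = 2
    rr_nominal_ms: float = 1000.0
    rr_jitter_ms: float = 5.0
    delta_ms: float = 2.4  # STEAM diffusion-gradient duration
    te_ms: float = 25.0

    def __post_init__(self) -> None:
        if self.tag not in (STEAM, M2SE):
            raise ValueError(f"unknown sequence tag {self.tag!r}")
        if not (self.b_main > self.b_ref >= 0):
            raise ValueError("require b_main > b_ref >= 0")
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("gradient directions must be unit vectors")
        if self.tr_rr not in (1, 2):
            raise ValueError("TR must be 1 or 2 RR intervals")

    @classmethod
    def steam(cls, **kw) -> "AcquisitionProtocol":
        return cls(tag=STEAM, averages_main=8, averages_ref=1, tr_rr=2,
                   te_ms=25.0, **kw)

    @classmethod
    def m2se(cls, **kw) -> "AcquisitionProtocol":
        return cls(tag=M2SE, averages_main=16, averages_ref=2, tr_rr=1,
                   te_ms=76.0, **kw)


# ---------------------------------------------------------------------------
# Image series
# ---------------------------------------------------------------------------

@dataclass
class DiffusionImageSeries:
    """A stack of diffusion-weighted magnitude frames with per-frame metadata.

    ``bvals`` holds the *nominal* per-frame b-value; the beat-to-beat
    correction rewrites it from the recorded RR interval of the encoding beat.
    """

    frames: np.ndarray            # (nframes, ny, nx) magnitude
    bvals: np.ndarray             # (nframes,) s mm^-2
    bvecs: np.ndarray             # (nframes, 3) unit direction
    rr_ms: np.ndarray             # (nframes,) RR of the encoding beat
    tag: str                      # STEAM | M2SE
    myocardium: np.ndarray        # (ny, nx) bool
    blood_pool: Optional[np.ndarray] = None   # (ny, nx) bool
    exclusion: Optional[np.ndarray] = None    # papillary / RV-septum mask
    corrupted: Optional[np.ndarray] = None    # (nframes,) bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        n = self.frames.shape[0]
        if self.frames.ndim != 3:
            raise ValueError("frames must be (nframes, ny, nx)")
        for name in ("bvals", "bvecs", "rr_ms"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"per-frame metadata {name} length != frame count")
        if self.myocardium.shape != self.frames.shape[1:]:
            raise ValueError("mask grid does not match frames")
        if self.corrupted is None:
            self.corrupted = np.zeros(n, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])  # type: ignore[return-value]

    def copy(self) -> "DiffusionImageSeries":
        return DiffusionImageSeries(
            frames=self.frames.copy(),
            bvals=self.bvals.copy(),
            bvecs=self.bvecs.copy(),
            rr_ms=self.rr_ms.copy(),
            tag=self.tag,
            myocardium=self.myocardium.copy(),
            blood_pool=None if self.blood_pool is None else self.blood_pool.copy(),
            exclusion=None if self.exclusion is None else self.exclusion.copy(),
            corrupted=None if self.corrupted is None else self.corrupted.copy(),
            provenance=dict(self.provenance),
        )

    def subset(self, keep: np.ndarray) -> "DiffusionImageSeries":
        keep = np.asarray(keep)
        out = self.copy()
        out.frames = self.frames[keep]
        out.bvals = self.bvals[keep]
        out.bvecs = self.bvecs[keep]
        out.rr_ms = self.rr_ms[keep]
        out.corrupted = self.corrupted[keep]
        return out


@dataclass
class DisplacementSeries:
    """Per-timeframe 2D displacement vector fields (mm) on the image grid.

    ``disp[t, :, :, k]`` is the displacement component (k=0: x, k=1: y) of the
    tissue that occupied the pixel at the reference timeframe (t=0), which is
    zero by construction.
    """

    disp: np.ndarray           # (nt, ny, nx, 2) mm
    dt_ms: float
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 2:
            raise ValueError("disp must be (nt, ny, nx, 2)")
        if not np.allclose(self.disp[0], 0.0):
            raise ValueError("displacement must be zero at the reference timeframe")

    @property
    def n_frames(self) -> int:
        return int(self.disp.shape[0])


# ---------------------------------------------------------------------------
# Tensor and coordinate fields
# ---------------------------------------------------------------------------

@dataclass
class TensorField:
    """Per-pixel symmetric diffusion tensors with fit diagnostics."""

    tensors: np.ndarray          # (ny, nx, 3, 3) mm^2 s^-1, NaN outside mask
    log_s0: np.ndarray           # (ny, nx)
    residual_rms: np.ndarray     # (ny, nx)
    valid: np.ndarray            # (ny, nx) bool

    def __post_init__(self) -> None:
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must be (ny, nx, 3, 3)")


@dataclass
class CardiacCoordinateField:
    """Per-pixel orthonormal cardiac triad and transmural depth.

    ``depth`` runs 0 at the epicardium to 1 at the endocardium.
    ``circumferential`` is counter-clockwise in image axes;
    ``longitudinal`` is the slice normal.
    """

    radial: np.ndarray            # (ny, nx, 3) outward unit vector
    circumferential: np.ndarray   # (ny, nx, 3)
    longitudinal: np.ndarray      # (ny, nx, 3)
    depth: np.ndarray             # (ny, nx), NaN outside annulus
    valid: np.ndarray             # (ny, nx) bool


@dataclass
class EigenField:
    """Eigen-decomposition of a tensor field (descending eigenvalues)."""

    eigenvalues: np.ndarray       # (ny, nx, 3) descending
    eigenvectors: np.ndarray      # (ny, nx, 3, 3); [..., i, :] is e_(i+1)
    valid: np.ndarray             # (ny, nx) bool
    nonpositive: np.ndarray       # (ny, nx) bool: any eigenvalue <= 0


@dataclass
class ScalarMaps:
    """Pixelwise microstructure maps. Flagged/undefined pixels are NaN."""

    md: np.ndarray
    fa: np.ndarray
    mode: np.ndarray
    ha: np.ndarray       # deg, signed, [-90, 90]
    ta: np.ndarray       # deg, signed
    e2a: np.ndarray      # deg, absolute, [0, 90]
    valid: np.ndarray


# ---------------------------------------------------------------------------
# Quality / statistics containers
# ---------------------------------------------------------------------------

@dataclass
class TransmuralProfile:
    """Helix-angle samples along one radial spoke, epicardium to endocardium."""

    spoke: int
    depth_pct: np.ndarray       # strictly increasing, 0 = epi, 100 = endo
    ha_deg: np.ndarray
    slope: float = np.nan       # deg per % wall depth
    intercept: float = np.nan
    r2: float = np.nan
    rmse: float = np.nan

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_pct, dtype=float)
        if d.size >= 2 and not np.all(np.diff(d) > 0):
            raise ValueError("depth must be strictly increasing along a spoke")


@dataclass
class StrainCurve:
    """Global LV strain vs time with extracted peaks."""

    time_ms: np.ndarray
    radial: np.ndarray
    circumferential: np.ndarray

    @property
    def peak_radial(self) -> float:
        return float(np.nanmax(self.radial))

    @property
    def peak_circumferential(self) -> float:
        # signed extreme: most negative (shortening)
        return float(np.nanmin(self.circumferential))


@dataclass
class ComparisonResult:
    """Result of one statistical comparison or correlation."""

    test: str
    n: int
    statistic: float
    p_value: float
    alpha: float = 0.05
    coefficient: float = np.nan       # r / rho where applicable
    slope: float = np.nan
    intercept: float = np.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)
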