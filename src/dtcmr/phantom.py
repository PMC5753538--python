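"""Synthetic left-ventricle phantom: ground-truth tensors, forward-simulated
diffusion-weighted series, motion artifacts and an analytic ring deformation
for strain.

The phantom is a 2D short-axis annulus. Myocyte (primary eigenvector)
orientation follows a linear transmural helix-angle ramp; the secondary
eigenvector is elevated out of the wall-tangent plane by a prescribed |E2A|,
emulating sheetlet tilt. The forward signal model is the monoexponential
tensor model S = S0 exp(-b g^T D g) with Rician magnitude noise; for STEAM
frames the *true* diffusion weighting tracks the drawn RR interval through
the Stejskal-Tanner dependence b = gamma^2 G^2 delta^2 (Delta - delta/3) with
Delta = RR.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .containers import (
    M2SE,
    STEAM,
    AcquisitionProtocol,
    CardiacCoordinateField,
    DiffusionImageSeries,
    DisplacementSeries,
    LVPhantomSpec,
    TensorField,
)

__all__ = [
    "PhantomGroundTruth",
    "build_tensor_field",
    "simulate_dwis",
    "inject_artifacts",
    "simulate_displacements",
    "steam_b_scale",
]


def _grid_mm(spec: LVPhantomSpec):
    n = spec.grid_size
    xs = (np.arange(n) - spec.centre[0]) * spec.pixel_spacing_mm
    ys = (np.arange(n) - spec.centre[1]) * spec.pixel_spacing_mm
    x, y = np.meshgrid(xs, ys)   # x varies along columns, y along rows
    return x, y


class PhantomGroundTruth:
    """Bundle of everything the generator knows about one phantom phase."""

    def __init__(self, spec: LVPhantomSpec, tensors: TensorField,
                 coords: CardiacCoordinateField, myocardium: np.ndarray,
                 blood_pool: np.ndarray, ha_deg: np.ndarray,
                 e2a_deg: np.ndarray):
        self.spec = spec
        self.tensors = tensors
        self.coords = coords
        self.myocardium = myocardium
        self.blood_pool = blood_pool
        self.ha_deg = ha_deg
        self.e2a_deg = e2a_deg


def build_tensor_field(spec: LVPhantomSpec) -> PhantomGroundTruth:
    """Construct the ground-truth tensor and cardiac-coordinate fields.

    At each myocardial pixel the primary eigenvector lies in the wall-tangent
    plane at the helix angle interpolated linearly from endo to epi; the
    secondary eigenvector makes the prescribed |E2A| with the tangent plane.
    Non-myocardial pixels carry no tensor (NaN).
    """
    x, y = _grid_mm(spec)
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    myo = (r >= spec.r_endo_mm) & (r <= spec.r_epi_mm)
    blood = r < spec.r_endo_mm
    if not myo.any():
        raise ValueError("degenerate geometry: no myocardial pixels on grid")

    # transmural depth: 0 at epicardium, 1 at endocardium
    depth = (spec.r_epi_mm - r) / (spec.r_epi_mm - spec.r_endo_mm)
    depth = np.where(myo, depth, np.nan)

    ha = spec.ha_epi_deg + depth * (spec.ha_endo_deg - spec.ha_epi_deg)
    e2a = np.where(myo, float(spec.e2a_deg), np.nan)

    rhat = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
    chat = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
    lhat = np.zeros_like(rhat)
    lhat[..., 2] = 1.0

    ha_r = np.deg2rad(np.where(myo, ha, 0.0))
    e2a_r = np.deg2rad(np.where(myo, e2a, 0.0))
    cos_ha, sin_ha = np.cos(ha_r)[..., None], np.sin(ha_r)[..., None]
    e1 = cos_ha * chat + sin_ha * lhat
    # cross-myocyte in-wall axis: tangent-plane direction perpendicular to e1
    sheet_axis = -sin_ha * chat + cos_ha * lhat
    ce, se = np.cos(e2a_r)[..., None], np.sin(e2a_r)[..., None]
    e2 = ce * sheet_axis + se * rhat
    e3 = np.cross(e1, e2)

    l1, l2, l3 = spec.eigenvalues
    D = (l1 * e1[..., :, None] * e1[..., None, :]
         + l2 * e2[..., :, None] * e2[..., None, :]
         + l3 * e3[..., :, None] * e3[..., None, :])
    D = np.where(myo[..., None, None], D, np.nan)

    tensors = TensorField(
        tensors=D,
        log_s0=np.where(myo, np.log(spec.s0), np.nan),
        residual_rms=np.where(myo, 0.0, np.nan),
        valid=myo.copy(),
    )
    coords = CardiacCoordinateField(
        radial=rhat, circumferential=chat, longitudinal=lhat,
        depth=depth, valid=myo.copy(),
    )
    return PhantomGroundTruth(spec, tensors, coords, myo, blood, ha, e2a)


def steam_b_scale(rr_ms: np.ndarray | float, rr_nominal_ms: float,
                  delta_ms: float) -> np.ndarray | float:
    """Stejskal-Tanner scaling of the STEAM b-value with the encoding-beat RR.

    b = gamma^2 G^2 delta^2 (Delta - delta/3) with Delta = RR, so
    b(RR) / b(RR_nominal) = (RR - delta/3) / (RR_nominal - delta/3).
    """
    denom = rr_nominal_ms - delta_ms / 3.0
    if denom <= 0:
        raise ValueError("nominal RR must exceed delta/3")
    return (np.asarray(rr_ms, dtype=float) - delta_ms / 3.0) / denom


def _draw_rr(rng: np.random.Generator, n: int, protocol: AcquisitionProtocol) -> np.ndarray:
    """Truncated-positive Gaussian RR intervals (truncation at delta/2)."""
    lo = max(protocol.delta_ms / 2.0, 1.0)
    rr = rng.normal(protocol.rr_nominal_ms, protocol.rr_jitter_ms, size=n)
    bad = rr <= lo
    while bad.any():
        rr[bad] = rng.normal(protocol.rr_nominal_ms, protocol.rr_jitter_ms,
                             size=int(bad.sum()))
        bad = rr <= lo
    return rr


def simulate_dwis(truth: PhantomGroundTruth, protocol: AcquisitionProtocol,
                  seed: int) -> DiffusionImageSeries:
    """Forward-simulate one diffusion-weighted series from the phantom.

    One frame per (b-shell, direction, average). The recorded per-frame
    b-value is the nominal one; the STEAM signal is generated with the true
    RR-dependent b so that the beat-to-beat correction stage can recover it
    exactly from the recorded RR. Blood-pool pixels are rendered hyperintense
    (``blood_multiplier`` x S0, emulating incomplete blood nulling) and the
    background is empty. Deterministic under a fixed seed.
    """
    spec = truth.spec
    if spec.noise_sigma < 0 or spec.s0 <= 0:
        raise ValueError("invalid noise/S0")
    rng = np.random.default_rng(seed)

    shells = [(protocol.b_ref, protocol.averages_ref),
              (protocol.b_main, protocol.averages_main)]
    bvals, bvecs = [], []
    for b, n_avg in shells:
        for _ in range(n_avg):
            for g in protocol.directions:
                bvals.append(b)
                bvecs.append(g)
    bvals = np.array(bvals)
    bvecs = np.array(bvecs)
    nframes = len(bvals)
    rr = _draw_rr(rng, nframes, protocol)

    if protocol.tag == STEAM:
        b_true = bvals * steam_b_scale(rr, protocol.rr_nominal_ms,
                                       protocol.delta_ms)
    else:
        b_true = bvals.copy()

    D = np.nan_to_num(truth.tensors.tensors)          # (ny, nx, 3, 3)
    myo = truth.myocardium
    blood = truth.blood_pool
    ny, nx = myo.shape

    frames = np.zeros((nframes, ny, nx))
    # quadratic form g^T D g per pixel, per direction
    for i in range(nframes):
        g = bvecs[i]
        adc = np.einsum("i,...ij,j->...", g, D, g)
        signal = np.where(myo, spec.s0 * np.exp(-b_true[i] * adc), 0.0)
        signal = np.where(blood, spec.blood_multiplier * spec.s0, signal)
        frames[i] = signal

    if spec.noise_sigma > 0:
        n1 = rng.normal(0.0, spec.noise_sigma, size=frames.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, size=frames.shape)
        frames = np.hypot(frames + n1, n2)

    return DiffusionImageSeries(
        frames=frames, bvals=bvals, bvecs=bvecs, rr_ms=rr, tag=protocol.tag,
        myocardium=myo.copy(), blood_pool=blood.copy(),
        provenance={"ground_truth": truth, "seed": int(seed),
                    "b_true": b_true},
    )


def inject_artifacts(series: DiffusionImageSeries, n_shifted: int,
                     shift: tuple[float, float], seed: int,
                     replace_with_noise: bool = False,
                     noise_scale: float = 1.0) -> DiffusionImageSeries:
    """Translate ``n_shifted`` randomly chosen frames by ``shift`` (dx, dy)
    pixels, or replace them with pure noise, recording a corruption ledger.

    The ledger (``provenance['artifacts']``) lists ``(frame, dx, dy)`` so that
    tests can assert exact recovery by the registration / rejection stages.
    """
    if n_shifted >= series.n_frames:
        raise ValueError("cannot corrupt every frame")
    ny, nx = series.shape
    dx, dy = float(shift[0]), float(shift[1])
    if abs(dx) >= nx or abs(dy) >= ny:
        raise ValueError("shift larger than image extent")
    out = series.copy()
    if n_shifted == 0:
        out.provenance.setdefault("artifacts", [])
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(series.n_frames, size=n_shifted, replace=False)
    ledger = []
    for i in sorted(int(j) for j in idx):
        if replace_with_noise:
            scale = noise_scale * max(float(np.abs(series.frames[i]).max()), 1e-12)
            out.frames[i] = rng.uniform(0.0, scale, size=(ny, nx))
            ledger.append((i, None, None))
        else:
            out.frames[i] = _translate(series.frames[i], dx, dy)
            ledger.append((i, dx, dy))
        out.corrupted[i] = True
    out.provenance["artifacts"] = ledger
    return out


def _translate(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Translate an image by (dx, dy) pixels (x = columns), wrapping at the
    edges so that integer shifts are exactly invertible."""
    if float(dx).is_integer() and float(dy).is_integer():
        return np.roll(img, (int(dy), int(dx)), axis=(0, 1))
    return ndimage.shift(img, (dy, dx), order=1, mode="grid-wrap")


# ---------------------------------------------------------------------------
# Analytic ring deformation for strain
# ---------------------------------------------------------------------------

def _ring_map_params(spec: LVPhantomSpec, peak_radial: float,
                     peak_circ: float):
    """Solve the two-parameter ring deformation for the prescribed global-mean
    peak strains.

    Deformed radius: r(R)^2 = a + (R^2 - R_endo^2) / lam, where ``a`` is the
    squared deformed endocardial radius and ``lam`` absorbs through-plane
    stretch (a pure-2D incompressible ring cannot reach arbitrary radial /
    circumferential peak pairs). Green-Lagrange strains of this map:
    E_cc = ((r/R)^2 - 1)/2 and E_rr = ((R/(lam r))^2 ... computed from
    dr/dR = R/(lam r).
    """
    x, y = _grid_mm(spec)
    R = np.hypot(x, y)
    myo = (R >= spec.r_endo_mm) & (R <= spec.r_epi_mm)
    Rm = R[myo]
    R0sq = spec.r_endo_mm ** 2

    def strains(params):
        a, lam = params
        rsq = a + (Rm ** 2 - R0sq) / lam
        if np.any(rsq <= 0) or lam <= 0 or a <= 0:
            return None
        ecc = 0.5 * (rsq / Rm ** 2 - 1.0)
        err = 0.5 * ((Rm ** 2) / (lam ** 2 * rsq) - 1.0)
        return float(err.mean()), float(ecc.mean())

    def residual(params):
        s = strains(params)
        if s is None:
            return [1e3, 1e3]
        return [s[0] - peak_radial, s[1] - peak_circ]

    # incompressible-ish starting point
    a0 = R0sq * (1.0 + 2.0 * peak_circ) if (1.0 + 2.0 * peak_circ) > 0 else R0sq * 0.5
    sol, info, ier, msg = optimize.fsolve(residual, x0=[max(a0, 1.0), 1.0],
                                          full_output=True)
    if ier != 1 or strains(sol) is None or np.max(np.abs(residual(sol))) > 1e-8:
        raise ValueError(
            f"geometrically impossible strain pair ({peak_radial}, {peak_circ}): {msg}")
    return float(sol[0]), float(sol[1])


def simulate_displacements(spec: LVPhantomSpec, peak_radial_strain: float,
                           peak_circumferential_strain: float,
                           n_frames: int = 21,
                           dt_ms: float = 30.0) -> DisplacementSeries:
    """Analytic ring deformation whose wall thickening and circumferential
    shortening reach the prescribed global-mean peaks at mid-series and return
    to zero.

    The displacement inside the cavity continues the wall map with matched
    value and slope at the endocardium (keeping finite differences across the
    wall boundary second-order accurate); far inside it is irrelevant to the
    myocardial strain average.
    """
    if peak_radial_strain <= -1:
        raise ValueError("peak radial strain must exceed -1")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")

    a_p, lam_p = _ring_map_params(spec, peak_radial_strain,
                                  peak_circumferential_strain)
    x, y = _grid_mm(spec)
    R = np.hypot(x, y)
    R0sq = spec.r_endo_mm ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        ux_dir = np.where(R > 0, x / np.maximum(R, 1e-12), 0.0)
        uy_dir = np.where(R > 0, y / np.maximum(R, 1e-12), 0.0)

    t = np.arange(n_frames)
    activation = np.sin(np.pi * t / (n_frames - 1)) ** 2  # 0 -> 1 -> 0

    disp = np.zeros((n_frames, spec.grid_size, spec.grid_size, 2))
    for k, s in enumerate(activation):
        if s == 0:
            continue
        a = R0sq + (a_p - R0sq) * s
        lam = 1.0 + (lam_p - 1.0) * s
        rsq = a + (R ** 2 - R0sq) / lam
        inside = R < spec.r_endo_mm
        r_endo = np.sqrt(a)
        # wall and exterior: analytic map; cavity: C1 linear extension
        r = np.sqrt(np.where(inside, 1.0, np.maximum(rsq, 0.0)) )
        slope_endo = spec.r_endo_mm / (lam * r_endo)
        r_in = r_endo + slope_endo * (R - spec.r_endo_mm)
        u_r = np.where(inside, r_in - R, r - R)
        # taper deep-cavity displacement to zero (away from any wall stencil)
        core = R < 0.5 * spec.r_endo_mm
        taper = np.clip(R / (0.5 * spec.r_endo_mm), 0.0, 1.0)
        u_r = np.where(core, u_r * taper, u_r)
        disp[k, ..., 0] = u_r * ux_dir
        disp[k, ..., 1] = u_r * uy_dir

    return DisplacementSeries(disp=disp, dt_ms=dt_ms,
                              pixel_spacing_mm=spec.pixel_spacing_mm)
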