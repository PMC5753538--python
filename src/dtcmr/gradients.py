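"""Diffusion-encoding gradient waveforms: exact moments, b-values, and the
design of first/second-order motion-compensated (velocity- and
acceleration-nulled) spin-echo encoding under amplitude and slew limits.

Waveforms are piecewise linear in time (ms) with amplitudes in mT/m.
Refocusing-pulse markers flip the *effective* polarity of everything that
follows them; all moments and the b-value are computed on the effective
waveform. With slew in T m^-1 s^-1 the numeric value is identical in
mT m^-1 ms^-1, so no unit conversion is needed for slope checks.

The motion-compensated design uses a short+long trapezoid pair before the
refocusing gap and the time-mirrored pair after it. The effective waveform
is then antisymmetric about the gap centre, which nulls M0 and M2
identically for any lobe durations; the remaining condition M1 = 0 fixes the
long-lobe duration, and the target b-value fixes the short-lobe duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GAMMA_PROTON",
    "GradientWaveform",
    "MomentReport",
    "InfeasibleWaveform",
    "compute_moments",
    "compute_b_value",
    "design_m2_waveform",
    "stejskal_tanner_pair",
    "stejskal_tanner_b",
    "time_reverse",
    "audit_limits",
]

GAMMA_PROTON = 2.675e8  # rad s^-1 T^-1


class InfeasibleWaveform(ValueError):
    """Requested design cannot be met under the hardware limits."""


@dataclass
class GradientWaveform:
    """Piecewise-linear gradient amplitude vs time with refocusing markers."""

    times_ms: np.ndarray            # breakpoints, sorted
    amps_mt_m: np.ndarray           # amplitude at each breakpoint
    refocus_ms: tuple[float, ...] = ()
    gmax_mt_m: float = 43.0
    slew_t_m_s: float = 180.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.amps_mt_m = np.asarray(self.amps_mt_m, dtype=float)
        if self.times_ms.shape != self.amps_mt_m.shape:
            raise ValueError("times and amplitudes must have equal length")
        if np.any(np.diff(self.times_ms) < 0):
            raise ValueError("breakpoints must be time-sorted")

    @property
    def duration_ms(self) -> float:
        return float(self.times_ms[-1] - self.times_ms[0]) if self.times_ms.size else 0.0

    def _effective_segments(self):
        """Yield (t0, t1, g0, g1) of the polarity-corrected waveform, with
        segments split at refocusing markers."""
        t = list(self.times_ms)
        g = list(self.amps_mt_m)
        for rt in self.refocus_ms:
            if t and t[0] < rt < t[-1] and rt not in t:
                i = int(np.searchsorted(t, rt))
                frac = (rt - t[i - 1]) / (t[i] - t[i - 1])
                t.insert(i, rt)
                g.insert(i, g[i - 1] + frac * (g[i] - g[i - 1]))
        segs = []
        for i in range(len(t) - 1):
            if t[i + 1] == t[i]:
                continue
            mid = 0.5 * (t[i] + t[i + 1])
            pol = (-1.0) ** sum(1 for rt in self.refocus_ms if rt <= mid)
            segs.append((t[i], t[i + 1], pol * g[i], pol * g[i + 1]))
        return segs


@dataclass
class MomentReport:
    """Gradient moments of the effective waveform at the end of encoding
    (the echo) and, when requested, the b-value."""

    m0: float          # mT m^-1 ms
    m1: float          # mT m^-1 ms^2
    m2: float          # mT m^-1 ms^3
    b_s_mm2: float = np.nan


def compute_moments(w: GradientWaveform, order: int = 2,
                    origin_ms: float | None = None) -> MomentReport:
    """Closed-form gradient moments M_n = int G_eff(t) (t - origin)^n dt.

    The reference time defaults to the waveform start; once M0 = 0 the first
    moment is origin-independent, and once M0 = M1 = 0 so is M2.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    t_org = float(w.times_ms[0]) if origin_ms is None else float(origin_ms)
    m = [0.0, 0.0, 0.0]
    for (t0, t1, g0, g1) in w._effective_segments():
        a = t0 - t_org
        dt = t1 - t0
        s = (g1 - g0) / dt
        # local integrals I_k = int_0^dt G(tau) tau^k dtau (cancellation-safe)
        i0 = g0 * dt + s * dt ** 2 / 2.0
        i1 = g0 * dt ** 2 / 2.0 + s * dt ** 3 / 3.0
        i2 = g0 * dt ** 3 / 3.0 + s * dt ** 4 / 4.0
        m[0] += i0
        if order >= 1:
            m[1] += a * i0 + i1
        if order >= 2:
            m[2] += a * a * i0 + 2.0 * a * i1 + i2
    return MomentReport(m0=m[0], m1=m[1], m2=m[2])


def compute_b_value(w: GradientWaveform, gamma: float = GAMMA_PROTON,
                    force: bool = False) -> float:
    """b-value (s mm^-2) of the effective waveform: b = int q(t)^2 dt with
    q(t) = gamma int_0^t G_eff, integrated exactly per linear segment.

    A waveform whose zeroth moment does not vanish at the echo leaves a net
    dephasing and its b-value is ill-defined for imaging; this errors unless
    ``force=True``.
    """
    segs = w._effective_segments()
    area_scale = sum(abs(0.5 * (g0 + g1) * (t1 - t0))
                     for (t0, t1, g0, g1) in segs) or 1.0
    m0 = compute_moments(w, order=0).m0
    if abs(m0) > 1e-9 * area_scale:
        if not force:
            raise ValueError("waveform is not refocused (M0 != 0 at echo); "
                             "pass force=True to integrate anyway")
        warnings.warn("b-value of a non-refocused waveform", stacklevel=2)

    b_si = 0.0
    q0 = 0.0  # rad / m
    for (t0, t1, g0, g1) in segs:
        dt = (t1 - t0) * 1e-3                      # s
        g0_si, g1_si = g0 * 1e-3, g1 * 1e-3        # T/m
        s = (g1_si - g0_si) / dt
        # q(tau) = q0 + gamma (g0 tau + s tau^2 / 2)
        poly = np.array([q0, gamma * g0_si, gamma * s / 2.0])
        sq = np.polynomial.polynomial.polymul(poly, poly)
        b_si += sum(c * dt ** (k + 1) / (k + 1) for k, c in enumerate(sq))
        q0 += gamma * (g0_si * dt + s * dt ** 2 / 2.0)
    return b_si / 1e6  # s/m^2 -> s/mm^2


def stejskal_tanner_b(g_mt_m: float, delta_ms: float, Delta_ms: float,
                      gamma: float = GAMMA_PROTON) -> float:
    """Analytic b = gamma^2 G^2 delta^2 (Delta - delta/3), in s mm^-2,
    for a rectangular monopolar pair (ramps neglected)."""
    g = g_mt_m * 1e-3
    d = delta_ms * 1e-3
    D = Delta_ms * 1e-3
    return gamma ** 2 * g ** 2 * d ** 2 * (D - d / 3.0) / 1e6


# ---------------------------------------------------------------------------
# Waveform construction
# ---------------------------------------------------------------------------

def _trapezoid(t0: float, duration: float, amp: float, slew: float):
    """Breakpoints of a slew-limited trapezoid lobe of given total duration.

    Falls back to a triangle when the duration cannot accommodate the full
    amplitude at the given slew rate."""
    ramp = abs(amp) / slew
    if 2.0 * ramp >= duration:
        peak = np.sign(amp) * slew * duration / 2.0
        return ([t0, t0 + duration / 2.0, t0 + duration],
                [0.0, peak, 0.0])
    return ([t0, t0 + ramp, t0 + duration - ramp, t0 + duration],
            [0.0, amp, amp, 0.0])


def _append(points_t, points_g, ts, gs):
    for t, g in zip(ts, gs):
        if points_t and abs(points_t[-1] - t) < 1e-12 and abs(points_g[-1] - g) < 1e-12:
            continue
        points_t.append(t)
        points_g.append(g)


def _m2_candidate(d1: float, d2: float, gmax: float, slew: float,
                  gap: float) -> GradientWaveform:
    """Short(d1)+long(d2) pair before the refocusing gap, mirrored after it
    (physical polarities + - | - +), all lobes amplitude-limited at gmax."""
    t: list[float] = []
    g: list[float] = []
    _append(t, g, *_trapezoid(0.0, d1, +gmax, slew))
    _append(t, g, *_trapezoid(d1, d2, -gmax, slew))
    start_post = d1 + d2 + gap
    _append(t, g, *_trapezoid(start_post, d2, -gmax, slew))
    _append(t, g, *_trapezoid(start_post + d2, d1, +gmax, slew))
    refocus = d1 + d2 + gap / 2.0
    return GradientWaveform(np.array(t), np.array(g), refocus_ms=(refocus,),
                            gmax_mt_m=gmax, slew_t_m_s=slew,
                            meta={"d1_ms": d1, "d2_ms": d2, "gap_ms": gap})


def stejskal_tanner_pair(g_mt_m: float, delta_ms: float, Delta_ms: float,
                         slew: float = 1e6, gmax: float | None = None,
                         gap_ms: float | None = None) -> GradientWaveform:
    """Monopolar lobe pair straddling a refocusing pulse (classic diffusion
    encoding); near-rectangular lobes by default (very high slew)."""
    gmax = g_mt_m if gmax is None else gmax
    t: list[float] = []
    g: list[float] = []
    _append(t, g, *_trapezoid(0.0, delta_ms, g_mt_m, slew))
    _append(t, g, *_trapezoid(Delta_ms, delta_ms, g_mt_m, slew))
    refocus = (delta_ms + Delta_ms) / 2.0 if gap_ms is None else gap_ms
    return GradientWaveform(np.array(t), np.array(g), refocus_ms=(refocus,),
                            gmax_mt_m=gmax, slew_t_m_s=slew)


def design_m2_waveform(target_b: float, gmax: float = 43.0,
                       slew: float = 180.0, refocus_gap_ms: float = 9.0,
                       d1_max_ms: float = 40.0) -> GradientWaveform:
    """Design a first/second-order motion-compensated encoding waveform with
    b within 0.1% of ``target_b`` under the amplitude and slew limits.

    Raises :class:`InfeasibleWaveform` (naming the limiting constraint) when
    the target b cannot be reached with a short-lobe duration up to
    ``d1_max_ms``.
    """
    if target_b < 0:
        raise ValueError("target b must be >= 0")
    if target_b == 0:
        return GradientWaveform(np.array([0.0]), np.array([0.0]),
                                gmax_mt_m=gmax, slew_t_m_s=slew)

    ramp = gmax / slew

    def solve_d2(d1: float) -> float:
        def m1_of(d2: float) -> float:
            return compute_moments(_m2_candidate(d1, d2, gmax, slew,
                                                 refocus_gap_ms)).m1
        lo = max(2.0 * ramp, 0.05)
        hi = max(d1 * 1.5, lo * 2.0)
        while m1_of(hi) < 0:
            hi *= 1.6
            if hi > 500.0:
                raise InfeasibleWaveform("cannot null M1: slew rate limits "
                                         "the long lobe")
        return brentq(m1_of, lo, hi, xtol=1e-12)

    def b_of(d1: float) -> float:
        wf = _m2_candidate(d1, solve_d2(d1), gmax, slew, refocus_gap_ms)
        return compute_b_value(wf)

    d1_lo = max(2.0 * ramp, 0.3)
    if b_of(d1_lo) > target_b:
        # scale the whole waveform's amplitude down instead (b ~ G^2)
        scale = np.sqrt(target_b / b_of(d1_lo))
        d2 = solve_d2(d1_lo)
        wf = _m2_candidate(d1_lo, d2, gmax * scale, slew, refocus_gap_ms)
        # durations kept: re-null M1 at the reduced amplitude (same solution,
        # M1 is linear in amplitude) and rescale to the target exactly
        b0 = compute_b_value(wf)
        wf = _m2_candidate(d1_lo, d2, gmax * scale * np.sqrt(target_b / b0),
                           slew, refocus_gap_ms)
        return wf
    if b_of(d1_max_ms) < target_b:
        raise InfeasibleWaveform(
            f"b = {target_b} s/mm^2 unreachable with Gmax = {gmax} mT/m, "
            f"slew = {slew} T/m/s and short lobe <= {d1_max_ms} ms "
            "(amplitude limit Gmax is the binding constraint)")
    d1 = brentq(lambda d: b_of(d) - target_b, d1_lo, d1_max_ms, xtol=1e-9)
    return _m2_candidate(d1, solve_d2(d1), gmax, slew, refocus_gap_ms)


def time_reverse(w: GradientWaveform) -> GradientWaveform:
    """Time-reversed waveform (markers mirrored as well)."""
    t_end = w.times_ms[-1]
    return GradientWaveform(
        times_ms=(t_end - w.times_ms)[::-1].copy(),
        amps_mt_m=w.amps_mt_m[::-1].copy(),
        refocus_ms=tuple(sorted(t_end - np.asarray(w.refocus_ms))),
        gmax_mt_m=w.gmax_mt_m, slew_t_m_s=w.slew_t_m_s)


def audit_limits(w: GradientWaveform, dt_us: float = 1.0,
                 rtol: float = 1e-6) -> dict:
    """Sample the physical waveform at ``dt_us`` resolution and check the
    amplitude and slew limits everywhere."""
    if w.times_ms.size < 2:
        return {"ok": True, "max_amp": 0.0, "max_slew": 0.0}
    dt = dt_us * 1e-3
    t = np.arange(w.times_ms[0], w.times_ms[-1] + dt / 2, dt)
    g = np.interp(t, w.times_ms, w.amps_mt_m)
    max_amp = float(np.abs(g).max())
    max_slew = float(np.abs(np.diff(g)).max() / dt) if t.size > 1 else 0.0
    ok = (max_amp <= w.gmax_mt_m * (1 + rtol)
          and max_slew <= w.slew_t_m_s * (1 + rtol))
    return {"ok": bool(ok), "max_amp": max_amp, "max_slew": max_slew}
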