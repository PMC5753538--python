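"""Closed-form sequence theory: the spin-echo vs stimulated-echo SNR ratio,
root-mean-square diffusion distances, and breath-hold scheduling arithmetic.

The SNR ratio model compares a motion-compensated spin echo (recovery over
one RR interval, long TE) against a STEAM acquisition (recovery over one RR,
short TE, but a factor-1/2 stimulated-echo penalty and T1 decay over the
mixing time TM ~ 1 RR):

    SNR_SE / SNR_STEAM =
        (1 - exp(-Trecov_SE/T1)) exp(-TE_SE/T2) exp(-b_SE D)
        -----------------------------------------------------------------
        1/2 (1 - exp(-Trecov_STEAM/T1)) exp(-TE_STEAM/T2) exp(-b_STEAM D)
            exp(-TM/T1)

with ideal 90/180-degree flip angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SnrTheoryParams",
    "ScheduleSpec",
    "theoretical_snr_ratio",
    "diffusion_distance",
    "breath_hold_rr",
]


@dataclass
class SnrTheoryParams:
    """Everything the SNR-ratio formula needs. Times in ms, D in mm^2 s^-1,
    b in s mm^-2."""

    t1_ms: float
    t2_ms: float
    d: float
    trecov_se_ms: float
    trecov_steam_ms: float
    tm_ms: float
    te_se_ms: float
    te_steam_ms: float
    b_se: float
    b_steam: float

    def __post_init__(self) -> None:
        for name in ("t1_ms", "t2_ms", "trecov_se_ms", "trecov_steam_ms",
                     "tm_ms", "te_se_ms", "te_steam_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d < 0:
            raise ValueError("diffusivity must be non-negative")

    @classmethod
    def agar_phantom(cls) -> "SnrTheoryParams":
        """Parameters of the agar phantom study: T1 = 1090 ms, T2 = 51 ms,
        D = 1.2e-3 mm^2/s, simulated RR (= recovery and mixing times) of
        1000 ms, TE 76/25 ms, reference b-values 30/34 s/mm^2."""
        return cls(t1_ms=1090.0, t2_ms=51.0, d=1.2e-3,
                   trecov_se_ms=1000.0, trecov_steam_ms=1000.0, tm_ms=1000.0,
                   te_se_ms=76.0, te_steam_ms=25.0, b_se=30.0, b_steam=34.0)


def theoretical_snr_ratio(p: SnrTheoryParams) -> float:
    """SNR_SE / SNR_STEAM from the closed-form ratio above."""
    num = ((1.0 - math.exp(-p.trecov_se_ms / p.t1_ms))
           * math.exp(-p.te_se_ms / p.t2_ms)
           * math.exp(-p.b_se * p.d))
    den = (0.5 * (1.0 - math.exp(-p.trecov_steam_ms / p.t1_ms))
           * math.exp(-p.te_steam_ms / p.t2_ms)
           * math.exp(-p.b_steam * p.d)
           * math.exp(-p.tm_ms / p.t1_ms))
    return num / den


def diffusion_distance(d: float, delta_t_s: float,
                       convention: str = "1d") -> float:
    """Root-mean-square distance (micrometres) diffused in ``delta_t_s``
    seconds at diffusivity ``d`` (mm^2 s^-1).

    The default 1D convention sqrt(2 D dt) is the one that reproduces the
    familiar ~75 um (free water over one cardiac cycle) and ~10 um (over a
    20 ms spin-echo diffusion time) figures; sqrt(6 D dt) gives the 3D norm.
    """
    if d < 0 or delta_t_s < 0:
        raise ValueError("D and delta_t must be non-negative")
    factor = {"1d": 2.0, "3d": 6.0}[convention]
    return math.sqrt(factor * d * delta_t_s) * 1000.0  # mm -> um


@dataclass
class ScheduleSpec:
    """Breath-hold shot structure of one sequence.

    ``prep_shots`` (EPI phase-correction + parallel-imaging reference lines)
    are acquired once per breath-hold; each average then needs one shot per
    b0 image plus one per diffusion direction; every shot costs ``tr_rr``
    RR intervals.
    """

    tag: str
    tr_rr: int
    prep_shots: int = 2
    b0_shots: int = 1
    n_directions: int = 6
    averages_per_breath_hold: int = 1

    def __post_init__(self) -> None:
        for name in ("tr_rr", "prep_shots", "b0_shots", "n_directions",
                     "averages_per_breath_hold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def steam(cls) -> "ScheduleSpec":
        return cls(tag="STEAM", tr_rr=2, averages_per_breath_hold=1)

    @classmethod
    def m2se(cls) -> "ScheduleSpec":
        return cls(tag="M2SE", tr_rr=1, averages_per_breath_hold=2)


def breath_hold_rr(schedule: ScheduleSpec) -> int:
    """RR intervals per breath-hold:
    TR_RR x (prep + averages x (b0 + directions))."""
    shots = (schedule.prep_shots
             + schedule.averages_per_breath_hold
             * (schedule.b0_shots + schedule.n_directions))
    return int(schedule.tr_rr * shots)
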