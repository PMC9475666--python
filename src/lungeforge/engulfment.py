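"""Engulfed volume, engulfed mass, engulfment drag and force residual.

The mouth follows a prescribed gape schedule over the deceleration: linear
opening to maximum gape over the first third, a plateau over the middle
third, and linear closing over the final third.  The posterior volume is the
integral of speed times projected mouth area from mouth opening to maximum
gape; the anterior volume is a 75-degree wedge of an ellipsoid of
revolution.  Engulfed mass is seawater density times total volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GapeSchedule",
    "EngulfmentResult",
    "gape_angle",
    "projected_area",
    "posterior_volume",
    "anterior_volume",
    "engulfment_drag",
    "force_residual",
    "compute_engulfment",
    "RHO_SEAWATER",
]

#: Default seawater density (kg m^-3); configurable everywhere it is used.
RHO_SEAWATER = 1025.0

DEFAULT_MAX_GAPE_DEG = 75.0


class EngulfmentError(ValueError):
    """Invalid engulfment-model input."""


@dataclass(frozen=True)
class GapeSchedule:
    """Rise/plateau/fall mouth-gape time course over one deceleration.

    Opening and closing each occupy a third of ``dT_decel`` at a constant
    angular rate; the middle third holds ``max_gape_deg``.
    """

    dT_decel: float
    max_gape_deg: float = DEFAULT_MAX_GAPE_DEG

    def __post_init__(self) -> None:
        if not self.dT_decel > 0:
            raise EngulfmentError(f"dT_decel must be positive, got {self.dT_decel}")
        if not 0 < self.max_gape_deg <= 90:
            raise EngulfmentError(f"max_gape_deg must be in (0, 90], got {self.max_gape_deg}")

    @property
    def t_open_end(self) -> float:
        return self.dT_decel / 3.0

    @property
    def t_close_start(self) -> float:
        return 2.0 * self.dT_decel / 3.0

    @property
    def angular_rate_deg(self) -> float:
        """Opening/closing rate in degrees per second."""
        return self.max_gape_deg / (self.dT_decel / 3.0)


def gape_angle(t_rel, schedule: GapeSchedule):
    """Instantaneous gape angle in radians at time ``t_rel`` into the decel.

    Accepts a scalar or array; every value must lie in [0, dT_decel].
    """
    t = np.asarray(t_rel, dtype=float)
    if np.any(t < -1e-12) or np.any(t > schedule.dT_decel + 1e-12):
        raise EngulfmentError(
            f"t_rel outside [0, {schedule.dT_decel}]: {t_rel!r}"
        )
    t = np.clip(t, 0.0, schedule.dT_decel)
    third = schedule.dT_decel / 3.0
    gmax = math.radians(schedule.max_gape_deg)
    rise = gmax * t / third
    fall = gmax * (schedule.dT_decel - t) / third
    out = np.minimum(np.minimum(rise, fall), gmax)
    return float(out) if np.isscalar(t_rel) else out


def projected_area(A_jaw: float, G_instant):
    """Projected mouth area: ``A_jaw * sin(G_instant)``."""
    if not A_jaw > 0:
        raise EngulfmentError(f"A_jaw must be positive, got {A_jaw}")
    g = np.asarray(G_instant, dtype=float)
    if np.any(g < -1e-12) or np.any(g > math.pi / 2 + 1e-12):
        raise EngulfmentError("gape angle outside [0, pi/2]")
    out = A_jaw * np.sin(g)
    return float(out) if np.isscalar(G_instant) else out


def posterior_volume(
    t: np.ndarray,
    speed: np.ndarray,
    A_jaw: float,
    schedule: GapeSchedule,
    T_MO: float,
    vpos_end: str = "half",
) -> float:
    """Volume swept through the mouth from mouth opening to maximum gape.

    Trapezoid integral of ``U_instant * A_proj`` over [T_MO, T_MG], with
    T_MG at ``T_MO + dT_decel/2`` (default) or ``T_MO + 2*dT_decel/3``
    (``vpos_end='two_thirds'``).  The endpoints are included by linear
    interpolation of the speed channel.
    """
    if vpos_end == "half":
        T_MG = T_MO + schedule.dT_decel / 2.0
    elif vpos_end == "two_thirds":
        T_MG = T_MO + 2.0 * schedule.dT_decel / 3.0
    else:
        raise EngulfmentError(f"vpos_end must be 'half' or 'two_thirds', got {vpos_end!r}")
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if t.size < 2:
        raise EngulfmentError("fewer than 2 samples in the [T_MO, T_MG] window")
    inside = (t > T_MO) & (t < T_MG)
    # The speed channel is only known at the native rate (and is treated as
    # piecewise linear), but the gape factor is analytic, so the quadrature
    # grid is refined and given knots at the schedule's slope breaks; this
    # keeps short decelerations (opening thirds of a few samples) accurate.
    knots = np.array([T_MO + schedule.t_open_end, T_MO + schedule.t_close_start])
    fine = np.linspace(T_MO, T_MG, 201)
    tt = np.unique(np.concatenate(
        [[T_MO, T_MG], t[inside], knots[(knots > T_MO) & (knots < T_MG)], fine]))
    uu = np.interp(tt, t, speed)
    a_proj = projected_area(A_jaw, gape_angle(tt - T_MO, schedule))
    v = float(np.trapezoid(uu * a_proj, tt))
    return max(v, 0.0)


def anterior_volume(W_bz: float, L_rbh: float, max_gape_deg: float = DEFAULT_MAX_GAPE_DEG) -> float:
    """Anterior (pre-TMJ) engulfed volume: a gape-angle wedge of an ellipsoid.

    ``2*pi*W_bz*L_rbh**2/3 * gape/360`` with the default 75-degree gape.
    """
    if not W_bz > 0:
        raise EngulfmentError(f"W_bz must be positive, got {W_bz}")
    if not L_rbh > 0:
        raise EngulfmentError(f"L_rbh must be positive, got {L_rbh}")
    return 2.0 * math.pi * W_bz * L_rbh**2 / 3.0 * (max_gape_deg / 360.0)


def engulfment_drag(M_W: float, U_MC: float, dT_decel: float) -> float:
    """Time-averaged reaction force of accelerating the engulfed mass.

    ``M_W * U_MC / dT_decel`` in newtons.
    """
    if not dT_decel > 0:
        raise EngulfmentError(f"dT_decel must be positive, got {dT_decel}")
    if M_W < 0 or U_MC < 0:
        raise EngulfmentError("M_W and U_MC must be non-negative")
    return M_W * U_MC / dT_decel


def force_residual(
    M_kg: float, U_MO: float, U_MC: float, dT_decel: float, D_engulf: float
) -> tuple[float, float | None]:
    """Shape-drag-minus-thrust residual and its engulfment-drag-normalized form.

    ``residual = M_kg*(U_MO - U_MC)/dT_decel - D_engulf``; positive means
    shape drag exceeds tail thrust.  The normalized value is None when
    D_engulf is zero.
    """
    if not U_MO > U_MC:
        raise EngulfmentError(
            f"inclusion rule violated: U_MO={U_MO} <= U_MC={U_MC}"
        )
    if D_engulf < 0:
        raise EngulfmentError("D_engulf must be non-negative")
    if not dT_decel > 0:
        raise EngulfmentError(f"dT_decel must be positive, got {dT_decel}")
    residual = M_kg * (U_MO - U_MC) / dT_decel - D_engulf
    normalized = residual / D_engulf if D_engulf > 0 else None
    return residual, normalized


@dataclass
class EngulfmentResult:
    """Volumes, engulfed mass and forces for one lunge."""

    V_pos: float
    V_ant: float
    M_W: float
    D_engulf: float
    force_residual: float
    normalized_residual: float | None
    rho: float
    T_MG: float
    A_proj: np.ndarray = field(repr=False, default=None)
    G_instant: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.V_pos < 0 or self.V_ant < 0:
            raise EngulfmentError("volumes must be non-negative")

    @property
    def V_total(self) -> float:
        return self.V_pos + self.V_ant


def compute_engulfment(
    t: np.ndarray,
    speed: np.ndarray,
    lunge,
    A_jaw: float,
    W_bz: float,
    L_rbh: float,
    M_kg: float,
    rho: float = RHO_SEAWATER,
    max_gape_deg: float = DEFAULT_MAX_GAPE_DEG,
    vpos_end: str = "half",
) -> EngulfmentResult:
    """Full engulfment computation for one segmented lunge."""
    schedule = GapeSchedule(dT_decel=lunge.dT_decel, max_gape_deg=max_gape_deg)
    V_pos = posterior_volume(t, speed, A_jaw, schedule, lunge.T_MO, vpos_end=vpos_end)
    V_ant = anterior_volume(W_bz, L_rbh, max_gape_deg)
    M_W = rho * (V_pos + V_ant)
    D_engulf = engulfment_drag(M_W, lunge.U_MC, lunge.dT_decel)
    residual, normalized = force_residual(M_kg, lunge.U_MO, lunge.U_MC, lunge.dT_decel, D_engulf)
    t = np.asarray(t, dtype=float)
    inside = (t >= lunge.T_MO) & (t <= lunge.T_MC)
    g_trace = gape_angle(t[inside] - lunge.T_MO, schedule)
    return EngulfmentResult(
        V_pos=V_pos,
        V_ant=V_ant,
        M_W=M_W,
        D_engulf=D_engulf,
        force_residual=residual,
        normalized_residual=normalized,
        rho=rho,
        T_MG=lunge.T_MO + (schedule.dT_decel / 2.0 if vpos_end == "half" else 2 * schedule.dT_decel / 3.0),
        A_proj=projected_area(A_jaw, g_trace),
        G_instant=g_trace,
    )
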