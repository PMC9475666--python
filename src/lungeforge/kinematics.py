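"""Segmentation of 10 Hz tag traces into lunges and their phases.

A lunge is located by a sustained run of strongly negative smoothed
acceleration (the engulfment deceleration), then the six event times are
refined with least-squares hinge (broken-stick) fits so that boundaries land
on the slope-change corners rather than on threshold crossings, which are
biased for shallow decelerations.  The y-gyroscope channel provides the
fluking onset, per-tailbeat periods, and the long-period final oscillation
that spans engulfment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TagTrace",
    "LungeEvent",
    "TailbeatRecord",
    "DetectionThresholds",
    "speed_from_ocdr",
    "detect_lunges",
    "segment_phases",
    "final_oscillation",
    "tailbeat_periods",
    "sample_middle_lunges",
    "sample_size_stability",
]

log = logging.getLogger(__name__)


class TraceError(ValueError):
    """Malformed tag trace."""


class SegmentationError(ValueError):
    """A lunge window that cannot be segmented."""


# --------------------------------------------------------------------------
# trace container


@dataclass
class TagTrace:
    """Regular-grid multichannel kinematic time series for one deployment.

    ``valid`` masks samples that were flagged as gaps on ingestion; masked
    spans are excluded from lunge detection and spans longer than 1 s split
    the trace (no interpolation across them).
    """

    t: np.ndarray
    depth: np.ndarray
    pitch: np.ndarray
    speed: np.ndarray
    gyro_y: np.ndarray
    sample_rate: float = 10.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("depth", "pitch", "speed", "gyro_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise TraceError(f"channel {name!r} length {arr.size} != t length {self.t.size}")
            setattr(self, name, arr)
        if self.t.size < 2:
            raise TraceError("trace needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise TraceError("time must be strictly increasing")
        if np.ptp(dt) > 1e-6:
            raise TraceError("sample interval not constant to within 1e-6 s")
        if abs(dt[0] - 1.0 / self.sample_rate) > 1e-6:
            raise TraceError(
                f"sample interval {dt[0]:.6f} s inconsistent with declared rate "
                f"{self.sample_rate} Hz"
            )
        if self.valid is None:
            nan = np.zeros(self.t.shape, dtype=bool)
            for name in ("depth", "pitch", "speed", "gyro_y"):
                nan |= np.isnan(getattr(self, name))
            self.valid = ~nan
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        for name in ("depth", "pitch", "speed", "gyro_y"):
            if np.any(np.isnan(getattr(self, name)[self.valid])):
                raise TraceError(f"NaN in channel {name!r} outside masked spans")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def __len__(self) -> int:
        return self.t.size

    def segments(self, max_gap: float = 1.0) -> list[tuple[int, int]]:
        """Contiguous valid index spans; masked gaps > ``max_gap`` split the trace.

        Shorter masked gaps are tolerated inside a segment (detection
        smoothing bridges them).
        """
        if self.valid.all():
            return [(0, len(self))]
        spans: list[tuple[int, int]] = []
        idx = np.flatnonzero(self.valid)
        if idx.size == 0:
            return []
        max_gap_n = int(round(max_gap * self.sample_rate))
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i - prev > max_gap_n:
                spans.append((start, prev + 1))
                start = i
            prev = i
        spans.append((start, prev + 1))
        return spans


# --------------------------------------------------------------------------
# domain records


@dataclass
class LungeEvent:
    """Event times/speeds, phase durations and context for one lunge."""

    T_fluke: float
    T_accel: float
    T_max: float
    T_MO: float
    T_MC: float
    T_min: float
    U_fluke: float
    U_accel: float
    U_max: float
    U_MO: float
    U_MC: float
    U_min: float
    depth_at_MO: float = float("nan")
    dive_id: int = -1
    position_in_dive: str = "middle"
    distance_decel: float = float("nan")
    T_gyr1: float | None = None
    T_gyr2: float | None = None
    T_gyr3: float | None = None
    individual_id: str = ""

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (self.T_fluke <= self.T_accel + eps
                and self.T_accel < self.T_max + eps
                and self.T_max <= self.T_MO + eps
                and self.T_MO < self.T_MC
                and self.T_MC <= self.T_min + eps):
            raise SegmentationError(
                "event ordering violated: "
                f"T_fluke={self.T_fluke:.2f} T_accel={self.T_accel:.2f} "
                f"T_max={self.T_max:.2f} T_MO={self.T_MO:.2f} "
                f"T_MC={self.T_MC:.2f} T_min={self.T_min:.2f}"
            )
        if not self.U_MO > self.U_MC:
            raise SegmentationError(
                f"inclusion rule violated: U_MO={self.U_MO:.3f} <= U_MC={self.U_MC:.3f}"
            )
        if self.T_min > self.T_MC + 5.0 + eps:
            raise SegmentationError("T_min must lie within 5 s after T_MC")
        if self.position_in_dive not in ("first", "middle", "last", "solitary"):
            raise SegmentationError(f"bad position_in_dive {self.position_in_dive!r}")

    @property
    def dT_accel(self) -> float:
        return self.T_max - self.T_accel

    @property
    def dT_adjust(self) -> float:
        return self.T_MO - self.T_max

    @property
    def dT_decel(self) -> float:
        return self.T_MC - self.T_MO

    @property
    def dT_finOs(self) -> float | None:
        if self.T_gyr1 is None or self.T_gyr3 is None:
            return None
        return self.T_gyr3 - self.T_gyr1

    @property
    def has_final_oscillation(self) -> bool:
        return self.T_gyr1 is not None


@dataclass
class TailbeatRecord:
    """Per-beat periods for one lunge; the final oscillation is last."""

    lunge: LungeEvent
    periods: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.periods):
            raise SegmentationError("tailbeat periods must be positive")

    @property
    def final_oscillation_period(self) -> float | None:
        return self.periods[-1] if self.periods else None


@dataclass(frozen=True)
class DetectionThresholds:
    """Tunable thresholds for lunge detection and phase segmentation.

    ``a_thresh`` defaults to 0.20 m s^-2: Table-calibrated blue-whale
    decelerations run as shallow as ~0.3 m s^-2, which a 0.35 threshold
    would miss outright.
    """

    a_thresh: float = 0.20          # m s^-2, core deceleration threshold
    g_thresh: float = 0.10          # rad s^-1, gyro activity threshold
    smooth_window: float = 0.5      # s, event-level speed smoothing
    detect_smooth: float = 1.0      # s, extra accel smoothing for run finding
    min_decel_duration: float = 0.4  # s
    bridge_gap: float = 0.3         # s, interruptions bridged inside a run
    min_speed_drop: float = 0.5     # m s^-1, required U_MO - U_MC
    t_accel_window: float = 30.0    # s before T_MO searched for T_accel
    t_min_window: float = 5.0       # s after T_MC searched for T_min
    min_pitch: float = 0.35         # rad, OCDR validity floor
    dive_depth: float = 1.0         # m, surface threshold for dive splitting
    quiet_gap: float = 2.0          # s of gyro quiet required before T_fluke


# --------------------------------------------------------------------------
# primitives


def speed_from_ocdr(depth_rate, pitch, min_pitch: float = 0.35) -> np.ma.MaskedArray:
    """Orientation-corrected depth-rate speed: depth rate over sin(pitch).

    Samples with ``|pitch| < min_pitch`` are masked (excluded), never zeroed,
    so a vertical-rate estimate is never produced from a near-horizontal
    posture and division by zero cannot occur.
    """
    depth_rate = np.atleast_1d(np.asarray(depth_rate, dtype=float))
    pitch = np.atleast_1d(np.asarray(pitch, dtype=float))
    excluded = np.abs(pitch) < min_pitch
    safe = np.where(excluded, 1.0, np.sin(pitch))
    out = np.ma.MaskedArray(depth_rate / safe, mask=excluded)
    return out


def _movavg(x: np.ndarray, width_s: float, fs: float) -> np.ndarray:
    """Centered moving average; width rounded to an odd sample count."""
    n = max(1, int(round(width_s * fs)))
    if n % 2 == 0:
        n += 1
    if n == 1:
        return x.astype(float)
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(xp, kernel, mode="valid")


def _hinge_fit(t: np.ndarray, y: np.ndarray, tau_grid: np.ndarray) -> float:
    """Least-squares broken-stick changepoint.

    Fits ``y ~ b0 + b1 t + b2 max(0, t - tau)`` for each candidate ``tau``
    and returns the tau minimizing the residual sum of squares.
    """
    best_tau = tau_grid[0]
    best_sse = np.inf
    for tau in tau_grid:
        X = np.column_stack([np.ones_like(t), t, np.maximum(0.0, t - tau)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        sse = float(r @ r)
        if sse < best_sse:
            best_sse = sse
            best_tau = tau
    return float(best_tau)


def _two_hinge_fit(
    t: np.ndarray,
    y: np.ndarray,
    tau1_grid: np.ndarray,
    tau2_grid: np.ndarray,
    min_sep: float,
    extra_cols: np.ndarray | None = None,
) -> tuple[float, float]:
    """Joint least-squares fit of two slope-change points.

    Fits ``y ~ b0 + b1 t + b2 relu(t - tau1) + b3 relu(t - tau2)`` over the
    candidate grid (tau2 > tau1 + min_sep) and returns the pair minimizing
    the residual sum of squares.  Used to land the deceleration start and
    end on the speed-trace corners.
    """
    ones = np.ones_like(t)
    extras = () if extra_cols is None else tuple(extra_cols.T)
    best = (float(tau1_grid[0]), float(tau2_grid[-1]))
    best_sse = np.inf
    for tau1 in tau1_grid:
        h1 = np.maximum(0.0, t - tau1)
        for tau2 in tau2_grid:
            if tau2 < tau1 + min_sep:
                continue
            X = np.column_stack([ones, t, h1, np.maximum(0.0, t - tau2), *extras])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ coef
            sse = float(r @ r)
            if sse < best_sse:
                best_sse = sse
                best = (float(tau1), float(tau2))
    return best


def _three_hinge_fit(
    t: np.ndarray,
    y: np.ndarray,
    grids: tuple[np.ndarray, np.ndarray, np.ndarray],
    min_seps: tuple[float, float],
    extra_cols: np.ndarray | None = None,
) -> tuple[tuple[float, float, float], np.ndarray]:
    """Joint least-squares fit of three slope-change points.

    Models a four-segment piecewise-linear trace (approach ramp, adjustment
    decline, engulfment deceleration, post-lunge slope).  ``extra_cols``
    are optional nuisance regressors.  Returns the best breakpoint triple,
    its coefficients, and the full (sse, taus, coef) candidate list sorted
    by residual sum of squares; the piecewise slopes are the cumulative
    sums of coefficients 1..4.
    """
    ones = np.ones_like(t)
    g1, g2, g3 = grids
    s12, s23 = min_seps
    extras = () if extra_cols is None else tuple(extra_cols.T)
    results = []
    for tau1 in g1:
        h1 = np.maximum(0.0, t - tau1)
        for tau2 in g2:
            if tau2 < tau1 + s12:
                continue
            h2 = np.maximum(0.0, t - tau2)
            for tau3 in g3:
                if tau3 < tau2 + s23:
                    continue
                X = np.column_stack(
                    [ones, t, h1, h2, np.maximum(0.0, t - tau3), *extras])
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                r = y - X @ coef
                results.append((float(r @ r),
                                (float(tau1), float(tau2), float(tau3)), coef))
    if not results:
        raise SegmentationError("no admissible breakpoint triple")
    results.sort(key=lambda item: item[0])
    return results[0][1], results[0][2], results


def integrate_speed(t: np.ndarray, speed: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoid integral of the speed channel over [t0, t1] (metres).

    Endpoints are included by linear interpolation, so the integral of a
    linear ramp equals mean speed times duration exactly.
    """
    if t1 <= t0:
        raise SegmentationError(f"empty integration window [{t0}, {t1}]")
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    inside = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[inside], [t1]])
    uu = np.concatenate([[float(np.interp(t0, t, speed))],
                         speed[inside],
                         [float(np.interp(t1, t, speed))]])
    return float(np.trapezoid(uu, tt))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _bridge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= max_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


# --------------------------------------------------------------------------
# dive segmentation


def segment_dives(trace: TagTrace, surface_depth: float = 1.0,
                  min_duration: float = 10.0) -> list[tuple[float, float]]:
    """Contiguous spans with depth > surface_depth, as (t_start, t_end).

    The depth channel is lightly smoothed and brief threshold flickers are
    bridged so sensor noise at the crossing cannot split a dive; spans
    shorter than ``min_duration`` are discarded.
    """
    depth_s = _movavg(trace.depth, 1.0, trace.sample_rate)
    sub = depth_s > surface_depth
    runs = _bridge_runs(_runs(sub), int(round(2.0 * trace.sample_rate)))
    out = []
    for s, e in runs:
        if (e - s) * trace.dt >= min_duration:
            out.append((float(trace.t[s]), float(trace.t[e - 1])))
    return out


def _assign_dive_context(events: list[LungeEvent], dives: list[tuple[float, float]]) -> list[LungeEvent]:
    by_dive: dict[int, list[int]] = {}
    for i, ev in enumerate(events):
        dive_id = -1
        for j, (t0, t1) in enumerate(dives):
            if t0 <= ev.T_MO <= t1:
                dive_id = j
                break
        ev.dive_id = dive_id
        by_dive.setdefault(dive_id, []).append(i)
    for dive_id, idxs in by_dive.items():
        idxs = sorted(idxs, key=lambda i: events[i].T_MO)
        if len(idxs) == 1:
            events[idxs[0]].position_in_dive = "solitary"
            continue
        for rank, i in enumerate(idxs):
            if rank == 0:
                events[i].position_in_dive = "first"
            elif rank == len(idxs) - 1:
                events[i].position_in_dive = "last"
            else:
                events[i].position_in_dive = "middle"
    return events


# --------------------------------------------------------------------------
# detection


def detect_lunges(
    trace: TagTrace,
    thresholds: DetectionThresholds = DetectionThresholds(),
    individual_id: str = "",
) -> list[LungeEvent]:
    """Locate lunges in a trace and segment each into a full LungeEvent.

    Candidates whose speed profile violates the accelerate-then-decelerate
    pattern (including U_MO <= U_MC) are rejected; counts are logged.
    """
    th = thresholds
    fs = trace.sample_rate
    found: list[LungeEvent] = []
    n_rejected = 0
    for seg_start, seg_stop in trace.segments():
        if (seg_stop - seg_start) * trace.dt < 2 * th.min_decel_duration + 2.0:
            continue
        t = trace.t[seg_start:seg_stop]
        speed = trace.speed[seg_start:seg_stop]
        gyro = trace.gyro_y[seg_start:seg_stop]
        # Fill any short masked gaps so the filters are defined everywhere.
        bad = ~trace.valid[seg_start:seg_stop]
        if bad.any():
            speed = speed.copy()
            gyro = gyro.copy()
            good = ~bad
            speed[bad] = np.interp(t[bad], t[good], speed[good])
            gyro[bad] = np.interp(t[bad], t[good], gyro[good])
        speed_s = _movavg(speed, th.smooth_window, fs)
        accel = np.gradient(speed_s, trace.dt)
        accel_det = _movavg(accel, th.detect_smooth, fs)
        core = accel_det < -th.a_thresh
        runs = _bridge_runs(_runs(core), int(round(th.bridge_gap * fs)))
        min_len = int(round(th.min_decel_duration * fs))
        for s, e in runs:
            if e - s < min_len:
                continue
            if speed_s[s] - speed_s[e - 1] < th.min_speed_drop:
                continue
            try:
                ev = segment_phases(
                    trace, (seg_start + s, seg_start + e),
                    thresholds=th, individual_id=individual_id,
                    _precomputed=(seg_start, t, speed, speed_s, gyro),
                )
            except SegmentationError as err:
                n_rejected += 1
                log.debug("candidate at t=%.1f rejected: %s", t[s], err)
                continue
            found.append(ev)
    # De-duplicate overlapping detections (keep the earlier one).
    found.sort(key=lambda ev: ev.T_MO)
    deduped: list[LungeEvent] = []
    for ev in found:
        if deduped and ev.T_MO < deduped[-1].T_MC:
            n_rejected += 1
            continue
        deduped.append(ev)
    dives = segment_dives(trace, th.dive_depth)
    _assign_dive_context(deduped, dives)
    for ev in deduped:
        _attach_final_oscillation(trace, ev, th)
    log.info("detected %d lunges (%d candidates rejected)", len(deduped), n_rejected)
    return deduped


def segment_phases(
    trace: TagTrace,
    window: tuple[int, int],
    thresholds: DetectionThresholds = DetectionThresholds(),
    individual_id: str = "",
    _precomputed=None,
) -> LungeEvent:
    """Populate all six event times/speeds for one candidate window.

    ``window`` is a (start, stop) index pair bracketing the core
    deceleration run (from :func:`detect_lunges`).
    """
    th = thresholds
    fs = trace.sample_rate
    dt = trace.dt
    if _precomputed is not None:
        seg_start, t, speed, speed_s, gyro = _precomputed
    else:
        seg_start = 0
        t = trace.t
        speed = trace.speed
        speed_s = _movavg(speed, th.smooth_window, fs)
        gyro = trace.gyro_y
    i0 = window[0] - seg_start
    i1 = window[1] - seg_start
    if i1 - i0 < 2:
        raise SegmentationError("candidate window shorter than 2 samples")
    n = t.size
    run_len = (i1 - i0) * dt

    def u_at(time: float) -> float:
        return float(np.interp(time, t, speed_s))

    # -- bracket the steep deceleration ------------------------------------
    # Longest run below 0.6x the peak smoothed deceleration: strict enough
    # to exclude the gentler adjustment decline, smoothed enough that noise
    # dips cannot drag the bracket outward.
    accel = np.gradient(speed_s, dt)
    accel_b = _movavg(accel, 1.0, fs)
    pad_run = int(round(1.0 * fs))
    b0 = max(0, i0 - pad_run)
    a_run = accel_b[b0:i1 + pad_run]
    peak = float(a_run.min())
    if peak >= 0:
        raise SegmentationError("no deceleration inside candidate window")
    runs_b = _runs(a_run < 0.6 * peak)
    if not runs_b:
        raise SegmentationError("no deceleration core inside candidate window")
    rs, re = max(runs_b, key=lambda r: r[1] - r[0])
    j0 = b0 + rs
    j1 = b0 + re

    # -- T_max, T_MO, T_MC: joint breakpoint fit ---------------------------
    # One four-segment broken-stick model covers approach ramp, optional
    # adjustment decline, engulfment deceleration and post-lunge slope.
    # Fitting the three corners jointly avoids the deadlock where the T_MO
    # fit is biased by an unmodelled peak corner and vice versa.  The
    # adjustment break is kept only if its segment genuinely flattens or
    # declines; otherwise the two-corner model is used and T_max = T_MO.
    t_j0 = t[j0]
    t_j1 = t[min(j1, n - 1)]
    lo_j = max(0, int(np.searchsorted(t, t_j0 - 4.5)))
    hi_j = min(n, int(np.searchsorted(t, t_j1 + 1.5)))
    tw = t[lo_j:hi_j]
    yw = speed[lo_j:hi_j]
    def _grid(center: float, back: float, fwd: float, step: float) -> np.ndarray:
        g = np.arange(center - back, center + fwd + 1e-9, step)
        return g[(g > tw[0] + dt) & (g < tw[-1] - dt)]

    def _joint(step_scale: float, centers=None):
        if centers is None:
            c1, c2, c3 = t_j0 - 1.5, t_j0, t_j1
            g1 = _grid(c1, 1.9, 1.15, 0.4 * step_scale)
            g2 = _grid(c2, 1.0, 1.0, 0.2 * step_scale)
            g3 = _grid(c3, 1.0, 0.6, 0.2 * step_scale)
        else:
            c1, c2, c3 = centers
            g1 = _grid(c1, 0.8, 0.8, dt)
            g2 = _grid(c2, 0.25, 0.25, dt)
            g3 = _grid(c3, 0.25, 0.25, dt)
        if min(g1.size, g2.size, g3.size) == 0:
            raise SegmentationError("empty breakpoint grid")
        return _three_hinge_fit(tw, yw, (g1, g2, g3), (0.3, 0.25))

    _, _, coarse = _joint(1.0)
    # refine the leading coarse basins, not just the single best: at low
    # noise nearly-degenerate optima can put the coarse winner in the
    # wrong basin
    seeds: list[tuple[float, float, float]] = []
    for _, taus_c, _ in coarse:
        if all(abs(taus_c[0] - s[0]) > 0.25 or abs(taus_c[1] - s[1]) > 0.25
               for s in seeds):
            seeds.append(taus_c)
        if len(seeds) == 3:
            break
    best_fine = None
    for s in seeds:
        taus_f, coef_f, fine = _joint(1.0, centers=s)
        if best_fine is None or fine[0][0] < best_fine[0]:
            best_fine = (fine[0][0], taus_f, coef_f)
    _, (tau1, tau2, tau3), coef = best_fine
    s1 = float(coef[1])
    s2 = s1 + float(coef[2])
    s3 = s2 + float(coef[3])
    has_adjust = (
        tau2 - tau1 >= 0.35
        and s1 > 0.04
        and s2 <= min(0.05, 0.5 * s1)
        and s3 < s2 - 0.1
        and s2 >= 0.72 * s3
    )
    if has_adjust:
        T_max, T_MO, T_MC = tau1, tau2, tau3
    else:
        g1 = t[(t >= t_j0 - 1.0) & (t <= t_j0 + 1.0)]
        g2 = t[(t >= t_j1 - 1.0) & (t <= t_j1 + 0.6)]
        g1 = g1[(g1 > tw[0]) & (g1 < tw[-1])]
        g2 = g2[(g2 > tw[0]) & (g2 < tw[-1])]
        if g1.size < 2 or g2.size < 2:
            raise SegmentationError("too few samples to refine T_MO/T_MC")
        T_MO, T_MC = _two_hinge_fit(tw, yw, g1, g2, min_sep=2 * dt)
        T_max = T_MO
    if T_MC <= T_MO + dt:
        raise SegmentationError("deceleration collapsed during refinement")
    j_mo = int(np.searchsorted(t, T_MO))
    j_mo = min(max(j_mo, 1), n - 1)
    U_MO_est = float(np.interp(T_MO, t, speed_s))

    # -- T_accel: walk back down the ramp, then a slope-change fit ---------
    # Slopes are taken over a 4 s central window, wide enough to average a
    # full tailbeat ripple cycle for every species.  The ramp foot is where
    # that slope stays shallow for a sustained half second *at low speed*
    # (the speed gate keeps the walk from stopping on the high-speed
    # adjustment plateau just before mouth opening).
    w4 = int(round(2.0 * fs))
    pad = np.concatenate([np.full(w4, speed_s[0]), speed_s, np.full(w4, speed_s[-1])])
    wslope = (pad[2 * w4:] - pad[:-2 * w4]) / (2 * w4 * dt)
    k_ref = max(0, j_mo - int(round(10.0 * fs)))
    # 75th percentile: robust to the adjustment plateau sitting inside the
    # lookback (its near-zero slopes occupy the lower quartiles)
    s_hat = float(np.percentile(wslope[k_ref:max(j_mo - int(round(1.0 * fs)), k_ref + 1)], 75))
    foot_thr = max(0.3 * s_hat, 0.02)
    speed_gate = 0.6 * U_MO_est
    need_quiet = int(round(0.5 * fs))
    k_lim = max(0, j_mo - int(round(th.t_accel_window * fs)))
    quiet = 0
    k = j_mo
    while k > k_lim and quiet < need_quiet:
        k -= 1
        ok = wslope[k] < foot_thr and speed_s[k] < speed_gate
        quiet = quiet + 1 if ok else 0
    j_foot = k + quiet
    # Smooth over one measured tailbeat period so the ripple cancels
    # exactly for this animal (a fixed width leaks at other frequencies).
    period = _tailbeat_period_estimate(t, gyro, j_foot, j_mo, th, fs)
    speed_4 = _movavg(speed, period, fs)   # ripple-free channel for the fit
    lo3 = max(0, j_foot - int(round(4.5 * fs)))
    # cap the post-foot window below the ramp top so the plateau corner
    # cannot leak into this single-break fit
    hi3 = min(j_mo + 1, j_foot + min(int(round(8.0 * fs)),
                                     max(4, int(0.75 * (j_mo - j_foot)))))
    grid3 = t[max(lo3 + 1, j_foot - int(round(2.0 * fs))):
              min(hi3 - 1, j_foot + int(round(2.0 * fs)))]
    if grid3.size < 2:
        raise SegmentationError("too few samples to refine T_accel")
    T_accel = _hinge_fit(t[lo3:hi3], speed_4[lo3:hi3], grid3)
    if T_accel >= T_max:
        T_accel = T_max - 2 * dt

    # -- T_fluke: gyro activity onset before T_accel -----------------------
    T_fluke = _fluke_onset(t, gyro, T_accel, th, fs)
    if T_fluke is None or T_fluke > T_accel:
        T_fluke = T_accel

    # -- T_min: minimum speed within 5 s after T_MC ------------------------
    j_mc = int(np.searchsorted(t, T_MC))
    j_hi = min(n, j_mc + int(round(th.t_min_window * fs)) + 1)
    if j_hi <= j_mc:
        raise SegmentationError("trace ends at T_MC; no T_min window")
    speed_post = _movavg(speed, 2 * th.smooth_window, fs)
    j_min = j_mc + int(np.argmin(speed_post[j_mc:j_hi]))
    # refine the V-shaped minimum with a slope-change fit around it; keep
    # the window clear of the mouth-closure corner and the settle break
    lo5 = max(j_mc + 2, j_min - int(round(2.6 * fs)))
    hi5 = min(n, j_min + int(round(1.4 * fs)))
    grid5 = t[lo5 + 4:hi5 - 4]
    grid5 = grid5[(grid5 > T_MC) & (grid5 <= T_MC + th.t_min_window)]
    if grid5.size >= 2:
        T_min = _hinge_fit(t[lo5:hi5], speed[lo5:hi5], grid5)
    else:
        T_min = float(t[j_min])
    T_min = min(max(T_min, T_MC), T_MC + th.t_min_window)

    # -- distance over the deceleration (trapezoid of raw speed) -----------
    distance = integrate_speed(t, speed, T_MO, T_MC)

    return LungeEvent(
        T_fluke=float(T_fluke), T_accel=float(T_accel), T_max=T_max,
        T_MO=float(T_MO), T_MC=float(T_MC), T_min=T_min,
        U_fluke=u_at(T_fluke), U_accel=u_at(T_accel), U_max=u_at(T_max),
        U_MO=u_at(T_MO), U_MC=u_at(T_MC), U_min=u_at(T_min),
        depth_at_MO=float(np.interp(T_MO, trace.t, trace.depth)),
        distance_decel=distance,
        individual_id=individual_id,
    )


def _tailbeat_period_estimate(
    t, gyro, j_lo: int, j_hi: int, th: DetectionThresholds, fs: float,
    default: float = 4.0,
) -> float:
    """Dominant tailbeat period (s) from gyro lobes over the approach."""
    lo = max(0, j_lo - int(round(3.0 * fs)))
    if j_hi - lo < int(round(2.0 * fs)):
        return default
    gy = _movavg(gyro[lo:j_hi], 0.3, fs)
    lobes = _gyro_lobes(t[lo:j_hi], gy, th.g_thresh / 2.0)
    if len(lobes) < 2:
        return default
    halves = [(lb["stop"] - lb["start"]) / fs for lb in lobes[1:-1]] or \
             [(lb["stop"] - lb["start"]) / fs for lb in lobes]
    period = 2.0 * float(np.median(halves))
    return float(np.clip(period, 1.0, 5.0))


def _fluke_onset(t, gyro, T_accel, th: DetectionThresholds, fs: float) -> float | None:
    """Start of sustained gyro oscillation preceding T_accel."""
    gy = _movavg(gyro, 0.3, fs)
    # Envelope: centered rolling max of |gyro| wide enough to bridge the
    # sub-threshold dips around tailbeat zero crossings.
    win = max(1, int(round(1.5 * fs)))
    env = pd.Series(np.abs(gy)).rolling(win, center=True, min_periods=1).max().to_numpy()
    active = env > th.g_thresh
    j_acc = int(np.searchsorted(t, T_accel))
    j_acc = min(j_acc, t.size - 1)
    if not active[j_acc]:
        later = np.flatnonzero(active[j_acc:])
        if later.size == 0:
            return None
        j_acc = j_acc + later[0]
    j = j_acc
    while j > 0 and active[j - 1]:
        j -= 1
    # Refine: advance to the first true threshold crossing, then step back
    # to where the signal was still inside the noise floor.
    floor = th.g_thresh / 3.0
    k = j
    while k < j_acc and abs(gy[k]) <= th.g_thresh:
        k += 1
    back = k
    while back > j and abs(gy[back - 1]) > floor:
        back -= 1
    # extrapolate the rising oscillation down to zero amplitude
    t_back = float(t[back])
    ahead = back + 3
    if ahead < gy.size and abs(gy[ahead]) > abs(gy[back]):
        slope = (abs(gy[ahead]) - abs(gy[back])) / float(t[ahead] - t[back])
        if slope > 1e-6:
            t_back -= min(0.3, abs(gy[back]) / slope)
    return t_back


# --------------------------------------------------------------------------
# gyro final oscillation


def _gyro_lobes(t, gy, floor: float, max_merge_gap: int = 5) -> list[dict]:
    """Sign-consistent lobes of the smoothed gyro with peak >= floor.

    Adjacent same-sign lobes split by noise micro-crossings are merged,
    but only across gaps of at most ``max_merge_gap`` samples — two
    oscillation bouts separated by a quiet spell stay distinct.
    """
    sign = np.sign(gy)
    sign[sign == 0] = 1
    lobes = []
    for s, e in _runs(sign > 0) + _runs(sign < 0):
        peak = float(np.max(np.abs(gy[s:e])))
        if peak >= floor:
            lobes.append({"start": s, "stop": e, "sign": float(sign[s]), "peak": peak})
    lobes.sort(key=lambda d: d["start"])
    merged: list[dict] = []
    for lobe in lobes:
        if (merged and merged[-1]["sign"] == lobe["sign"]
                and lobe["start"] - merged[-1]["stop"] <= max_merge_gap):
            merged[-1]["stop"] = lobe["stop"]
            merged[-1]["peak"] = max(merged[-1]["peak"], lobe["peak"])
        else:
            merged.append(lobe)
    return merged


def final_oscillation(
    trace: TagTrace,
    lunge: LungeEvent,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> tuple[float, float, float, float] | None:
    """Times (T_gyr1, T_gyr2, T_gyr3) and duration of the final oscillation.

    The final oscillation is the last zero-crossing-bounded full gyro cycle
    (two opposite-sign lobes) whose span intersects [T_MO, T_MC].  Returns
    None when no qualifying cycle exists (the lunge is flagged, not errored).
    """
    th = thresholds
    fs = trace.sample_rate
    gy = _movavg(trace.gyro_y, 0.3, fs)
    t = trace.t
    # Only look from mid-acceleration to a while after mouth closure.
    j0 = int(np.searchsorted(t, lunge.T_accel))
    j1 = int(np.searchsorted(t, lunge.T_MC + 15.0))
    gy = gy[j0:j1]
    tt = t[j0:j1]
    if gy.size < 4:
        return None
    lobes = _gyro_lobes(tt, gy, th.g_thresh / 2.0)
    floor = th.g_thresh / 4.0
    best = None
    for a, b in zip(lobes, lobes[1:]):
        if a["sign"] == b["sign"]:
            continue
        if max(a["peak"], b["peak"]) < th.g_thresh:
            continue
        # the two half-cycles must be contiguous, not separate bouts
        if tt[b["start"]] - tt[a["stop"] - 1] > 0.6:
            continue
        start = _edge_time(tt, gy, a, floor, side="start")
        mid = 0.5 * (tt[a["stop"] - 1] + tt[b["start"]])
        stop = _edge_time(tt, gy, b, floor, side="stop")
        if start <= lunge.T_MC and stop >= lunge.T_MO:
            best = (start, mid, stop)
    if best is None:
        return None
    T_gyr1, T_gyr2, T_gyr3 = best
    return T_gyr1, T_gyr2, T_gyr3, T_gyr3 - T_gyr1


def _edge_time(tt, gy, lobe, floor, side: str) -> float:
    """Outer edge of a lobe: walk from the peak to the noise floor.

    The walk never leaves the lobe's own zero-crossing boundaries, so an
    adjacent oscillation bout cannot be absorbed.
    """
    s, e = lobe["start"], lobe["stop"]
    j_peak = s + int(np.argmax(np.abs(gy[s:e])))
    dt = float(tt[1] - tt[0]) if tt.size > 1 else 0.1
    if side == "start":
        j = j_peak
        while j > s and abs(gy[j - 1]) > floor:
            j -= 1
        edge = float(tt[j])
        if j + 2 < e:   # extrapolate the rise down to zero amplitude
            slope = (abs(gy[j + 2]) - abs(gy[j])) / (2 * dt)
            if slope > 1e-6:
                edge -= min(3 * dt, abs(gy[j]) / slope)
        return max(edge, float(tt[s]) - 3 * dt)
    j = j_peak
    while j < e - 1 and abs(gy[j + 1]) > floor:
        j += 1
    edge = float(tt[j])
    if j - 2 > s:
        slope = (abs(gy[j - 2]) - abs(gy[j])) / (2 * dt)
        if slope > 1e-6:
            edge += min(3 * dt, abs(gy[j]) / slope)
    return min(edge, float(tt[e - 1]) + 3 * dt)


def _attach_final_oscillation(trace: TagTrace, ev: LungeEvent, th: DetectionThresholds) -> None:
    osc = final_oscillation(trace, ev, th)
    if osc is not None:
        ev.T_gyr1, ev.T_gyr2, ev.T_gyr3, _ = osc


def tailbeat_periods(
    trace: TagTrace,
    lunge: LungeEvent,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> TailbeatRecord:
    """Per-beat periods between T_fluke and T_gyr1, final oscillation last.

    Periods are taken between successive same-direction zero crossings of
    the smoothed gyro.
    """
    th = thresholds
    fs = trace.sample_rate
    gy = _movavg(trace.gyro_y, 0.3, fs)
    t = trace.t
    t_end = lunge.T_gyr1 if lunge.T_gyr1 is not None else lunge.T_MO
    j0 = int(np.searchsorted(t, lunge.T_fluke))
    j1 = int(np.searchsorted(t, t_end))
    lobes = _gyro_lobes(t[j0:j1], gy[j0:j1], th.g_thresh / 2.0)
    # a full beat spans two adjacent opposite-sign lobes
    periods = []
    for a, b in zip(lobes, lobes[1:]):
        if a["sign"] != b["sign"]:
            p = float(t[j0:j1][b["stop"] - 1] - t[j0:j1][a["start"]])
            if p > 0:
                periods.append(p)
    if lunge.dT_finOs is not None:
        periods.append(lunge.dT_finOs)
    return TailbeatRecord(lunge=lunge, periods=periods)


# --------------------------------------------------------------------------
# sampling


def sample_middle_lunges(
    events: Sequence[LungeEvent], n: int = 30, seed: int | None = None
) -> list[LungeEvent]:
    """Uniform sample without replacement of "middle" lunges.

    Middle lunges are those that are neither first, last nor solitary in
    their dive.  Returns all of them when fewer than ``n`` exist.
    """
    middle = [ev for ev in events if ev.position_in_dive == "middle"]
    if not middle:
        warnings.warn("no middle lunges available to sample", stacklevel=2)
        return []
    if len(middle) <= n:
        return sorted(middle, key=lambda ev: ev.T_MO)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(middle), size=n, replace=False)
    return sorted((middle[i] for i in idx), key=lambda ev: ev.T_MO)


_STABILITY_PARAMS = ("U_MO", "U_MC", "U_max", "dT_accel", "dT_adjust", "dT_decel")


def sample_size_stability(
    events: Sequence[LungeEvent],
    sizes: Sequence[int],
    replicates: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stability of kinematic means against random sample size.

    For each requested size, draws ``replicates`` random subsets of middle
    lunges and reports the mean and between-replicate sd of each kinematic
    parameter's subset mean.  Sizes beyond the available pool are capped
    with a warning.
    """
    middle = [ev for ev in events if ev.position_in_dive == "middle"]
    pool = len(middle)
    if pool == 0:
        raise SegmentationError("no middle lunges available")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        eff = min(size, pool)
        if eff < size:
            warnings.warn(f"sample size {size} capped at pool size {pool}", stacklevel=2)
        means = {p: [] for p in _STABILITY_PARAMS}
        for _ in range(replicates):
            idx = rng.choice(pool, size=eff, replace=False)
            for p in _STABILITY_PARAMS:
                means[p].append(float(np.mean([getattr(middle[i], p) for i in idx])))
        for p in _STABILITY_PARAMS:
            arr = np.asarray(means[p])
            rows.append({
                "size": size,
                "effective_size": eff,
                "parameter": p,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if replicates > 1 else float("nan"),
            })
    return pd.DataFrame(rows)
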