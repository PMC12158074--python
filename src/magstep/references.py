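"""Reference step-width definitions from 3-D marker trajectories.

Three optical reference methods, each sampling "step width" differently:

* initial contact - perpendicular distance from the contralateral initial
  contact to the line joining two subsequent same-foot initial contacts,
  computed on belt-motion-compensated ground-plane positions;
* mid-swing - mediolateral heel separation at the instant the swing foot
  passes the stance foot, detected as crossings of the forward components;
* shank clearance - the device-level twin of the magnetic pipeline: OMC
  distances between the device centroids fed through the same two-stage
  event detection and triangle solution.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.ndimage import minimum_filter1d

from .containers import (
    FORWARD_CROSSING,
    INITIAL_CONTACT,
    LEFT,
    RIGHT,
    UNKNOWN,
    DistanceSeries,
    GaitEvent,
    StepWidthSeries,
    TrajectorySet,
)
from .errors import ValidationError
from .events import EventParams, extract_events
from .geometry import DeviceGeometry, solve_triangle_series

logger = logging.getLogger(__name__)

__all__ = [
    "rigid_body_centroid",
    "omc_distances",
    "detect_initial_contacts",
    "step_width_initial_contact",
    "detect_forward_crossings",
    "step_width_mid_swing",
    "step_width_shank_clearance",
    "trim_to_equal_sides",
]


def rigid_body_centroid(cluster: Sequence[np.ndarray]) -> np.ndarray:
    """Per-sample arithmetic mean of a cluster of marker trajectories.

    The centroid of the reflective-marker rigid body serves as the device
    position proxy.
    """
    if len(cluster) == 0:
        raise ValidationError("rigid_body_centroid: empty cluster")
    arrs = [np.asarray(c, dtype=float) for c in cluster]
    return np.mean(arrs, axis=0)


def omc_distances(traj: TrajectorySet, da: float) -> DistanceSeries:
    """Optical twin of the magnetic distance estimates.

    d_lower(n) = |A0(n) - S0(n)|, d_upper(n) = |A0(n) - S1(n)|.  The
    baseline ``da`` comes from the device configuration, not from the data.
    """
    traj.require("A0", "S0", "S1")
    a0 = traj.markers["A0"]
    d_lower = np.linalg.norm(a0 - traj.markers["S0"], axis=1)
    d_upper = np.linalg.norm(a0 - traj.markers["S1"], axis=1)
    return DistanceSeries(fs=traj.fs, d_lower=d_lower, d_upper=d_upper, da=da, t0=traj.t0)


def _plateau_minima(
    x: np.ndarray, half: int, min_prominence: float | None
) -> list[int]:
    """Non-strict windowed minima with plateau collapsing.

    Candidates attain the min of their +/-half window; each maximal run of
    adjacent candidates collapses to its (floor) midpoint.  Remaining
    candidates are accepted greedily left-to-right with spacing > half
    (earliest-tie policy).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    size = 2 * half + 1
    wmin = minimum_filter1d(x, size=size, mode="nearest")
    cand = np.flatnonzero(x == wmin)
    if len(cand) == 0:
        return []
    runs: list[tuple[int, int]] = []
    run_start = prev = cand[0]
    for k in cand[1:]:
        if k == prev + 1:
            prev = k
            continue
        runs.append((int(run_start), int(prev)))
        run_start = prev = k
    runs.append((int(run_start), int(prev)))
    out: list[int] = []
    for lo, hi in runs:
        if lo == hi and (lo == 0 or lo == n - 1):
            continue  # single boundary sample: no flank to verify
        k = (lo + hi) // 2
        if min_prominence is not None:
            # prominence over the plateau extent plus half a window each side,
            # so plateaus longer than the window are still accepted
            a = max(0, lo - half)
            b = min(n, hi + half + 1)
            if np.max(x[a:b]) - x[k] < min_prominence:
                continue
        if out and k - out[-1] <= half:
            continue
        out.append(k)
    return out


def detect_initial_contacts(
    traj: TrajectorySet,
    foot: str,
    spacing: float = 0.5,
    min_prominence: float | None = 0.005,
) -> list[GaitEvent]:
    """Initial contacts from windowed minima of the heel vertical component.

    During stance the heel height sits on a flat plateau; each plateau (or
    point minimum) yields one event at its centre.  The default 5 mm
    prominence guard suppresses jitter on flat segments.
    """
    if foot not in (LEFT, RIGHT):
        raise ValidationError(f"foot must be 'left' or 'right', got {foot!r}")
    name = "heel_L" if foot == LEFT else "heel_R"
    traj.require(name)
    z = traj.markers[name][:, 2]
    half = int(round(spacing * traj.fs))
    idx = _plateau_minima(z, half, min_prominence)
    return [
        GaitEvent(kind=INITIAL_CONTACT, k=k, time=traj.t0 + k / traj.fs, side=foot)
        for k in idx
    ]


def _compensated_ground(traj: TrajectorySet, name: str) -> np.ndarray:
    """Ground-plane (x, y) positions with belt motion added back to x."""
    m = traj.markers[name]
    t = traj.times
    x = m[:, 0] + traj.belt_speed * (t - traj.t0)
    return np.column_stack([x, m[:, 1]])


def point_line_distance(p1: np.ndarray, p2: np.ndarray, q: np.ndarray) -> float:
    """Perpendicular distance from q to the line through p1, p2 (2-D)."""
    d = np.asarray(p2, float) - np.asarray(p1, float)
    r = np.asarray(q, float) - np.asarray(p1, float)
    norm = float(np.hypot(d[0], d[1]))
    if norm == 0.0:
        raise ValidationError("degenerate stride: p1 == p2")
    return abs(d[0] * r[1] - d[1] * r[0]) / norm


def step_width_initial_contact(
    traj: TrajectorySet,
    ic_left: list[GaitEvent],
    ic_right: list[GaitEvent],
    simplified: bool = False,
    min_stride: float = 1e-3,
) -> StepWidthSeries:
    """Initial-contact step width.

    For each pair of subsequent same-foot initial contacts at compensated
    ground positions P1, P2 bracketing exactly one contralateral contact at
    Q: stride = |P2 - P1| and width = perpendicular distance from Q to the
    line P1-P2.  With ``simplified=True`` the line of progression is assumed
    to point forward and width = |y_Q - (y_P1 + y_P2) / 2|.  Pairs without
    exactly one intermediate contralateral contact, and degenerate strides
    (< ``min_stride``), are skipped with a logged count.  Each width is an
    event of the contralateral (Q) foot.
    """
    pos = {
        LEFT: _compensated_ground(traj, "heel_L"),
        RIGHT: _compensated_ground(traj, "heel_R"),
    }
    results: list[tuple[GaitEvent, float]] = []
    n_skipped = 0
    for same, other in ((ic_left, ic_right), (ic_right, ic_left)):
        for e1, e2 in zip(same, same[1:]):
            between = [q for q in other if e1.time < q.time < e2.time]
            if len(between) != 1:
                n_skipped += 1
                continue
            q_ev = between[0]
            p1 = pos[e1.side][int(e1.k)]
            p2 = pos[e2.side][int(e2.k)]
            q = pos[q_ev.side][int(q_ev.k)]
            stride = float(np.hypot(*(p2 - p1)))
            if stride < min_stride:
                n_skipped += 1
                continue
            if simplified:
                width = abs(q[1] - 0.5 * (p1[1] + p2[1]))
            else:
                width = point_line_distance(p1, p2, q)
            ev = GaitEvent(kind=INITIAL_CONTACT, k=q_ev.k, time=q_ev.time, side=q_ev.side)
            results.append((ev, width))
    if n_skipped:
        logger.info("step_width_initial_contact: skipped %d pairs", n_skipped)
    results.sort(key=lambda r: r[0].time)
    return StepWidthSeries(
        method="initial_contact",
        events=[r[0] for r in results],
        widths=np.array([r[1] for r in results], dtype=float),
    )


def detect_forward_crossings(traj: TrajectorySet) -> list[GaitEvent]:
    """Crossings of the two heel forward components (mid-swing events).

    In the raw treadmill frame the stance foot drifts backward while the
    swing foot advances, so the forward components x_L(n) and x_R(n) cross
    once per step.  The crossing index is fractional (linear interpolation
    between the bracketing samples); the side is the foot with the greater
    forward velocity at the crossing (the swing foot).
    """
    traj.require("heel_L", "heel_R")
    x_l = traj.markers["heel_L"][:, 0]
    x_r = traj.markers["heel_R"][:, 0]
    g = x_l - x_r
    s = np.sign(g)
    events: list[GaitEvent] = []

    def _side_at(k: int) -> str:
        lo = max(0, k - 1)
        hi = min(len(g) - 1, k + 1)
        v_l = x_l[hi] - x_l[lo]
        v_r = x_r[hi] - x_r[lo]
        if v_l > v_r:
            return LEFT
        if v_r > v_l:
            return RIGHT
        return UNKNOWN

    nz = np.flatnonzero(s != 0)
    if len(nz) == 0:
        return []
    # leading / trailing zero runs adjacent to a nonzero sample count as
    # crossings at the first zero of the run
    if nz[0] > 0:
        events.append(GaitEvent(kind=FORWARD_CROSSING, k=0.0,
                                time=traj.t0, side=_side_at(0)))
    for i, j in zip(nz, nz[1:]):
        if s[i] == s[j]:
            continue
        if j == i + 1:
            frac = i + g[i] / (g[i] - g[j])
        else:
            frac = float(i + 1)  # first sample of the exact-zero run
        events.append(GaitEvent(
            kind=FORWARD_CROSSING,
            k=float(frac),
            time=traj.t0 + frac / traj.fs,
            side=_side_at(int(round(frac))),
        ))
    return events


def _interp_at(series: np.ndarray, frac: float) -> float:
    i = int(np.floor(frac))
    i = min(max(i, 0), len(series) - 1)
    f = frac - i
    if f <= 0 or i + 1 >= len(series):
        return float(series[i])
    return float((1.0 - f) * series[i] + f * series[i + 1])


def step_width_mid_swing(traj: TrajectorySet, crossings: list[GaitEvent]) -> StepWidthSeries:
    """Mediolateral heel separation sampled at each forward crossing.

    width = |y_L - y_R| and dz = |z_L - z_R|, both linearly interpolated at
    the fractional crossing index.
    """
    traj.require("heel_L", "heel_R")
    y_l = traj.markers["heel_L"][:, 1]
    y_r = traj.markers["heel_R"][:, 1]
    z_l = traj.markers["heel_L"][:, 2]
    z_r = traj.markers["heel_R"][:, 2]
    widths = [abs(_interp_at(y_l, ev.k) - _interp_at(y_r, ev.k)) for ev in crossings]
    dz = [abs(_interp_at(z_l, ev.k) - _interp_at(z_r, ev.k)) for ev in crossings]
    return StepWidthSeries(
        method="mid_swing",
        events=list(crossings),
        widths=np.array(widths, dtype=float),
        dz=np.array(dz, dtype=float),
    )


def step_width_shank_clearance(
    traj: TrajectorySet,
    geometry: DeviceGeometry | None = None,
    params: EventParams | None = None,
) -> StepWidthSeries:
    """Device-level reference: OMC distances through the magnetic pipeline."""
    geom = geometry or DeviceGeometry()
    ds = omc_distances(traj, da=geom.da)
    evs = extract_events(ds, params)
    return solve_triangle_series(ds, evs, method="shank_clearance")


def trim_to_equal_sides(sw: StepWidthSeries) -> StepWidthSeries:
    """Remove surplus trailing events so left and right counts are equal.

    Implemented as the longest balanced prefix (the minimal trailing-suffix
    removal achieving balance).  Pathological side sequences that admit no
    balanced prefix reduce to an empty series with a warning.
    """
    n_l = n_r = 0
    best = 0
    for i, ev in enumerate(sw.events):
        if ev.side == LEFT:
            n_l += 1
        elif ev.side == RIGHT:
            n_r += 1
        if n_l == n_r:
            best = i + 1
    dropped = len(sw) - best
    if dropped:
        level = logging.WARNING if best == 0 and len(sw) else logging.INFO
        logger.log(level, "trim_to_equal_sides: dropped %d trailing events", dropped)
    return sw.subset(np.arange(best))
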