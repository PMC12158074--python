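"""Triangle geometry separating mediolateral from vertical shank distance.

The device carries two sensors S0 (lower) and S1 (upper) on one shank, a
known vertical baseline ``da`` apart, and one actuator A0 on the other shank.
At a gait event the measured distances db = |A0-S0| and dc = |A0-S1| form a
triangle with da.  The law of cosines gives the angle beta at S1,

    beta = arccos((da^2 + dc^2 - db^2) / (2 da dc)),

from which the height of the triangle perpendicular to da,

    dy = dc sin(beta),

is the mediolateral distance (the step-width proxy), and

    dz = da/2 - dc cos(beta)

is the signed vertical shift of A0 relative to the S0-S1 midpoint (positive
upward).  Both the beta < 90 deg and beta > 90 deg configurations are covered
by the same formulas since sin(pi - beta) = sin(beta).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .containers import GaitEvent, REFINED_PAIR, StepWidthSeries, DistanceSeries
from .errors import InvalidGeometryError, TriangleViolationError

logger = logging.getLogger(__name__)

__all__ = [
    "DeviceGeometry",
    "TriangleSolution",
    "solve_triangle",
    "solve_triangle_series",
]


@dataclass(frozen=True)
class DeviceGeometry:
    """Fixed device geometry.

    Parameters
    ----------
    da : float
        Inter-sensor baseline S0-S1 in metres (default 0.10).
    sensor_height : float
        Height of the lower sensor above the heel marker in metres
        (default 0.05).  The actuator is centred between the two sensors, so
        its mounting height is ``sensor_height + da / 2``.
    """

    da: float = 0.10
    sensor_height: float = 0.05

    def __post_init__(self) -> None:
        if not self.da > 0:
            raise InvalidGeometryError(f"da must be positive, got {self.da}")
        if self.sensor_height < 0:
            raise InvalidGeometryError(
                f"sensor_height must be non-negative, got {self.sensor_height}"
            )

    @property
    def actuator_height(self) -> float:
        return self.sensor_height + self.da / 2


@dataclass(frozen=True)
class TriangleSolution:
    """Solved triangle: angle at S1 and the separated distance components."""

    beta: float  # rad, in [0, pi]
    dy: float    # m, >= 0 (height perpendicular to da)
    dz: float    # m, signed vertical shift of A0 vs the S0-S1 midpoint


def solve_triangle(da: float, db: float, dc: float, tol: float = 1e-6) -> TriangleSolution:
    """Separate mediolateral (dy) and vertical (dz) components of a distance pair.

    Parameters
    ----------
    da : float
        Inter-sensor baseline S0-S1 (m).
    db : float
        Lower distance A0-S0 (m).
    dc : float
        Upper distance A0-S1 (m).
    tol : float
        Relative tolerance on the arccos argument: values within ``tol`` of
        +/-1 are clamped (measurement noise can push near-collinear triples
        slightly outside validity); values beyond raise
        :class:`TriangleViolationError`.

    Returns
    -------
    TriangleSolution
        beta in [0, pi]; dy >= 0; dz positive for upward shifts of A0.
    """
    if not (da > 0 and db > 0 and dc > 0):
        raise InvalidGeometryError(
            f"all sides must be positive: da={da}, db={db}, dc={dc}"
        )
    arg = (da * da + dc * dc - db * db) / (2.0 * da * dc)
    if arg > 1.0 + tol or arg < -1.0 - tol:
        raise TriangleViolationError(
            f"triangle inequality violated beyond tolerance: "
            f"da={da}, db={db}, dc={dc} (arccos argument {arg:.9g})"
        )
    arg = min(1.0, max(-1.0, arg))
    beta = math.acos(arg)
    dy = dc * math.sin(beta)
    dz = da / 2.0 - dc * math.cos(beta)
    return TriangleSolution(beta=beta, dy=dy, dz=dz)


def solve_triangle_series(
    ds: DistanceSeries,
    events: list[GaitEvent],
    method: str = "magnetic",
    tol: float = 1e-6,
) -> StepWidthSeries:
    """Apply :func:`solve_triangle` at each refined minima pair.

    Each event supplies the lower distance at its ``k_lower`` index and the
    upper distance at its ``k_upper`` index.  Events whose distance triple
    fails the triangle check are excluded and counted in ``n_flagged`` (with
    a log record), not silently dropped.  An empty event list yields an empty
    series.
    """
    kept: list[GaitEvent] = []
    widths: list[float] = []
    dz: list[float] = []
    n_flagged = 0
    for ev in events:
        if ev.kind != REFINED_PAIR or ev.k_lower is None or ev.k_upper is None:
            raise InvalidGeometryError(
                f"solve_triangle_series requires refined_pair events, got {ev.kind!r}"
            )
        db = float(ds.d_lower[ev.k_lower])
        dc = float(ds.d_upper[ev.k_upper])
        try:
            sol = solve_triangle(ds.da, db, dc, tol=tol)
        except (TriangleViolationError, InvalidGeometryError) as exc:
            n_flagged += 1
            logger.warning("event at t=%.3f s flagged: %s", ev.time, exc)
            continue
        kept.append(ev)
        widths.append(sol.dy)
        dz.append(sol.dz)
    if n_flagged:
        logger.info("solve_triangle_series: %d of %d events flagged and excluded",
                    n_flagged, len(events))
    return StepWidthSeries(
        method=method,
        events=kept,
        widths=np.array(widths, dtype=float),
        dz=np.array(dz, dtype=float),
        n_flagged=n_flagged,
    )
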