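"""Shared in-memory containers for the step-width pipeline.

Everything is SI internally: metres, seconds, radians.  Sample indices are
0-based; times in seconds are the exchange currency between modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: Side labels used throughout.  ``unknown`` is a flag, never an exception.
LEFT = "left"
RIGHT = "right"
UNKNOWN = "unknown"

#: Event kinds.
PRIMARY_MIN = "primary_min"
REFINED_PAIR = "refined_pair"
INITIAL_CONTACT = "initial_contact"
FORWARD_CROSSING = "forward_crossing"


@dataclass
class DistanceSeries:
    """Paired lower/upper distance signals sharing one time base.

    ``d_lower`` is the actuator-to-lower-sensor distance (A0-S0) and
    ``d_upper`` the actuator-to-upper-sensor distance (A0-S1); ``da`` is the
    fixed inter-sensor baseline S0-S1, known a priori from the device, not
    from data.
    """

    fs: float
    d_lower: np.ndarray
    d_upper: np.ndarray
    da: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.d_lower = np.asarray(self.d_lower, dtype=float)
        self.d_upper = np.asarray(self.d_upper, dtype=float)
        if self.d_lower.ndim != 1 or self.d_upper.ndim != 1:
            raise ValidationError("distance signals must be 1-D")
        if len(self.d_lower) != len(self.d_upper):
            raise ValidationError(
                f"d_lower and d_upper lengths differ: "
                f"{len(self.d_lower)} vs {len(self.d_upper)}"
            )
        if len(self.d_lower) < 2:
            raise ValidationError("distance series needs at least 2 samples")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not self.da > 0:
            raise ValidationError(f"inter-sensor baseline da must be positive, got {self.da}")
        for name, d in (("d_lower", self.d_lower), ("d_upper", self.d_upper)):
            if not np.all(np.isfinite(d)):
                raise ValidationError(f"{name} contains non-finite samples")
            if not np.all(d > 0):
                k = int(np.flatnonzero(d <= 0)[0])
                raise ValidationError(f"{name}[{k}] = {d[k]} is not positive")

    @property
    def n(self) -> int:
        return len(self.d_lower)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class GaitEvent:
    """A detected time point with a side label.

    ``k`` is the sample index on the owning series; fractional for
    interpolated forward crossings, integer otherwise.  For refined minima
    pairs, ``k`` is the primary (low-pass) minimum and ``k_lower``/``k_upper``
    the per-channel refined indices.
    """

    kind: str
    k: float
    time: float
    side: str = UNKNOWN
    k_lower: int | None = None
    k_upper: int | None = None


@dataclass
class StepWidthSeries:
    """Per-event step widths (m) with side labels and a method tag.

    ``method`` is one of ``initial_contact``, ``mid_swing``,
    ``shank_clearance``, ``magnetic``.  ``dz`` carries the vertical component
    where the method defines one.  ``n_flagged`` counts events excluded by
    downstream geometry checks (logged, never silently dropped).
    """

    method: str
    events: list[GaitEvent]
    widths: np.ndarray
    dz: np.ndarray | None = None
    n_flagged: int = 0

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if len(self.events) != len(self.widths):
            raise ValidationError(
                f"events ({len(self.events)}) and widths ({len(self.widths)}) "
                "must have equal length"
            )
        if self.dz is not None:
            self.dz = np.asarray(self.dz, dtype=float)
            if len(self.dz) != len(self.widths):
                raise ValidationError("dz and widths must have equal length")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def sides(self) -> list[str]:
        return [e.side for e in self.events]

    def subset(self, idx) -> "StepWidthSeries":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return StepWidthSeries(
            method=self.method,
            events=[self.events[int(i)] for i in idx],
            widths=self.widths[idx],
            dz=None if self.dz is None else self.dz[idx],
            n_flagged=self.n_flagged,
        )


@dataclass
class TrajectorySet:
    """Synchronized 3-D marker trajectories in the treadmill frame.

    Frame convention: x forward (direction of progression), y mediolateral,
    z vertical up, origin on the belt surface.  ``markers`` maps a marker (or
    device-centroid) name to an (n, 3) array in metres.
    """

    fs: float
    markers: dict[str, np.ndarray]
    belt_speed: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not self.markers:
            raise ValidationError("trajectory set has no markers")
        n = None
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"marker {name!r} must be an (n, 3) array")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValidationError(
                    f"marker {name!r} length {arr.shape[0]} differs from {n}"
                )
            self.markers[name] = arr

    @property
    def n(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def require(self, *names: str) -> None:
        missing = [m for m in names if m not in self.markers]
        if missing:
            raise ValidationError(f"missing required markers: {missing}")
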