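"""Signal conditioning and two-stage gait-event detection.

Mid-swing events are found in two stages.  First the two distance channels
are averaged sample-by-sample and low-pass filtered (2 Hz, 2nd-order
Butterworth, zero-phase); strict windowed minima of this auxiliary signal,
at least 500 ms apart, are the primary events.  Second, the per-channel
minima are refined on the unfiltered signals (full tracking bandwidth)
within +/-100 ms of each primary event.  Comparing the refined minimum
values classifies the step side: during a right swing the actuator passes
the upper sensor more closely than the lower one, and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import butter, filtfilt

from .containers import (
    LEFT,
    PRIMARY_MIN,
    REFINED_PAIR,
    RIGHT,
    UNKNOWN,
    DistanceSeries,
    GaitEvent,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EventParams",
    "zero_phase_lowpass",
    "lowpass_average",
    "detect_primary_minima",
    "refine_minima",
    "classify_side",
    "extract_events",
]


@dataclass(frozen=True)
class EventParams:
    """Tunables of the two-stage detection.

    ``spacing`` and ``refine_window`` are half-widths in seconds of the
    primary search window (N0 samples) and the refinement window (N1
    samples).  ``min_prominence`` (m) discards primary minima whose window
    does not rise at least that much above the minimum; it suppresses
    spurious noise minima on quasi-constant signals (e.g. standing) and is
    harmless during gait, where the window swing is tens of centimetres.
    """

    cutoff: float = 2.0
    order: int = 2
    spacing: float = 0.5
    refine_window: float = 0.1
    min_prominence: float | None = 0.01
    boundary: str = "truncate"  # or "discard"
    enforce_alternation: bool = True


def zero_phase_lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    """Forward-backward Butterworth low-pass (no phase shift, squared magnitude).

    Edge transients use Gustafsson's method (initial conditions chosen so
    forward-then-backward equals backward-then-forward), which makes the
    output exactly time-reversal equivariant - the property the two-stage
    detection relies on near the series ends.
    """
    x = np.asarray(x, dtype=float)
    min_len = 6 * (order + 1)
    if len(x) <= min_len:
        raise ValidationError(
            f"series of length {len(x)} too short for zero-phase filtering "
            f"(needs > {min_len} samples)"
        )
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, x, method="gust")


def lowpass_average(ds: DistanceSeries, cutoff: float = 2.0, order: int = 2) -> np.ndarray:
    """Zero-phase low-pass of the sample-wise mean of the two channels."""
    mean = 0.5 * (ds.d_lower + ds.d_upper)
    return zero_phase_lowpass(mean, ds.fs, cutoff, order)


def _strict_windowed_minima(
    x: np.ndarray,
    half: int,
    boundary: str = "truncate",
    min_prominence: float | None = None,
) -> list[int]:
    """Indices k with x[k] < x[n] for all n in [k-half, k+half], n != k.

    Windows are truncated at the series ends under the default boundary
    policy; ``boundary='discard'`` drops events whose full window does not
    fit.  Two strict minima are necessarily more than ``half`` samples
    apart.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    size = 2 * half + 1
    # mode="nearest" replicates edge samples, which leaves the window min
    # identical to the truncated-window min.
    wmin = minimum_filter1d(x, size=size, mode="nearest")
    if min_prominence is not None:
        wmax = maximum_filter1d(x, size=size, mode="nearest")
    out: list[int] = []
    for k in np.flatnonzero(x == wmin):
        if k == 0 or k == n - 1:
            continue  # an endpoint cannot be verified as a minimum
        lo = max(0, k - half)
        hi = min(n, k + half + 1)
        if np.count_nonzero(x[lo:hi] == x[k]) != 1:
            continue  # tied minimum: not strict
        if boundary == "discard" and (k - half < 0 or k + half >= n):
            continue
        if min_prominence is not None and wmax[k] - x[k] < min_prominence:
            continue
        out.append(int(k))
    return out


def detect_primary_minima(
    dlp: np.ndarray,
    fs: float,
    spacing: float = 0.5,
    boundary: str = "truncate",
    min_prominence: float | None = None,
    t0: float = 0.0,
) -> list[GaitEvent]:
    """Strict minima of the low-pass signal over a +/-N0 window.

    N0 = round(spacing * fs) is the half-width of the symmetric search
    window, which simultaneously enforces the minimum spacing between
    events.  Ties (equal values within one window) leave no strict minimum.
    """
    half = int(round(spacing * fs))
    if half < 1:
        raise ValidationError(f"spacing {spacing} s at fs {fs} Hz gives empty window")
    idx = _strict_windowed_minima(np.asarray(dlp, float), half, boundary, min_prominence)
    return [
        GaitEvent(kind=PRIMARY_MIN, k=k, time=t0 + k / fs) for k in idx
    ]


def refine_minima(ds: DistanceSeries, primary: GaitEvent, window: float = 0.1) -> GaitEvent:
    """Per-channel argmin on the raw signals within +/-N1 of a primary event.

    The comparison is non-strict; ties break toward the earlier index
    (``np.argmin`` semantics).  The window is clipped to the series bounds.
    """
    half = int(round(window * ds.fs))
    ki = int(primary.k)
    lo = max(0, ki - half)
    hi = min(ds.n, ki + half + 1)
    k_lower = lo + int(np.argmin(ds.d_lower[lo:hi]))
    k_upper = lo + int(np.argmin(ds.d_upper[lo:hi]))
    return GaitEvent(
        kind=REFINED_PAIR,
        k=ki,
        time=ds.t0 + ki / ds.fs,
        k_lower=k_lower,
        k_upper=k_upper,
    )


def classify_side(ds: DistanceSeries, ev: GaitEvent) -> str:
    """Step side from the refined minimum values.

    The swinging shank carries the actuator past the sensor bar: during a
    right swing the upper distance dips lower than the lower distance, and
    conversely.  Exact equality is labelled ``unknown``.
    """
    if ev.k_lower is None or ev.k_upper is None:
        raise ValidationError("classify_side requires a refined_pair event")
    v_lower = ds.d_lower[ev.k_lower]
    v_upper = ds.d_upper[ev.k_upper]
    if v_upper < v_lower:
        return RIGHT
    if v_lower < v_upper:
        return LEFT
    return UNKNOWN


def _event_depth(ds: DistanceSeries, ev: GaitEvent) -> float:
    return float(min(ds.d_lower[ev.k_lower], ds.d_upper[ev.k_upper]))


def extract_events(ds: DistanceSeries, params: EventParams | None = None) -> list[GaitEvent]:
    """Full two-stage detection: low-pass average, primary minima, refinement,
    side classification, and alternation enforcement.

    When two consecutive events share a side, the weaker minimum (larger
    refined minimum value) is dropped; unknown-side events are dropped before
    enforcement.  Dropped counts are logged.  Events are returned in
    chronological order.
    """
    p = params or EventParams()
    dlp = lowpass_average(ds, cutoff=p.cutoff, order=p.order)
    primaries = detect_primary_minima(
        dlp, ds.fs, spacing=p.spacing, boundary=p.boundary,
        min_prominence=p.min_prominence, t0=ds.t0,
    )
    events = [refine_minima(ds, ev, window=p.refine_window) for ev in primaries]
    for ev in events:
        ev.side = classify_side(ds, ev)
    if not p.enforce_alternation:
        return events

    n_unknown = sum(1 for ev in events if ev.side == UNKNOWN)
    events = [ev for ev in events if ev.side != UNKNOWN]
    kept: list[GaitEvent] = []
    n_dropped = 0
    for ev in events:
        if kept and kept[-1].side == ev.side:
            n_dropped += 1
            if _event_depth(ds, ev) < _event_depth(ds, kept[-1]):
                kept[-1] = ev  # new event is the stronger minimum
        else:
            kept.append(ev)
    if n_unknown or n_dropped:
        logger.info(
            "extract_events: dropped %d unknown-side and %d same-side events "
            "(%d retained)", n_unknown, n_dropped, len(kept),
        )
    return kept
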