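"""End-to-end convenience: distance signals to a step-width series."""

from __future__ import annotations

from .containers import DistanceSeries, StepWidthSeries
from .events import EventParams, extract_events
from .geometry import solve_triangle_series
from .references import trim_to_equal_sides

__all__ = ["estimate_step_width"]


def estimate_step_width(
    ds: DistanceSeries,
    params: EventParams | None = None,
    trim: bool = True,
) -> StepWidthSeries:
    """Magnetic pipeline: two-stage event detection, triangle solution,
    optional trailing-step trimming to equal left/right counts."""
    events = extract_events(ds, params)
    sw = solve_triangle_series(ds, events, method="magnetic")
    return trim_to_equal_sides(sw) if trim else sw
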