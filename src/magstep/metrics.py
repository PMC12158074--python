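"""Validation metrics: per-participant errors and cross-participant averaging.

For paired (estimate, reference) step series the signed error e = est - ref
is summarised by its mean (bias) and sample standard deviation (precision),
by MAE and RMSE (accuracy), by the Spearman correlation (rank agreement),
and by MAE-VAR, the absolute difference between the step-width standard
deviations of the two series (variability agreement).  Aggregation across
participants weights by step count and uses the arithmetic mean for bias,
MAE, SCC and MAE-VAR but the root-mean-square for SD and RMSE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import LEFT, RIGHT, StepWidthSeries
from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSteps",
    "MetricSet",
    "pair_events",
    "paired_steps",
    "error_metrics",
    "timing_metrics",
    "aggregate_participants",
    "subset_by_side",
    "metrics_frame",
]


@dataclass
class PairedSteps:
    """One-to-one matched estimate/reference step widths and times (SI)."""

    est: np.ndarray
    ref: np.ndarray
    est_t: np.ndarray
    ref_t: np.ndarray
    sides: list[str]
    n_unmatched: int = 0

    def __post_init__(self) -> None:
        self.est = np.asarray(self.est, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        self.est_t = np.asarray(self.est_t, dtype=float)
        self.ref_t = np.asarray(self.ref_t, dtype=float)
        n = len(self.est)
        if not (len(self.ref) == len(self.est_t) == len(self.ref_t) == len(self.sides) == n):
            raise ValidationError("paired series must have equal lengths")

    def __len__(self) -> int:
        return len(self.est)


@dataclass
class MetricSet:
    """Error summary for one participant/subset.  Spatial fields in m (or ms
    for timing), SCC dimensionless; NaN marks an undefined metric."""

    bias: float
    sd: float
    mae: float
    rmse: float
    scc: float
    mae_var: float
    n_steps: int


def pair_events(
    est_t: np.ndarray, ref_t: np.ndarray, tol: float = 0.25
) -> tuple[list[tuple[int, int]], int]:
    """Greedy nearest-in-time one-to-one matching within ``tol`` seconds.

    Returns the matched (estimate index, reference index) pairs sorted by
    estimate time, and the number of unmatched events (both lists counted).
    """
    est_t = np.asarray(est_t, dtype=float)
    ref_t = np.asarray(ref_t, dtype=float)
    cands: list[tuple[float, int, int]] = []
    for i, te in enumerate(est_t):
        dt = np.abs(ref_t - te)
        for j in np.flatnonzero(dt <= tol):
            cands.append((float(dt[j]), i, int(j)))
    cands.sort()
    used_e: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cands:
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        pairs.append((i, j))
    pairs.sort()
    n_unmatched = (len(est_t) - len(pairs)) + (len(ref_t) - len(pairs))
    return pairs, n_unmatched


def paired_steps(
    est: StepWidthSeries, ref: StepWidthSeries, tol: float = 0.25
) -> PairedSteps:
    """Pair two step-width series by event time and collect matched widths."""
    pairs, n_unmatched = pair_events(est.times, ref.times, tol=tol)
    if n_unmatched:
        logger.info("paired_steps: %d unmatched events excluded", n_unmatched)
    ei = [p[0] for p in pairs]
    ri = [p[1] for p in pairs]
    return PairedSteps(
        est=est.widths[ei],
        ref=ref.widths[ri],
        est_t=est.times[ei],
        ref_t=ref.times[ri],
        sides=[est.events[i].side for i in ei],
        n_unmatched=n_unmatched,
    )


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("Spearman correlation undefined on constant series; reported as NaN")
        return float("nan")
    rho = spearmanr(a, b).statistic
    return float(rho)


def error_metrics(p: PairedSteps) -> MetricSet:
    """Spatial error metrics (m) on matched step widths."""
    if len(p) < 2:
        raise InsufficientDataError(f"need at least 2 paired steps, got {len(p)}")
    e = p.est - p.ref
    return MetricSet(
        bias=float(np.mean(e)),
        sd=float(np.std(e, ddof=1)),
        mae=float(np.mean(np.abs(e))),
        rmse=float(np.sqrt(np.mean(e * e))),
        scc=_spearman(p.est, p.ref),
        mae_var=float(abs(np.std(p.est, ddof=1) - np.std(p.ref, ddof=1))),
        n_steps=len(p),
    )


def timing_metrics(p: PairedSteps) -> MetricSet:
    """Temporal error metrics in ms on matched event times."""
    if len(p) < 2:
        raise InsufficientDataError(f"need at least 2 paired events, got {len(p)}")
    e = (p.est_t - p.ref_t) * 1e3
    return MetricSet(
        bias=float(np.mean(e)),
        sd=float(np.std(e, ddof=1)),
        mae=float(np.mean(np.abs(e))),
        rmse=float(np.sqrt(np.mean(e * e))),
        scc=float("nan"),
        mae_var=float("nan"),
        n_steps=len(p),
    )


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    ok = np.isfinite(values)
    if not np.any(ok):
        return float("nan")
    return float(np.sum(weights[ok] * values[ok]) / np.sum(weights[ok]))


def aggregate_participants(sets: list[MetricSet]) -> MetricSet:
    """Step-count-weighted cross-participant average.

    bias, MAE, SCC and MAE-VAR aggregate by weighted arithmetic mean; SD and
    RMSE by weighted root mean square.
    """
    if not sets:
        raise InsufficientDataError("aggregate_participants: empty list")
    w = np.array([float(s.n_steps) for s in sets])
    if np.any(w <= 0):
        raise ValidationError("every MetricSet needs n_steps > 0")

    def mean_of(attr: str) -> float:
        return _weighted_mean(np.array([getattr(s, attr) for s in sets]), w)

    def rms_of(attr: str) -> float:
        v = np.array([getattr(s, attr) for s in sets])
        ok = np.isfinite(v)
        if not np.any(ok):
            return float("nan")
        return float(np.sqrt(np.sum(w[ok] * v[ok] ** 2) / np.sum(w[ok])))

    return MetricSet(
        bias=mean_of("bias"),
        sd=rms_of("sd"),
        mae=mean_of("mae"),
        rmse=rms_of("rmse"),
        scc=mean_of("scc"),
        mae_var=mean_of("mae_var"),
        n_steps=int(np.sum(w)),
    )


def subset_by_side(p: PairedSteps) -> dict[str, PairedSteps]:
    """Split matched steps into left / right / all subsets.

    'all' preserves the original time order; left + right counts equal the
    total (unknown-side pairs, if any, appear only in 'all').
    """
    out: dict[str, PairedSteps] = {}
    for label in (LEFT, RIGHT):
        idx = [i for i, s in enumerate(p.sides) if s == label]
        out[label] = PairedSteps(
            est=p.est[idx], ref=p.ref[idx],
            est_t=p.est_t[idx], ref_t=p.ref_t[idx],
            sides=[p.sides[i] for i in idx],
            n_unmatched=p.n_unmatched,
        )
    out["all"] = p
    return out


_SPATIAL_COLUMNS = ["Bias (cm)", "SD (cm)", "MAE (cm)", "RMSE (cm)", "SCC", "MAE-VAR (cm)", "n"]
_TEMPORAL_COLUMNS = ["Bias (ms)", "SD (ms)", "MAE (ms)", "RMSE (ms)", "n"]


def metrics_frame(rows: dict[str, MetricSet], kind: str = "spatial") -> pd.DataFrame:
    """Render metric sets as a report table (cm for spatial, ms for temporal).

    This is the single SI-to-report-unit conversion boundary.
    """
    if kind == "spatial":
        data = {
            name: [m.bias * 100, m.sd * 100, m.mae * 100, m.rmse * 100,
                   m.scc, m.mae_var * 100, m.n_steps]
            for name, m in rows.items()
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=_SPATIAL_COLUMNS)
    if kind == "temporal":
        data = {
            name: [m.bias, m.sd, m.mae, m.rmse, m.n_steps]
            for name, m in rows.items()
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=_TEMPORAL_COLUMNS)
    raise ValidationError(f"unknown table kind {kind!r}")
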