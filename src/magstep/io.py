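"""File readers/writers and run configuration.

Formats are plain delimited text in SI units:

* trajectory file - TSV, header ``time`` then ``<marker>_x/_y/_z`` per
  marker, with an optional JSON sidecar (same stem, ``.json``) carrying
  ``fs``, ``belt_speed``, ``t0`` and a role mapping;
* distance file - CSV with header ``time,d_lower,d_upper``;
* step-width file - CSV with header ``time,side,width,dz``;
* config - YAML mapping onto :class:`RunConfig` (unknown keys rejected).

Reports convert to cm/ms at the writer; files stay SI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import DistanceSeries, GaitEvent, StepWidthSeries, TrajectorySet
from .errors import ValidationError
from .events import EventParams
from .geometry import DeviceGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_trajectories",
    "write_trajectories",
    "read_distances",
    "write_distances",
    "read_step_widths",
    "write_step_widths",
    "write_truth",
    "read_truth",
]

_TIME_TOL = 1e-6  # s, uniform-sampling tolerance


@dataclass
class RunConfig:
    """Run-level configuration: device geometry, processing, reporting."""

    da: float = 0.10
    sensor_height: float = 0.05
    fs: float = 100.0
    belt_speed: float = 0.5
    cutoff: float = 2.0
    filter_order: int = 2
    spacing: float = 0.5
    refine_window: float = 0.1
    min_prominence: float = 0.01
    pairing_tol: float = 0.25
    simplified_ic: bool = False
    actuator_side: str = "right"
    report_units: str = "cm"
    seed: int = 0

    def geometry(self) -> DeviceGeometry:
        return DeviceGeometry(da=self.da, sensor_height=self.sensor_height)

    def event_params(self) -> EventParams:
        return EventParams(
            cutoff=self.cutoff,
            order=self.filter_order,
            spacing=self.spacing,
            refine_window=self.refine_window,
            min_prominence=self.min_prominence,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValidationError(
            f"unknown config keys {unknown}; known keys: {sorted(known)}"
        )
    cfg = RunConfig(**data)
    if cfg.actuator_side not in ("left", "right"):
        raise ValidationError(f"actuator_side must be left/right, got {cfg.actuator_side!r}")
    for name in ("da", "fs", "cutoff", "spacing", "refine_window", "pairing_tol"):
        if not getattr(cfg, name) > 0:
            raise ValidationError(f"config field {name} must be positive")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def _check_uniform(time: np.ndarray, path: str | Path) -> float:
    if len(time) < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    dt = np.diff(time)
    bad = np.flatnonzero(np.abs(dt - dt[0]) > _TIME_TOL)
    if len(bad):
        row = int(bad[0]) + 2  # 1-based, after the header
        raise ValidationError(
            f"{path}: non-uniform sampling at data row {row} "
            f"(dt={dt[bad[0]]:.9g} s vs {dt[0]:.9g} s)"
        )
    return 1.0 / dt[0]


def write_trajectories(traj: TrajectorySet, path: str | Path) -> None:
    """TSV with full float precision plus a JSON sidecar (lossless round trip)."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time": traj.times}
    for name, arr in traj.markers.items():
        for ax, j in (("x", 0), ("y", 1), ("z", 2)):
            cols[f"{name}_{ax}"] = arr[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "fs": traj.fs,
        "t0": traj.t0,
        "belt_speed": traj.belt_speed,
        "markers": list(traj.markers),
        "units": "SI",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectories(
    path: str | Path, mapping: dict[str, str] | None = None
) -> TrajectorySet:
    """Read a tri-axial tabular motion file.

    ``mapping`` renames file marker names to the roles the pipeline expects
    (``heel_L``, ``heel_R``, ``A0``, ``S0``, ``S1``), e.g.
    ``{"heel_L": "LHEE"}``.  Column order is irrelevant (header-driven).
    Sampling must be uniform within 1 us; a JSON sidecar supplies
    ``belt_speed``/``t0``, otherwise SI units and zero belt speed are
    assumed with a warning.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise ValidationError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if "time" not in df.columns:
        raise ValidationError(f"{path}: missing 'time' column")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2
        raise ValidationError(f"{path}: malformed/missing values at data row {row}")
    fs = _check_uniform(df["time"].to_numpy(float), path)

    names = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    markers: dict[str, np.ndarray] = {}
    for name in names:
        try:
            markers[name] = df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy(float)
        except KeyError as exc:
            raise ValidationError(f"{path}: marker {name!r} missing an axis column") from exc
    if mapping:
        for role, src in mapping.items():
            if src not in markers:
                raise ValidationError(f"{path}: mapped marker {src!r} not in file")
            markers[role] = markers.pop(src)

    sidecar = path.with_suffix(".json")
    belt_speed, t0 = 0.0, float(df["time"].iloc[0])
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        belt_speed = float(meta.get("belt_speed", 0.0))
        t0 = float(meta.get("t0", t0))
        fs = float(meta.get("fs", fs))
    else:
        warnings.warn(f"{path}: no sidecar found; assuming SI units and belt_speed=0")
    return TrajectorySet(fs=fs, markers=markers, belt_speed=belt_speed, t0=t0)


def write_distances(ds: DistanceSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time": ds.times, "d_lower": ds.d_lower, "d_upper": ds.d_upper}
    ).to_csv(path, index=False, float_format="%.17g")


def read_distances(path: str | Path, da: float, fs: float | None = None) -> DistanceSeries:
    """Read a ``time,d_lower,d_upper`` CSV; ``da`` comes from the config."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time", "d_lower", "d_upper"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: header must be {','.join(expected)}, got {list(df.columns)}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2
        raise ValidationError(f"{path}: malformed/missing values at data row {row}")
    time = df["time"].to_numpy(float)
    inferred = _check_uniform(time, path)
    return DistanceSeries(
        fs=fs if fs is not None else inferred,
        d_lower=df["d_lower"].to_numpy(float),
        d_upper=df["d_upper"].to_numpy(float),
        da=da,
        t0=float(time[0]),
    )


def write_step_widths(sw: StepWidthSeries, path: str | Path) -> None:
    dz = sw.dz if sw.dz is not None else np.full(len(sw), np.nan)
    pd.DataFrame({
        "time": sw.times,
        "side": sw.sides,
        "width": sw.widths,
        "dz": dz,
    }).to_csv(path, index=False, float_format="%.17g")


def read_step_widths(path: str | Path, method: str = "magnetic") -> StepWidthSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time", "side", "width", "dz"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: header must be {','.join(expected)}")
    events = [
        GaitEvent(kind="refined_pair", k=i, time=float(t), side=str(s))
        for i, (t, s) in enumerate(zip(df["time"], df["side"]))
    ]
    dz = df["dz"].to_numpy(float)
    return StepWidthSeries(
        method=method,
        events=events,
        widths=df["width"].to_numpy(float),
        dz=None if np.all(np.isnan(dz)) else dz,
    )


def write_truth(truth, gait, noise, path: str | Path) -> None:
    """Serialise simulator ground truth plus generating parameters."""
    payload = {
        "gait_params": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(gait).items()
        },
        "noise_params": dataclasses.asdict(noise),
        **truth.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path):
    from .simulate import SimulationTruth

    payload = json.loads(Path(path).read_text())
    return SimulationTruth.from_dict(payload), payload
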