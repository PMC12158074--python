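"""Seeded synthetic treadmill-gait generator with ground truth.

The generator emulates the study protocol: 120 s of treadmill walking at
0.5 m/s sampled at 100 Hz, step time 0.8 s, mean step width 10 cm with
1.3 cm variability.  Each foot alternates stance (backward belt drift,
heel on the ground) and swing (smooth half-cosine forward advance with a
half-sine heel-lift bump).  Lateral foot placement is redrawn every step
and settles during the first half of swing, so the width realised at
pass-by is the fresh draw.  Devices ride rigidly on the shanks: two
sensors S0/S1 stacked above the left heel, the actuator A0 centred at the
same height above the right heel, each offset a little outward of the
heel line - the origin of the proxy bias between shank-level and
heel-level step width.

Magnetic distance signals are the true device distances plus a
gait-phase-dependent noise model: the transmitted dipole field decays with
1/r^3, so the distance-noise SD grows as sigma0 * (d / d0)^3 (low noise at
mid-swing where the shanks are close, high noise near initial contact
where they are far apart), plus shock-induced bursts under a Gaussian
envelope at each initial contact, band-limited to the tracking bandwidth.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .containers import LEFT, RIGHT, DistanceSeries, TrajectorySet
from .errors import ValidationError
from .geometry import DeviceGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "GaitParams",
    "NoiseParams",
    "StepTruth",
    "SimulationTruth",
    "simulate_walk",
    "simulate_standing",
    "simulate_magnetic_distances",
    "add_marker_noise",
    "make_fixture",
    "SCENARIOS",
]


@dataclass(frozen=True)
class GaitParams:
    """Treadmill-gait generator parameters (SI units).

    Defaults reproduce the study conditions: 120 s at 0.5 m/s, 0.8 s step
    time, about 10 +/- 1.3 cm step width.  ``step_width_sd`` is the standard
    deviation of the widths realised at pass-by; per-foot placement draws are
    scaled accordingly (sqrt(2) * sd per half-placement, since consecutive
    pass-by widths each combine two independent half-placements).
    ``device_lateral_offset`` shifts each device mount outward of its heel
    line; it creates the shank-vs-heel proxy bias.
    """

    duration: float = 120.0
    belt_speed: float = 0.5
    step_time: float = 0.8
    step_length: float = 0.4
    step_width_mean: float = 0.10
    step_width_sd: float = 0.013
    heel_lift: float = 0.05
    swing_fraction: float = 0.4
    trunk_sway: float = 0.003
    device_lateral_offset: float = 0.02
    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    fs: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("duration", "belt_speed", "step_time", "step_length",
                     "step_width_mean", "heel_lift", "fs"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("step_width_sd", "trunk_sway", "device_lateral_offset"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 < self.swing_fraction < 1:
            raise ValidationError("swing_fraction must be in (0, 1)")
        cadence_speed = self.step_length / self.step_time
        if abs(cadence_speed - self.belt_speed) > 0.2 * self.belt_speed:
            warnings.warn(
                f"step_length/step_time = {cadence_speed:.3g} m/s deviates more "
                f"than 20% from belt_speed = {self.belt_speed:.3g} m/s"
            )

    @property
    def stride_time(self) -> float:
        return 2.0 * self.step_time

    @property
    def swing_time(self) -> float:
        return self.swing_fraction * self.stride_time

    @property
    def stance_time(self) -> float:
        return self.stride_time - self.swing_time


@dataclass(frozen=True)
class NoiseParams:
    """Distance-signal noise model.

    ``sigma0`` is the distance-noise SD at the reference distance ``d0``
    (3 mm at 20 cm, the mid-swing shank separation); the SD scales with
    (d/d0)**distance_exponent, exponent 3 for a dipole field.
    ``impact_sigma`` bursts (Gaussian envelope of SD impact_duration/2)
    fire at each initial contact.  ``bandwidth`` band-limits the channels
    (None = no band-limiting, exact distances when noise is off).
    ``marker_sigma`` is per-axis optical marker noise for robustness
    experiments; fixtures keep markers noise-free as ground truth.
    """

    sigma0: float = 0.003
    d0: float = 0.20
    distance_exponent: float = 3.0
    impact_sigma: float = 0.02
    impact_duration: float = 0.08
    marker_sigma: float = 0.0005
    bandwidth: float | None = 25.0

    def __post_init__(self) -> None:
        for name in ("sigma0", "impact_sigma", "impact_duration", "marker_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not self.d0 > 0:
            raise ValidationError("d0 must be positive")


@dataclass
class StepTruth:
    """Ground truth for one step (the swing of one foot)."""

    side: str
    ic_time: float
    ic_index: int | None
    midswing_time: float
    midswing_index: int
    device_dy: float
    device_dz: float
    heel_separation: float
    crossing_time: float
    ic_x: float
    ic_y: float


@dataclass
class SimulationTruth:
    steps: list[StepTruth]

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def sides(self) -> list[str]:
        return [s.side for s in self.steps]

    @property
    def midswing_times(self) -> np.ndarray:
        return np.array([s.midswing_time for s in self.steps])

    @property
    def device_dy(self) -> np.ndarray:
        return np.array([s.device_dy for s in self.steps])

    @property
    def heel_separation(self) -> np.ndarray:
        return np.array([s.heel_separation for s in self.steps])

    @property
    def ic_times(self) -> np.ndarray:
        return np.array([s.ic_time for s in self.steps])

    def to_dict(self) -> dict:
        return {"steps": [dataclasses.asdict(s) for s in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(steps=[StepTruth(**s) for s in d["steps"]])


def _foot_kinematics(
    t: np.ndarray,
    offset: float,
    placements: np.ndarray,
    p: GaitParams,
) -> np.ndarray:
    """Piecewise stance/swing trajectory of one heel; returns (n, 3)."""
    T, Tw, Ts = p.stride_time, p.swing_time, p.stance_time
    rel = t - offset
    c = np.floor(rel / T).astype(int)
    phase = rel - c * T
    stance = phase < Ts
    s = np.clip((phase - Ts) / Tw, 0.0, 1.0)

    amp = p.belt_speed * Ts  # swing must regain the stance-phase belt drift
    x = np.where(stance, -p.belt_speed * phase,
                 -p.belt_speed * Ts + amp * 0.5 * (1.0 - np.cos(np.pi * s)))
    z = np.where(stance, 0.0, p.heel_lift * np.sin(np.pi * s))

    ci = np.clip(c, 0, len(placements) - 1)
    cn = np.clip(c + 1, 0, len(placements) - 1)
    p_cur = placements[ci]
    p_next = placements[cn]
    # lateral re-placement completes in the first half of swing
    ramp = np.where(s < 0.5, 0.5 * (1.0 - np.cos(2.0 * np.pi * s)), 1.0)
    y = np.where(stance, p_cur, p_cur + (p_next - p_cur) * ramp)
    return np.column_stack([x, y, z])


def _device_markers(heel_l: np.ndarray, heel_r: np.ndarray, p: GaitParams) -> dict[str, np.ndarray]:
    g = p.geometry
    off = p.device_lateral_offset
    return {
        "S0": heel_l + np.array([0.0, off, g.sensor_height]),
        "S1": heel_l + np.array([0.0, off, g.sensor_height + g.da]),
        "A0": heel_r + np.array([0.0, -off, g.actuator_height]),
    }


def simulate_walk(
    p: GaitParams | None = None, rng: np.random.Generator | None = None
) -> tuple[TrajectorySet, SimulationTruth]:
    """Generate heel and device trajectories plus per-step ground truth.

    The first step is a right swing ending at t = step_time; steps then
    alternate sides every step_time, floor(duration / step_time) in total.
    Same seed, same output, bit for bit.
    """
    p = p or GaitParams()
    if rng is None:
        rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs))
    t = np.arange(n) / p.fs
    T, Tw, Ts = p.stride_time, p.swing_time, p.stance_time

    n_steps = int(math.floor(p.duration / p.step_time + 1e-9))
    sides = [RIGHT if k % 2 == 0 else LEFT for k in range(n_steps)]
    if p.step_width_sd > 0:
        w = rng.normal(p.step_width_mean, math.sqrt(2.0) * p.step_width_sd, n_steps)
    else:
        w = np.full(n_steps, p.step_width_mean)

    pl_r = np.concatenate([[-p.step_width_mean / 2],
                           [-w[k] / 2 for k in range(n_steps) if sides[k] == RIGHT]])
    pl_l = np.concatenate([[+p.step_width_mean / 2],
                           [+w[k] / 2 for k in range(n_steps) if sides[k] == LEFT]])

    heel_l = _foot_kinematics(t, 0.0, pl_l, p)
    heel_r = _foot_kinematics(t, -p.step_time, pl_r, p)
    sway = p.trunk_sway * np.sin(2.0 * np.pi * t / T)
    heel_l[:, 1] += sway
    heel_r[:, 1] += sway

    markers = {"heel_L": heel_l, "heel_R": heel_r}
    markers.update(_device_markers(heel_l, heel_r, p))
    traj = TrajectorySet(fs=p.fs, markers=markers, belt_speed=p.belt_speed)

    a0, s0, s1 = markers["A0"], markers["S0"], markers["S1"]
    db = np.linalg.norm(a0 - s0, axis=1)
    dc = np.linalg.norm(a0 - s1, axis=1)
    dmean = 0.5 * (db + dc)
    dev_h = np.hypot(a0[:, 0] - s0[:, 0], a0[:, 1] - s0[:, 1])
    dev_dz = a0[:, 2] - 0.5 * (s0[:, 2] + s1[:, 2])
    sep = heel_l[:, 1] - heel_r[:, 1]

    steps: list[StepTruth] = []
    for k in range(n_steps):
        ic_time = (k + 1) * p.step_time
        i0 = max(0, int(math.ceil((ic_time - Tw) * p.fs - 1e-9)))
        i1 = min(n - 1, int(math.floor(ic_time * p.fs + 1e-9)))
        if i1 <= i0:
            continue
        idx = i0 + int(np.argmin(dmean[i0:i1 + 1]))
        crossing_time = ic_time - Tw / 2.0
        ic_idx = int(round(ic_time * p.fs))
        placement = w[k] / 2.0
        steps.append(StepTruth(
            side=sides[k],
            ic_time=ic_time,
            ic_index=ic_idx if ic_idx < n else None,
            midswing_time=idx / p.fs,
            midswing_index=idx,
            device_dy=float(dev_h[idx]),
            device_dz=float(dev_dz[idx]),
            heel_separation=float(abs(np.interp(crossing_time, t, sep))),
            crossing_time=crossing_time,
            ic_x=p.belt_speed * ic_time,
            ic_y=float((placement if sides[k] == LEFT else -placement)
                       + p.trunk_sway * math.sin(2.0 * math.pi * ic_time / T)),
        ))
    return traj, SimulationTruth(steps=steps)


def simulate_standing(
    duration: float = 30.0, p: GaitParams | None = None
) -> tuple[TrajectorySet, SimulationTruth]:
    """Quiet standing: constant positions, no gait events."""
    p = p or GaitParams()
    n = int(round(duration * p.fs))
    half = p.step_width_mean / 2.0
    heel_l = np.tile([0.0, +half, 0.0], (n, 1))
    heel_r = np.tile([0.0, -half, 0.0], (n, 1))
    markers = {"heel_L": heel_l, "heel_R": heel_r}
    markers.update(_device_markers(heel_l, heel_r, p))
    traj = TrajectorySet(fs=p.fs, markers=markers, belt_speed=0.0)
    return traj, SimulationTruth(steps=[])


def simulate_magnetic_distances(
    traj: TrajectorySet,
    noise: NoiseParams | None = None,
    da: float = 0.10,
    ic_times: np.ndarray | list[float] = (),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> DistanceSeries:
    """Magnetic distance channels: true device distances plus structured noise.

    Noise stages, in rng substream order (lower white, upper white, lower
    impacts, upper impacts):

    1. heteroscedastic Gaussian noise, SD sigma0 * (d / d0)**exponent;
    2. zero-mean impact bursts under a Gaussian envelope (SD =
       impact_duration / 2) centred at each initial contact, drawn
       independently per channel (shock couples through both sensors);
    3. zero-phase low-pass at the tracking bandwidth.
    """
    noise = noise or NoiseParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    traj.require("A0", "S0", "S1")
    a0 = traj.markers["A0"]
    db = np.linalg.norm(a0 - traj.markers["S0"], axis=1)
    dc = np.linalg.norm(a0 - traj.markers["S1"], axis=1)
    n = len(db)
    t = traj.times

    channels = []
    white = [rng.standard_normal(n) if noise.sigma0 > 0 else None for _ in range(2)]
    env = None
    if noise.impact_sigma > 0 and len(ic_times) > 0:
        env = np.zeros(n)
        sd_env = noise.impact_duration / 2.0
        for tic in np.asarray(ic_times, dtype=float):
            lo = max(0, int((tic - 4 * sd_env - traj.t0) * traj.fs))
            hi = min(n, int((tic + 4 * sd_env - traj.t0) * traj.fs) + 1)
            if hi > lo:
                env[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tic) / sd_env) ** 2)
    for i, d in enumerate((db, dc)):
        out = d.copy()
        if white[i] is not None:
            sd = noise.sigma0 * (d / noise.d0) ** noise.distance_exponent
            out = out + sd * white[i]
        channels.append(out)
    if env is not None:
        for i in range(2):
            channels[i] = channels[i] + noise.impact_sigma * env * rng.standard_normal(n)
    if noise.bandwidth is not None and noise.bandwidth < traj.fs / 2:
        b, a = butter(4, noise.bandwidth, btype="low", fs=traj.fs)
        channels = [filtfilt(b, a, ch) for ch in channels]
    floor_d = 1e-4
    n_clipped = sum(int(np.count_nonzero(ch < floor_d)) for ch in channels)
    if n_clipped:
        logger.warning("simulate_magnetic_distances: clipped %d non-positive samples", n_clipped)
        channels = [np.maximum(ch, floor_d) for ch in channels]
    return DistanceSeries(fs=traj.fs, d_lower=channels[0], d_upper=channels[1],
                          da=da, t0=traj.t0)


def add_marker_noise(
    traj: TrajectorySet, sigma: float, rng: np.random.Generator
) -> TrajectorySet:
    """Additive iid Gaussian noise on every marker axis (OMC imperfection)."""
    markers = {
        name: arr + rng.normal(0.0, sigma, arr.shape)
        for name, arr in traj.markers.items()
    }
    return TrajectorySet(fs=traj.fs, markers=markers,
                         belt_speed=traj.belt_speed, t0=traj.t0)


SCENARIOS = ("noise_free", "calibrated_noise", "standing", "high_variability")


def make_fixture(name: str, outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write trajectory, distance, truth, and config files for a scenario.

    Seed handling: one SeedSequence spawns the walk and noise substreams, in
    that order, so fixtures are bit-reproducible.
    """
    from . import io as mio  # deferred to avoid an import cycle

    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    outdir = Path(outdir) / name
    outdir.mkdir(parents=True, exist_ok=True)
    walk_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    walk_rng = np.random.default_rng(walk_ss)
    noise_rng = np.random.default_rng(noise_ss)

    if name == "standing":
        gait = GaitParams(seed=seed)
        traj, truth = simulate_standing(duration=30.0, p=gait)
        noise = NoiseParams()
    elif name == "noise_free":
        gait = GaitParams(seed=seed)
        traj, truth = simulate_walk(gait, rng=walk_rng)
        noise = NoiseParams(sigma0=0.0, impact_sigma=0.0, marker_sigma=0.0, bandwidth=None)
    elif name == "high_variability":
        gait = GaitParams(step_width_sd=0.03, seed=seed)
        traj, truth = simulate_walk(gait, rng=walk_rng)
        noise = NoiseParams()
    else:  # calibrated_noise
        gait = GaitParams(seed=seed)
        traj, truth = simulate_walk(gait, rng=walk_rng)
        noise = NoiseParams()

    ds = simulate_magnetic_distances(
        traj, noise, da=gait.geometry.da, ic_times=truth.ic_times if len(truth) else (),
        rng=noise_rng,
    )
    paths = {
        "trajectories": outdir / "trajectories.tsv",
        "distances": outdir / "distances.csv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    mio.write_trajectories(traj, paths["trajectories"])
    mio.write_distances(ds, paths["distances"])
    mio.write_truth(truth, gait, noise, paths["truth"])
    cfg = mio.RunConfig(
        da=gait.geometry.da,
        sensor_height=gait.geometry.sensor_height,
        fs=gait.fs,
        belt_speed=traj.belt_speed,
        seed=seed,
    )
    mio.save_config(cfg, paths["config"])
    return paths
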