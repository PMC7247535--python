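"""Rotational head kinematics: haversine pulses, measured traces, metrics.

Loading is purely rotational, described per anatomic plane by angular
acceleration about the plane's normal axis.  Idealised impacts use a
haversine (sin^2) acceleration pulse parameterised by peak angular
acceleration alpha_p (rad/s^2) and total angular velocity change
delta_omega (rad/s); its duration is T = 2*delta_omega/alpha_p, since the
mean of sin^2 over a period is 1/2.  Measured impacts arrive as CSV
time-series of 3-axis angular velocity or acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .geometry import PLANE_IDS

#: Default sampling interval for generated pulses, s.
DEFAULT_DT = 1e-4
#: Default truncation horizon for measured traces, s.
DEFAULT_T_MAX = 0.060
#: Default study pulse space: 0.1-15 krad/s^2 and 1-100 rad/s.
DEFAULT_ACCEL_RANGE = (100.0, 15_000.0)
DEFAULT_VEL_RANGE = (1.0, 100.0)

_AXIS_COLUMNS = {"x": "coronal", "y": "sagittal", "z": "axial"}


class TraceError(ValueError):
    """Raised for malformed or unusable kinematic inputs."""


@dataclass(frozen=True)
class HaversinePulse:
    """Idealised sin^2 rotational acceleration pulse."""

    peak_accel: float  # rad/s^2
    delta_velocity: float  # rad/s
    axis: str = "coronal"
    excluded: bool = False  # True when duration exceeds the study cap

    def __post_init__(self):
        if self.peak_accel <= 0 or self.delta_velocity <= 0:
            raise TraceError("peak_accel and delta_velocity must be > 0")

    @property
    def duration(self) -> float:
        """Pulse duration T = 2*delta_velocity/peak_accel, s."""
        return 2.0 * self.delta_velocity / self.peak_accel


@dataclass
class KinematicTrace:
    """Uniformly sampled angular kinematics about one plane's axis."""

    time: np.ndarray  # s
    ang_accel: np.ndarray  # rad/s^2
    ang_vel: np.ndarray  # rad/s
    ang_pos: np.ndarray  # rad
    axis: str = "coronal"

    @classmethod
    def from_acceleration(cls, time: np.ndarray, ang_accel: np.ndarray, axis: str = "coronal") -> "KinematicTrace":
        time = np.asarray(time, dtype=float)
        ang_accel = np.asarray(ang_accel, dtype=float)
        if time.ndim != 1 or np.any(np.diff(time) <= 0):
            raise TraceError("time must be strictly increasing")
        vel = cumulative_trapezoid(ang_accel, time, initial=0.0)
        pos = cumulative_trapezoid(vel, time, initial=0.0)
        return cls(time, ang_accel, vel, pos, axis)

    @classmethod
    def from_velocity(cls, time: np.ndarray, ang_vel: np.ndarray, axis: str = "coronal") -> "KinematicTrace":
        time = np.asarray(time, dtype=float)
        ang_vel = np.asarray(ang_vel, dtype=float)
        if time.ndim != 1 or np.any(np.diff(time) <= 0):
            raise TraceError("time must be strictly increasing")
        acc = np.gradient(ang_vel, time)
        pos = cumulative_trapezoid(ang_vel, time, initial=0.0)
        return cls(time, acc, ang_vel, pos, axis)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class Trace3D:
    """Three per-plane traces sharing a common time base."""

    coronal: KinematicTrace
    sagittal: KinematicTrace
    axial: KinematicTrace

    def __post_init__(self):
        t0 = self.coronal.time
        for tr in (self.sagittal, self.axial):
            if tr.time.shape != t0.shape or not np.allclose(tr.time, t0):
                raise TraceError("the three traces must share one time vector")

    def __getitem__(self, plane_id: str) -> KinematicTrace:
        return getattr(self, plane_id)

    def planes(self):
        return {p: getattr(self, p) for p in PLANE_IDS}


def generate_haversine(
    peak_accel: float,
    delta_velocity: float,
    dt: float = DEFAULT_DT,
    axis: str = "coronal",
    pad_to: float | None = None,
) -> KinematicTrace:
    """Sample a haversine pulse: a(t) = alpha_p * sin^2(pi t / T), t in [0, T].

    ``pad_to`` optionally extends the trace with zero acceleration (and
    constant terminal velocity) to a longer window.
    """
    if peak_accel <= 0 or delta_velocity <= 0 or dt <= 0:
        raise TraceError("peak_accel, delta_velocity and dt must be > 0")
    T = 2.0 * delta_velocity / peak_accel
    if dt >= T / 20:
        raise TraceError(
            f"dt = {dt} too coarse for pulse duration T = {T:.4g} s (need dt < T/20)"
        )
    t_end = max(T, pad_to) if pad_to is not None else T
    n = int(round(t_end / dt))
    time = np.arange(n + 1) * dt
    accel = np.where(time <= T, peak_accel * np.sin(np.pi * time / T) ** 2, 0.0)
    return KinematicTrace.from_acceleration(time, accel, axis=axis)


def trace_from_pulse(pulse: HaversinePulse, dt: float | None = None, pad_to: float | None = None) -> KinematicTrace:
    """Sample a pulse; ``dt=None`` picks min(1e-4, T/100) so short pulses resolve."""
    if dt is None:
        dt = min(DEFAULT_DT, pulse.duration / 100.0)
    return generate_haversine(pulse.peak_accel, pulse.delta_velocity, dt=dt, axis=pulse.axis, pad_to=pad_to)


def read_trace_csv(path: str | Path, dt: float | None = None) -> Trace3D:
    """Read a 3-axis kinematics CSV.

    Expected header: ``time_s`` plus either ``wx_rads, wy_rads, wz_rads``
    (angular velocity) or ``ax_rads2, ay_rads2, az_rads2`` (angular
    acceleration); the unit suffix in the header is mandatory.  Traces
    are resampled to a uniform grid by linear interpolation and missing
    derivative/integral channels computed numerically.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if "time_s" not in cols:
        raise TraceError("CSV must contain a 'time_s' column (unit tag required)")
    time = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise TraceError("time_s must be strictly increasing")
    vel_cols = [f"w{a}_rads" for a in "xyz"]
    acc_cols = [f"a{a}_rads2" for a in "xyz"]
    if all(c in cols for c in vel_cols):
        kind, data_cols = "velocity", vel_cols
    elif all(c in cols for c in acc_cols):
        kind, data_cols = "acceleration", acc_cols
    else:
        raise TraceError(
            "CSV must contain wx_rads/wy_rads/wz_rads or ax_rads2/ay_rads2/az_rads2"
        )
    if dt is None:
        dt = float(np.median(np.diff(time)))
    grid = np.arange(time[0], time[-1] + 0.5 * dt, dt)
    traces = {}
    for col, ax in zip(data_cols, "xyz"):
        y = np.interp(grid, time, df[col].to_numpy(dtype=float))
        plane = _AXIS_COLUMNS[ax]
        if kind == "velocity":
            traces[plane] = KinematicTrace.from_velocity(grid, y, axis=plane)
        else:
            traces[plane] = KinematicTrace.from_acceleration(grid, y, axis=plane)
    return Trace3D(**traces)


def truncate_trace(trace: KinematicTrace, t_max: float = DEFAULT_T_MAX) -> KinematicTrace:
    """Drop samples beyond ``t_max`` (default 60 ms)."""
    if t_max <= 0:
        raise TraceError("t_max must be > 0")
    keep = trace.time <= t_max + 1e-12
    if not np.any(keep):
        raise TraceError("truncation removed every sample")
    return KinematicTrace(
        trace.time[keep], trace.ang_accel[keep], trace.ang_vel[keep], trace.ang_pos[keep], trace.axis
    )


def peak_metrics(trace: KinematicTrace) -> tuple[float, float]:
    """Return (peak |angular acceleration|, peak |angular velocity|)."""
    return float(np.max(np.abs(trace.ang_accel))), float(np.max(np.abs(trace.ang_vel)))


def sample_pulse_space(
    accel_range: tuple[float, float] = DEFAULT_ACCEL_RANGE,
    vel_range: tuple[float, float] = DEFAULT_VEL_RANGE,
    n_per_axis: int = 17,
    seed: int | None = None,
    max_duration: float = DEFAULT_T_MAX,
    axis: str = "coronal",
) -> list[HaversinePulse]:
    """Log-spaced grid of (peak_accel, delta_velocity) study conditions.

    ``n_per_axis`` values are taken per variable (n_per_axis^2 pairs).
    Pairs whose implied duration 2*delta_velocity/peak_accel exceeds
    ``max_duration`` are returned with ``excluded=True`` rather than
    dropped, so exclusion counts can be reported.  ``seed`` is accepted
    for interface uniformity; the grid itself is deterministic.
    """
    if n_per_axis < 1:
        raise TraceError("n_per_axis must be >= 1")
    if n_per_axis == 1:
        accels = [float(np.sqrt(accel_range[0] * accel_range[1]))]
        vels = [float(np.sqrt(vel_range[0] * vel_range[1]))]
    else:
        accels = np.geomspace(*accel_range, n_per_axis)
        vels = np.geomspace(*vel_range, n_per_axis)
    out = []
    for a in accels:
        for v in vels:
            excl = (2.0 * v / a) > max_duration
            out.append(HaversinePulse(float(a), float(v), axis=axis, excluded=excl))
    return out
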