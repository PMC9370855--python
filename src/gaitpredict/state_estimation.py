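"""Trajectory container, CSV ingest, acquisition prefilter and raw-state
estimation from sampled positions.

The raw state sequence derives heading from the four-quadrant arctangent of
per-sample displacement, speed from the displacement norm over the sample
interval, and acceleration / turn rate as backward differences of speed and
unwrapped heading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .motion_models import MotionState, wrap_angle

__all__ = [
    "Trajectory",
    "StateSequence",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "lowpass_prefilter",
    "estimate_raw_states",
]

#: bit-exact CSV header for trajectory files
CSV_COLUMNS = ("t_s", "x_m", "y_m", "pelvis_yaw_rad")

_DT_TOL = 1e-9


@dataclass
class Trajectory:
    """Uniformly sampled 2-D landmark track with pelvis yaw.

    Fields are 1-D float arrays of equal length ``n >= 3``; ``t`` must be
    strictly increasing with constant spacing (tolerance 1e-9 s).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi_pelvis: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.phi_pelvis = np.asarray(self.phi_pelvis, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.phi_pelvis.size == n):
            raise ValueError("trajectory channels must all have the same length")
        if n < 3:
            raise ValueError(f"trajectory needs at least 3 samples, got {n}")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.max(np.abs(dts - dts[0])) > _DT_TOL:
            raise ValueError("sample times must be uniformly spaced")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class StateSequence:
    """Per-sample motion states aligned to a :class:`Trajectory`.

    ``variant`` tags the estimation route: ``raw`` (direct differences),
    ``offline`` (from the polynomial baseline) or ``realtime`` (gait
    compensated). Headings are stored wrapped to (-pi, pi].
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    v: np.ndarray
    a: np.ndarray
    w: np.ndarray
    variant: str
    dt: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.variant not in ("raw", "offline", "realtime"):
            raise ValueError(f"unknown variant tag {self.variant!r}")
        n = len(self.t)
        for name in ("x", "y", "phi", "v", "a", "w"):
            if len(getattr(self, name)) != n:
                raise ValueError("state channels must all have the same length")
        if self.dt == 0.0:
            self.dt = float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return len(self.t)

    def state_at(self, k: int) -> MotionState:
        if not 0 <= k < self.n:
            raise IndexError(f"sample index {k} out of range [0, {self.n})")
        return MotionState(
            float(self.x[k]),
            float(self.y[k]),
            float(self.phi[k]),
            float(self.v[k]),
            float(self.a[k]),
            float(self.w[k]),
        )


def read_trajectory_csv(path) -> Trajectory:
    """Read a trajectory CSV (header ``t_s,x_m,y_m,pelvis_yaw_rad``)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing column(s): {', '.join(missing)}")
    return Trajectory(
        t=df["t_s"].to_numpy(),
        x=df["x_m"].to_numpy(),
        y=df["y_m"].to_numpy(),
        phi_pelvis=df["pelvis_yaw_rad"].to_numpy(),
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        {
            "t_s": traj.t,
            "x_m": traj.x,
            "y_m": traj.y,
            "pelvis_yaw_rad": traj.phi_pelvis,
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def _filter_channel(b, a, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.filtfilt(b, a, x)
    # initialise at the first sample so a constant input passes unchanged
    zi = signal.lfilter_zi(b, a) * x[0]
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def lowpass_prefilter(
    traj: Trajectory,
    order: int = 3,
    cutoff_hz: float = 6.0,
    zero_phase: bool = False,
) -> Trajectory:
    """Butterworth low-pass acquisition prefilter (default 3rd order, 6 Hz).

    Filters ``x``, ``y`` and ``phi_pelvis`` (the yaw is unwrapped first and
    re-wrapped after). Causal by default; ``zero_phase=True`` selects
    forward-backward filtering for offline use.
    """
    nyquist = 0.5 / traj.dt
    if not cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / traj.dt)
    yaw = np.unwrap(traj.phi_pelvis)
    return Trajectory(
        t=traj.t.copy(),
        x=_filter_channel(b, a, traj.x, zero_phase),
        y=_filter_channel(b, a, traj.y, zero_phase),
        phi_pelvis=wrap_angle(_filter_channel(b, a, yaw, zero_phase)),
    )


def estimate_raw_states(traj: Trajectory, variant: str = "raw") -> StateSequence:
    """Estimate the raw state sequence (phi, v, a, w) from positions.

    Heading is atan2 of the per-sample displacement; samples with zero
    displacement carry the previous heading forward. Undefined leading
    samples are filled by copying the first computable value (phi, v from
    index 1; a, w from index 2).
    """
    n = traj.n
    if n < 3:
        raise ValueError("need at least 3 samples to estimate states")
    dt = traj.dt
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    disp = np.hypot(dx, dy)

    v = np.empty(n)
    v[1:] = disp / dt
    v[0] = v[1]

    phi = np.empty(n)
    phi[1:] = np.arctan2(dy, dx)
    # standing-still samples: carry the previous heading forward
    zero = disp == 0.0
    if np.any(zero):
        for k in np.flatnonzero(zero) + 1:
            phi[k] = phi[k - 1] if k > 1 else 0.0
    phi[0] = phi[1]

    phi_u = np.unwrap(phi)
    a = np.empty(n)
    a[2:] = np.diff(v[1:]) / dt
    a[0] = a[1] = a[2]
    w = np.empty(n)
    w[2:] = np.diff(phi_u[1:]) / dt
    w[0] = w[1] = w[2]

    return StateSequence(
        t=traj.t.copy(),
        x=traj.x.copy(),
        y=traj.y.copy(),
        phi=wrap_angle(phi_u),
        v=v,
        a=a,
        w=w,
        variant=variant,
        dt=dt,
    )
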