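"""Synthetic walking-trajectory generator with ground truth.

Builds biomechanically structured walks: a smooth straight or circular
path, forward speed oscillating twice per stride and crossing its running
mean at foot-contact instants, lateral pelvic sway once per stride along
the path normal, and pelvis yaw oscillating in counter-phase with the
heading that position differencing will recover. Every output carries the
ground truth the estimation stages are supposed to recover (smooth
baseline, contact times, blend gain), which makes the generator a test
harness, not a biomechanical claim.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .state_estimation import Trajectory
from .motion_models import wrap_angle

__all__ = ["SynthConfig", "SynthOutput", "synthesize", "benchmark_suite"]

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Parameters of one synthetic walk.

    ``duration`` defaults to the time needed to cover ``length_m`` (straight)
    or one full turn of ``radius_m`` (circle) at the configured speed ramp.
    ``vel_osc_amp`` defaults to 10% of ``mean_speed``.
    """

    path_kind: str = "straight"
    length_m: float = 5.4
    radius_m: float = 1.5
    mean_speed: float = 1.2
    mean_accel: float = 0.0
    stride_hz: float = 1.0
    sway_amp: float = 0.025
    vel_osc_amp: float | None = None
    pelvis_osc_amp: float = 0.08
    heading_osc_counterphase: bool = True
    noise_sd: float = 0.0
    dt: float = 0.01
    duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.path_kind not in ("straight", "circle"):
            raise ValueError(f"path_kind must be 'straight' or 'circle', got {self.path_kind!r}")
        if self.dt <= 0 or self.mean_speed <= 0:
            raise ValueError("dt and mean_speed must be positive")
        if self.sway_amp < 0 or self.noise_sd < 0:
            raise ValueError("sway_amp and noise_sd must be non-negative")
        if not 0.3 <= self.stride_hz <= 2.0:
            raise ValueError(f"stride_hz {self.stride_hz} outside plausible range [0.3, 2]")
        if self.vel_osc_amp is None:
            self.vel_osc_amp = 0.1 * self.mean_speed
        if self.duration is None:
            distance = (
                self.length_m if self.path_kind == "straight" else 2.0 * math.pi * self.radius_m
            )
            exact = _time_to_cover(distance, self.mean_speed, self.mean_accel)
            # snap to the sample grid so the walk ends on a sample (distance
            # error at most mean_speed*dt/2)
            self.duration = max(1, round(exact / self.dt)) * self.dt


def _time_to_cover(distance: float, v0: float, accel: float) -> float:
    """Time for the smooth speed ramp v0 + accel*t to cover ``distance``."""
    if abs(accel) < 1e-12:
        return distance / v0
    disc = v0 * v0 + 2.0 * accel * distance
    if disc <= 0:
        raise ValueError("speed ramp never covers the requested distance")
    return (-v0 + math.sqrt(disc)) / accel


@dataclass
class SynthOutput:
    """One synthetic walk plus the ground truth used by the tests."""

    traj: Trajectory
    baseline_truth: Trajectory
    event_times_truth: np.ndarray
    K_truth: float
    cfg: SynthConfig
    subject: int = -1
    rep: int = -1

    @property
    def path_kind(self) -> str:
        return self.cfg.path_kind


def _path_point(cfg: SynthConfig, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth path position and heading at arc length ``s``."""
    if cfg.path_kind == "straight":
        return s, np.zeros_like(s), np.zeros_like(s)
    r = cfg.radius_m
    psi = s / r
    return r * np.sin(psi), r * (1.0 - np.cos(psi)), psi


def synthesize(cfg: SynthConfig) -> SynthOutput:
    """Generate one synthetic walk from ``cfg`` (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration + 0.5 * cfg.dt, cfg.dt)
    f = cfg.stride_hz

    # forward speed: smooth ramp + twice-per-stride oscillation whose zeros
    # (the contact instants) are exactly where the speed equals the ramp
    osc_phase = 4.0 * math.pi * f * t
    s_smooth = cfg.mean_speed * t + 0.5 * cfg.mean_accel * t * t
    s_obs = s_smooth + cfg.vel_osc_amp / (4.0 * math.pi * f) * (1.0 - np.cos(osc_phase))

    bx, by, bpsi = _path_point(cfg, s_smooth)
    px, py, psi = _path_point(cfg, s_obs)

    # lateral pelvic sway once per stride along the path normal; phased so
    # that the induced heading oscillation is +sin, i.e. in counter-phase
    # with the pelvis yaw oscillation below
    if cfg.heading_osc_counterphase:
        lateral = -cfg.sway_amp * np.cos(2.0 * math.pi * f * t)
    else:
        lateral = cfg.sway_amp * np.sin(2.0 * math.pi * f * t)
    x = px - lateral * np.sin(psi)
    y = py + lateral * np.cos(psi)
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=t.size)
        y = y + rng.normal(0.0, cfg.noise_sd, size=t.size)

    pelvis = psi - cfg.pelvis_osc_amp * np.sin(2.0 * math.pi * f * t)

    # analytic ground truth for the calibration stage: the position-derived
    # heading oscillates with amplitude 2*pi*f*sway/<v>, the pelvis with
    # pelvis_osc_amp, in counter-phase; the least-squares blend gain is the
    # amplitude ratio
    v_bar = cfg.mean_speed + 0.5 * cfg.mean_accel * cfg.duration
    a_heading = 2.0 * math.pi * f * cfg.sway_amp / v_bar
    denom = a_heading + cfg.pelvis_osc_amp
    k_truth = a_heading / denom if denom > 0 else 0.0

    n_events = int(math.floor(2.0 * f * cfg.duration + 1e-9))
    event_times = (np.arange(n_events) + 1) / (2.0 * f)

    if cfg.path_kind == "circle":
        revolutions = s_smooth[-1] / (2.0 * math.pi * cfg.radius_m)
        if revolutions > 1.25:
            logger.warning(
                "circle walk spans %.2f revolutions; the degree-8 offline fit "
                "needs single-turn segmentation",
                revolutions,
            )

    traj = Trajectory(t=t, x=x, y=y, phi_pelvis=wrap_angle(pelvis))
    baseline = Trajectory(t=t, x=bx, y=by, phi_pelvis=wrap_angle(bpsi))
    return SynthOutput(
        traj=traj,
        baseline_truth=baseline,
        event_times_truth=event_times,
        K_truth=k_truth,
        cfg=cfg,
    )


def benchmark_suite(seed: int, n_subjects: int = 5, n_reps: int = 5) -> list[SynthOutput]:
    """Deterministic benchmark: per subject, 5 straight 5.4 m walks and
    5 single-turn 1.5 m-radius circles with speeds increasing across
    repetitions. Per-subject cadence, sway and pelvis-oscillation
    parameters are drawn once from plausible ranges."""
    rng = np.random.default_rng(seed)
    walks: list[SynthOutput] = []
    for subject in range(n_subjects):
        stride_hz = rng.uniform(0.8, 1.25)
        sway_amp = rng.uniform(0.012, 0.02)
        pelvis_osc = rng.uniform(0.06, 0.10)
        base_speed = rng.uniform(1.0, 1.4)
        for rep in range(n_reps):
            cfg = SynthConfig(
                path_kind="straight",
                length_m=5.4,
                mean_speed=base_speed * rng.uniform(0.95, 1.05),
                mean_accel=0.0,
                stride_hz=stride_hz,
                sway_amp=sway_amp,
                pelvis_osc_amp=pelvis_osc,
                noise_sd=1.4e-3,
                seed=int(rng.integers(0, 2**31)),
            )
            out = synthesize(cfg)
            out.subject, out.rep = subject, rep
            walks.append(out)
        for rep in range(n_reps):
            cfg = SynthConfig(
                path_kind="circle",
                radius_m=1.5,
                mean_speed=base_speed * (0.85 + 0.075 * rep),
                mean_accel=0.04,
                stride_hz=stride_hz,
                sway_amp=sway_amp,
                pelvis_osc_amp=pelvis_osc,
                noise_sd=1.4e-3,
                seed=int(rng.integers(0, 2**31)),
            )
            out = synthesize(cfg)
            out.subject, out.rep = subject, rep
            walks.append(out)
    return walks
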