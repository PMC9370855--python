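"""Real-time gait-biomechanics compensation of the raw states.

The walking speed derived from waist positions oscillates twice per stride
and crosses its stride mean at foot-contact instants, which show up as
extrema of the speed derivative. Holding the speed sampled at those events
(zero-order hold) removes the oscillation causally. The position-derived
heading and the pelvis yaw oscillate in counter-phase, so a proportional
blend ``K*phi_pelvis + (1-K)*phi_raw`` cancels the heading sway; ``K`` is
calibrated per subject against the offline baseline by scalar least
squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .motion_models import wrap_angle
from .state_estimation import StateSequence, Trajectory, estimate_raw_states

__all__ = [
    "GaitEvents",
    "CompensationParams",
    "detect_contacts",
    "hold_velocity",
    "blend_orientation",
    "calibrate_K",
    "build_realtime_states",
]

logger = logging.getLogger(__name__)

INITIAL_CONTACT = "initial_contact"
FINAL_CONTACT = "final_contact"


@dataclass
class GaitEvents:
    """Ordered foot-contact events detected from the speed derivative."""

    indices: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.labels) != self.indices.size:
            raise ValueError("labels and indices must have the same length")
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("event indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class CompensationParams:
    """Tuning knobs of the compensation stage.

    ``K`` is the orientation blend gain in [0, 1]; ``phi_offset`` is the
    constant pelvis-mounting offset (rad) subtracted from the pelvis yaw
    before blending, estimated during calibration.
    """

    K: float = 0.0
    # contacts arrive 4x per stride (one max + one min of dv/dt per step);
    # at the fastest plausible cadence (~1.3 strides/s) that is ~0.19 s apart
    peak_min_interval_s: float = 0.12
    peak_min_prominence_frac: float = 0.10
    phi_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.K <= 1.0:
            raise ValueError(f"K must lie in [0, 1], got {self.K}")
        if self.peak_min_interval_s <= 0:
            raise ValueError("peak_min_interval_s must be positive")


def _require_variant(states: StateSequence, variant: str, op: str) -> None:
    if states.variant != variant:
        raise ValueError(f"{op} requires a {variant!r} state sequence, got {states.variant!r}")


def detect_contacts(raw: StateSequence, params: CompensationParams | None = None) -> GaitEvents:
    """Detect foot contacts as alternating extrema of d(v_raw)/dt.

    Causal: an extremum is confirmed one sample after it occurs. Candidate
    extrema are accepted when they clear a prominence threshold (a fraction
    of the running peak-to-peak of the derivative) and a minimum inter-event
    separation; a repeated same-polarity extremum replaces the previous one
    if more extreme. Returns empty events when no extremum qualifies.
    """
    if params is None:
        params = CompensationParams()
    _require_variant(raw, "raw", "detect_contacts")
    n = raw.n
    dt = raw.dt
    dv = np.empty(n)
    dv[1:] = np.diff(raw.v) / dt
    dv[0] = dv[1]

    min_sep = max(1, int(round(params.peak_min_interval_s / dt)))
    indices: list[int] = []
    kinds: list[str] = []
    run_min = run_max = dv[0]
    for k in range(1, n - 1):
        run_min = min(run_min, dv[k])
        run_max = max(run_max, dv[k])
        scale = run_max - run_min
        if scale <= 0.0:
            continue
        is_max = dv[k - 1] < dv[k] >= dv[k + 1]
        is_min = dv[k - 1] > dv[k] <= dv[k + 1]
        if not (is_max or is_min):
            continue
        kind = "max" if is_max else "min"
        prominence = params.peak_min_prominence_frac * scale
        if indices and kinds[-1] == kind:
            more_extreme = dv[k] > dv[indices[-1]] if kind == "max" else dv[k] < dv[indices[-1]]
            if more_extreme:
                indices[-1] = k
            continue
        if indices:
            if k - indices[-1] < min_sep:
                continue
            if abs(dv[k] - dv[indices[-1]]) < prominence:
                continue
        else:
            if k < min_sep:  # warm-up: the fill-in at the start fakes extrema
                continue
            reference = run_min if kind == "max" else run_max
            if abs(dv[k] - reference) < prominence:
                continue
        indices.append(k)
        kinds.append(kind)

    labels = [INITIAL_CONTACT if kind == "max" else FINAL_CONTACT for kind in kinds]
    if not indices:
        logger.info("detect_contacts: no qualifying extrema found")
    return GaitEvents(indices=np.asarray(indices, dtype=int), labels=labels)


def hold_velocity(
    raw: StateSequence, events: GaitEvents
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-order hold of the raw speed at contact events.

    Before the first event both outputs copy the raw channels. From each
    event onward the speed holds the raw value sampled at that event; the
    acceleration holds the speed increment between consecutive events over
    the inter-event time. Empty events fall back to the raw channels.
    """
    _require_variant(raw, "raw", "hold_velocity")
    v_tilde = raw.v.copy()
    a_tilde = raw.a.copy()
    if len(events) == 0:
        logger.warning("hold_velocity: no events, passing raw velocity through")
        return v_tilde, a_tilde
    idx = events.indices
    n = raw.n
    for j, e in enumerate(idx):
        end = idx[j + 1] if j + 1 < len(idx) else n
        v_tilde[e:end] = raw.v[e]
        if j >= 1:
            prev = idx[j - 1]
            a_tilde[e:end] = (raw.v[e] - raw.v[prev]) / ((e - prev) * raw.dt)
    return v_tilde, a_tilde


def blend_orientation(
    raw: StateSequence, traj: Trajectory, params: CompensationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Proportional blend of pelvis yaw and position-derived heading.

    Both angle sequences are unwrapped; the calibrated mounting offset is
    subtracted from the pelvis yaw first. Returns the blended heading
    (wrapped) and its backward-difference turn rate.
    """
    _require_variant(raw, "raw", "blend_orientation")
    if traj.n != raw.n:
        raise ValueError("trajectory and state sequence lengths differ")
    if np.any(~np.isfinite(traj.phi_pelvis)):
        raise ValueError("pelvis yaw channel contains non-finite values")
    phi_r = np.unwrap(raw.phi)
    phi_h = np.unwrap(traj.phi_pelvis) - params.phi_offset
    phi_tilde = params.K * phi_h + (1.0 - params.K) * phi_r
    w_tilde = np.empty(raw.n)
    w_tilde[1:] = np.diff(phi_tilde) / raw.dt
    w_tilde[0] = w_tilde[1]
    return wrap_angle(phi_tilde), w_tilde


def calibrate_K(
    raw: StateSequence | list[StateSequence],
    baseline: StateSequence | list[StateSequence],
    traj: Trajectory | list[Trajectory],
) -> CompensationParams:
    """Least-squares calibration of the blend gain K against the baseline.

    Minimises ``sum_k (K*phi_h + (1-K)*phi_r - phi_b)^2`` in closed form,
    clipped to [0, 1]. Lists of aligned walks are pooled (per-subject
    calibration across recordings). A degenerate problem (pelvis yaw
    identical to raw heading) yields K = 0 with a warning.
    """
    raws = raw if isinstance(raw, list) else [raw]
    bases = baseline if isinstance(baseline, list) else [baseline]
    trajs = traj if isinstance(traj, list) else [traj]
    if not len(raws) == len(bases) == len(trajs):
        raise ValueError("raw, baseline and trajectory lists must be aligned")

    num = 0.0
    den = 0.0
    offsets = []
    weights = []
    for rw, bl, tr in zip(raws, bases, trajs):
        _require_variant(rw, "raw", "calibrate_K")
        _require_variant(bl, "offline", "calibrate_K")
        if not (rw.n == bl.n == tr.n):
            raise ValueError("raw, baseline and trajectory lengths differ")
        phi_r = np.unwrap(rw.phi)
        phi_h = np.unwrap(tr.phi_pelvis)
        phi_b = np.unwrap(bl.phi)
        offset = float(np.mean(phi_h - phi_r))
        offsets.append(offset)
        weights.append(rw.n)
        d = (phi_h - offset) - phi_r
        r = phi_r - phi_b
        num += float(np.dot(d, r))
        den += float(np.dot(d, d))

    phi_offset = float(np.average(offsets, weights=weights))
    if den < 1e-12:
        logger.warning("calibrate_K: pelvis yaw and raw heading coincide; K undefined, using 0")
        return CompensationParams(K=0.0, phi_offset=phi_offset)
    k_star = float(np.clip(-num / den, 0.0, 1.0))
    return CompensationParams(K=k_star, phi_offset=phi_offset)


def build_realtime_states(
    traj: Trajectory,
    params: CompensationParams,
    raw: StateSequence | None = None,
) -> StateSequence:
    """Assemble the real-time estimated state sequence.

    Raw positions, event-held speed/acceleration, pelvis-blended heading
    and its turn rate. Each value at index k depends only on samples up to
    k+1 (one-sample event-confirmation lag). Degrades to the raw sequence
    when no events are detected or the pelvis channel is unusable.
    """
    if raw is None:
        raw = estimate_raw_states(traj)
    _require_variant(raw, "raw", "build_realtime_states")
    events = detect_contacts(raw, params)
    v_tilde, a_tilde = hold_velocity(raw, events)
    try:
        phi_tilde, w_tilde = blend_orientation(raw, traj, params)
    except ValueError:
        logger.warning("build_realtime_states: pelvis channel unusable, using raw heading")
        phi_tilde, w_tilde = raw.phi.copy(), raw.w.copy()
    return StateSequence(
        t=raw.t.copy(),
        x=raw.x.copy(),
        y=raw.y.copy(),
        phi=phi_tilde,
        v=v_tilde,
        a=a_tilde,
        w=w_tilde,
        variant="realtime",
        dt=raw.dt,
    )
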