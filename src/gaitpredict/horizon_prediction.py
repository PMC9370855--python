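"""Recursive fixed-horizon forecasting and the horizon-error analysis.

Every admissible start sample seeds the chosen model with the estimated
state at that sample; the model is applied recursively for H steps and the
Euclidean distance to the *measured* positions is recorded at each horizon
step. Errors are aggregated as RMS across starts, per horizon step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motion_models import ModelKind, step_arrays
from .state_estimation import StateSequence, Trajectory

__all__ = [
    "HorizonErrorProfile",
    "predict_from",
    "error_sequence",
    "sweep",
    "combine_profiles",
    "summarize",
]

#: the first two samples of an estimated sequence carry copied (undefined)
#: differences, so predictions never seed there
FIRST_VALID_START = 2


@dataclass
class HorizonErrorProfile:
    """RMS prediction error per horizon step for one model/variant."""

    model: ModelKind
    variant: str
    rms: np.ndarray
    H: int
    n_starts: int
    dt: float
    path_type: str = ""

    def __post_init__(self) -> None:
        self.rms = np.asarray(self.rms, dtype=float)
        if self.rms.size != self.H:
            raise ValueError("rms length must equal the horizon H")
        if np.any(~np.isfinite(self.rms)) or np.any(self.rms < 0):
            raise ValueError("rms values must be finite and non-negative")

    def rms_at(self, at_s: float) -> float:
        """RMS error (metres) at the horizon time ``at_s`` seconds."""
        h = int(round(at_s / self.dt))
        if not 1 <= h <= self.H:
            raise ValueError(f"horizon {at_s} s outside the profile (H={self.H})")
        return float(self.rms[h - 1])


def predict_from(
    states: StateSequence, k: int, model: ModelKind, H: int
) -> np.ndarray:
    """Recursively predicted positions for samples k+1 .. k+H, shape (H, 2)."""
    if H < 1:
        raise ValueError(f"horizon must be >= 1, got {H}")
    if not 0 <= k < states.n:
        raise ValueError(f"start index {k} out of range [0, {states.n})")
    model = ModelKind(model)
    x = states.x[k]
    y = states.y[k]
    phi = states.phi[k]
    v = states.v[k]
    a = states.a[k] if model.uses_accel else 0.0
    w = states.w[k] if model.uses_turn else 0.0
    out = np.empty((H, 2))
    for h in range(H):
        x, y, phi, v = step_arrays(x, y, phi, v, a, w, states.dt)
        out[h, 0] = x
        out[h, 1] = y
    return out


def error_sequence(predicted: np.ndarray, actual: Trajectory, k: int) -> np.ndarray:
    """Euclidean distances of predictions to the measured positions.

    Element h-1 compares the h-step-ahead prediction with the raw position
    at sample k+h, regardless of which estimation variant seeded the
    prediction.
    """
    predicted = np.asarray(predicted, dtype=float)
    H = predicted.shape[0]
    if predicted.ndim != 2 or predicted.shape[1] != 2:
        raise ValueError("predicted must have shape (H, 2)")
    if k + H >= actual.n:
        raise ValueError(
            f"prediction from k={k} over {H} steps exceeds trajectory length {actual.n}"
        )
    sl = slice(k + 1, k + 1 + H)
    return np.hypot(predicted[:, 0] - actual.x[sl], predicted[:, 1] - actual.y[sl])


def sweep(
    states: StateSequence,
    actual: Trajectory,
    model: ModelKind,
    H: int | None = None,
    path_type: str = "",
) -> HorizonErrorProfile:
    """Predict from every admissible start sample and aggregate RMS per step.

    ``H`` defaults to round(1 s / dt). Starts range over
    ``[FIRST_VALID_START, n - H)``; the whole sweep is vectorised across
    starts (one kernel step advances every pending prediction at once).
    """
    model = ModelKind(model)
    if states.n != actual.n:
        raise ValueError("state sequence and trajectory lengths differ")
    dt = states.dt
    if H is None:
        H = int(round(1.0 / dt))
    if states.n <= H + FIRST_VALID_START:
        raise ValueError(f"trajectory too short (n={states.n}) for horizon H={H}")

    ks = np.arange(FIRST_VALID_START, states.n - H)
    x = states.x[ks].copy()
    y = states.y[ks].copy()
    phi = states.phi[ks].copy()
    v = states.v[ks].copy()
    a = states.a[ks] if model.uses_accel else np.zeros(ks.size)
    w = states.w[ks] if model.uses_turn else np.zeros(ks.size)

    sq = np.empty((H, ks.size))
    for h in range(1, H + 1):
        x, y, phi, v = step_arrays(x, y, phi, v, a, w, dt)
        ex = x - actual.x[ks + h]
        ey = y - actual.y[ks + h]
        sq[h - 1] = ex * ex + ey * ey
    rms = np.sqrt(sq.mean(axis=1))
    return HorizonErrorProfile(
        model=model,
        variant=states.variant,
        rms=rms,
        H=H,
        n_starts=ks.size,
        dt=dt,
        path_type=path_type,
    )


def combine_profiles(
    profiles: list[HorizonErrorProfile], path_type: str = ""
) -> HorizonErrorProfile:
    """Pool profiles over their start sets (weighted quadratic mean).

    All profiles must share model, variant, H and dt; the result's RMS at
    each step is the n_starts-weighted quadratic mean of the inputs.
    """
    if not profiles:
        raise ValueError("need at least one profile to combine")
    first = profiles[0]
    total = 0
    acc = np.zeros(first.H)
    for p in profiles:
        if (p.model, p.variant, p.H) != (first.model, first.variant, first.H):
            raise ValueError("profiles must share model, variant and horizon")
        if abs(p.dt - first.dt) > 1e-12:
            raise ValueError("profiles must share the sample interval")
        acc += p.n_starts * p.rms**2
        total += p.n_starts
    return HorizonErrorProfile(
        model=first.model,
        variant=first.variant,
        rms=np.sqrt(acc / total),
        H=first.H,
        n_starts=total,
        dt=first.dt,
        path_type=path_type,
    )


def summarize(
    profiles: list[HorizonErrorProfile], at_s: float = 1.0
) -> pd.DataFrame:
    """Tabulate RMS error (millimetres) at a fixed horizon time.

    One row per profile with columns
    ``model, variant, path_type, horizon_s, rms_mm, n_starts``.
    """
    rows = []
    for p in profiles:
        rows.append(
            {
                "model": p.model.value,
                "variant": p.variant,
                "path_type": p.path_type,
                "horizon_s": at_s,
                "rms_mm": p.rms_at(at_s) * 1000.0,
                "n_starts": p.n_starts,
            }
        )
    return pd.DataFrame(rows, columns=["model", "variant", "path_type", "horizon_s", "rms_mm", "n_starts"])
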