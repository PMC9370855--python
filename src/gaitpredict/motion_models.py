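"""Discrete planar kinematic motion models: CV, CA, CTRV and CTRA.

All four models share a single closed-form one-step update that integrates

    x' = v cos(phi),  y' = v sin(phi),  phi' = w,  v' = a

exactly over one sample interval under piecewise-constant ``a`` and ``w``.
The update is written around the mid-step heading with series fallbacks for
small turn angles, so it is uniformly accurate in ``w`` (no division by the
turn rate anywhere) and continuous through ``w = 0``: CV and CA are simply
the ``w = 0`` evaluations of the same kernel, and CTRV/CTRA degrade
gracefully on straight-walking data where the turn rate hovers around zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["MotionState", "ModelKind", "propagate", "propagate_n", "wrap_angle"]

_TWO_PI = 2.0 * math.pi

#: below this step turn angle (w*dt, rad) series expansions replace the
#: closed-form trig expressions, which otherwise lose precision to
#: cancellation; well above machine noise, well below any walking turn step.
_SMALL_THETA = 1e-3


def wrap_angle(phi):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    wrapped = -(np.mod(-np.asarray(phi, dtype=float) + math.pi, _TWO_PI) - math.pi)
    if np.ndim(phi) == 0:
        return float(wrapped)
    return wrapped


class ModelKind(str, Enum):
    """The four kinematic model particularisations."""

    CV = "cv"
    CA = "ca"
    CTRV = "ctrv"
    CTRA = "ctra"

    @property
    def uses_accel(self) -> bool:
        return self in (ModelKind.CA, ModelKind.CTRA)

    @property
    def uses_turn(self) -> bool:
        return self in (ModelKind.CTRV, ModelKind.CTRA)


@dataclass(frozen=True)
class MotionState:
    """Planar motion state (x, y, phi, v, a, w) at one instant.

    Units: metres, radians, seconds. ``v`` may go negative during
    propagation (a decelerating CA/CTRA step is not clamped); estimated
    states always carry ``v >= 0``.
    """

    x: float
    y: float
    phi: float
    v: float
    a: float = 0.0
    w: float = 0.0

    def is_finite(self) -> bool:
        return all(
            math.isfinite(f) for f in (self.x, self.y, self.phi, self.v, self.a, self.w)
        )


def _turn_coefficients(theta):
    """Displacement shape factors for a step turn angle ``theta = w*dt``.

    Returns ``(s, h1, h2)`` such that, with mid-step heading
    ``phim = phi + theta/2``:

        dx = v*dt*cos(phim)*s + a*dt^2*( sin(phim)*h1 + cos(phim)*h2)
        dy = v*dt*sin(phim)*s + a*dt^2*(-cos(phim)*h1 + sin(phim)*h2)

    which reproduces the exact constant-turn-rate integrals and limits to
    the straight-line forms (s=1, h1=0, h2=1/2) as theta -> 0.
    """
    theta = np.asarray(theta, dtype=float)
    small = np.abs(theta) < _SMALL_THETA
    th = np.where(small, 1.0, theta)  # placeholder avoids 0/0 warnings
    t2 = theta * theta

    s = np.where(small, 1.0 - t2 / 24.0 + t2 * t2 / 1920.0, 2.0 * np.sin(th / 2.0) / th)
    h1 = np.where(
        small,
        -theta / 12.0 + theta * t2 / 480.0,
        (th * np.cos(th / 2.0) - 2.0 * np.sin(th / 2.0)) / (th * th),
    )
    h2 = np.where(small, 0.5 - t2 / 48.0 + t2 * t2 / 3840.0, np.sin(th / 2.0) / th)
    return s, h1, h2


def step_arrays(x, y, phi, v, a, w, dt):
    """Vectorised one-step update; broadcasts over array inputs.

    ``a`` and ``w`` are the *effective* per-step constants (already zeroed
    by the caller for models that do not use them). Returns the updated
    ``(x, y, phi, v)`` with ``phi`` wrapped to (-pi, pi].
    """
    theta = np.asarray(w, dtype=float) * dt
    s, h1, h2 = _turn_coefficients(theta)
    phim = phi + 0.5 * theta
    c = np.cos(phim)
    sn = np.sin(phim)
    adt2 = np.asarray(a, dtype=float) * dt * dt
    vdt = np.asarray(v, dtype=float) * dt
    new_x = x + vdt * c * s + adt2 * (sn * h1 + c * h2)
    new_y = y + vdt * sn * s + adt2 * (-c * h1 + sn * h2)
    new_phi = wrap_angle(phi + theta)
    new_v = v + np.asarray(a, dtype=float) * dt
    return new_x, new_y, new_phi, new_v


def effective_inputs(state: MotionState, model: ModelKind) -> tuple[float, float]:
    """Per-step constant (a, w) actually applied by ``model``."""
    a = state.a if model.uses_accel else 0.0
    w = state.w if model.uses_turn else 0.0
    return a, w


def propagate(state: MotionState, model: ModelKind, dt: float) -> MotionState:
    """Propagate ``state`` one step of ``dt`` seconds under ``model``.

    The ``a`` and ``w`` fields are carried through unchanged (they are the
    model's per-step constants), so recursive application reuses the same
    seed values. ``phi`` of the result is wrapped to (-pi, pi].
    """
    if not isinstance(model, ModelKind):
        model = ModelKind(model)
    if not state.is_finite():
        raise ValueError("motion state contains non-finite values")
    if not (math.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be a positive finite number, got {dt!r}")
    a_eff, w_eff = effective_inputs(state, model)
    x, y, phi, v = step_arrays(state.x, state.y, state.phi, state.v, a_eff, w_eff, dt)
    return MotionState(float(x), float(y), float(phi), float(v), state.a, state.w)


def propagate_n(
    state: MotionState, model: ModelKind, dt: float, n_steps: int
) -> list[MotionState]:
    """Apply :func:`propagate` recursively; returns the ``n_steps`` states
    after the seed (element ``i`` is the seed propagated ``i+1`` times)."""
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    out = []
    current = state
    for _ in range(n_steps):
        current = propagate(current, model, dt)
        out.append(current)
    return out
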