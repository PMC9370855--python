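"""Independent oracles used by the tests.

These deliberately avoid the package's propagation kernel: the ODE oracle
is a plain RK4 integrator of the continuous planar motion equations with
piecewise-constant acceleration and turn rate.
"""

from __future__ import annotations

import numpy as np


def rk4_propagate(x, y, phi, v, a, w, dt, n_sub=20):
    """RK4 integration of x'=v cos(phi), y'=v sin(phi), phi'=w, v'=a."""
    h = dt / n_sub

    def deriv(state):
        _, _, phi_, v_ = state
        return np.array([v_ * np.cos(phi_), v_ * np.sin(phi_), w, a])

    s = np.array([x, y, phi, v], dtype=float)
    for _ in range(n_sub):
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * h * k1)
        k3 = deriv(s + 0.5 * h * k2)
        k4 = deriv(s + h * k3)
        s = s + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return s[0], s[1], s[2], s[3]


def wrap_pm_pi(phi):
    """Reference wrap to (-pi, pi] via plain modular arithmetic."""
    out = np.mod(phi + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out) if np.ndim(phi) else (
        np.pi if out == -np.pi else float(out)
    )


def half_ptp(signal):
    """Oscillation amplitude as half the peak-to-peak of a 1-D signal."""
    signal = np.asarray(signal)
    return 0.5 * (signal.max() - signal.min())
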