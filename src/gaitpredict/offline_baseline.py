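"""Offline polynomial-regression baseline: whole-signal smoothing of the
walked path to strip gait-induced waviness, plus its derived states.

This is the acausal reference route — it sees the entire recording, so it
can never run inside the real-time prediction path. Straight segments use
degree 1, single-turn curved segments degree 8 by convention; multi-turn
recordings must be pre-split into single-turn segments.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import Polynomial

from .state_estimation import StateSequence, Trajectory, estimate_raw_states

__all__ = ["fit_baseline", "estimate_offline_states"]

DEGREE_STRAIGHT = 1
DEGREE_CURVED = 8


def _fit_channel(t: np.ndarray, values: np.ndarray, degree: int) -> np.ndarray:
    # Polynomial.fit maps the abscissa to [-1, 1] internally (conditioning)
    poly = Polynomial.fit(t, values, deg=degree)
    return poly(t)


def fit_baseline(
    traj: Trajectory,
    degree: int,
    segments: list[tuple[int, int]] | None = None,
) -> Trajectory:
    """Least-squares polynomial fit of x(t) and y(t) at the given degree.

    ``segments`` is an optional list of 0-based half-open ``[start, end)``
    sample-index pairs; each segment is fitted independently (required when
    a curved recording spans several turns). The pelvis channel passes
    through untouched.
    """
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    if segments is None:
        segments = [(0, traj.n)]
    xs = traj.x.copy()
    ys = traj.y.copy()
    for start, end in segments:
        if not (0 <= start < end <= traj.n):
            raise ValueError(f"segment [{start}, {end}) out of range for n={traj.n}")
        if end - start <= degree + 1:
            raise ValueError(
                f"segment [{start}, {end}) has {end - start} samples, "
                f"too few for a degree-{degree} fit"
            )
        sl = slice(start, end)
        xs[sl] = _fit_channel(traj.t[sl], traj.x[sl], degree)
        ys[sl] = _fit_channel(traj.t[sl], traj.y[sl], degree)
    return Trajectory(t=traj.t.copy(), x=xs, y=ys, phi_pelvis=traj.phi_pelvis.copy())


def estimate_offline_states(baseline: Trajectory) -> StateSequence:
    """Derive the offline state sequence from a smoothed baseline trajectory."""
    return estimate_raw_states(baseline, variant="offline")
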