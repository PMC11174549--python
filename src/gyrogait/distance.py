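"""Per-step angular displacement selection and chord-model distance.

A step's travelled distance is modelled as the chord of a circle of radius
``L`` (the configured leg length) subtending the net shank angular
displacement ``theta``::

    d = L * sqrt(2 * (1 - cos(theta))) = 2 * L * sin(|theta| / 2)

The ``2*L*sin(|theta|/2)`` form is used numerically for small-angle
stability; both are identical in exact arithmetic.
"""

from __future__ import annotations

import math
import warnings

__all__ = ["select_displacement", "step_distance", "reset_integrators"]


def select_displacement(theta_pos: float, theta_neg: float) -> float:
    """Pick the dominant signed displacement of a step.

    ``theta_pos`` is the accumulated positive angular displacement over the
    TO->IC window (>= 0) and ``theta_neg`` the accumulated negative one
    (<= 0).  The one with the larger magnitude wins, sign preserved, which
    is what lets backward steps come out negative.
    """
    if theta_pos < 0:
        raise ValueError("theta_pos must be >= 0")
    if theta_neg > 0:
        raise ValueError("theta_neg must be <= 0")
    return theta_pos if theta_pos >= -theta_neg else theta_neg


def step_distance(theta: float, leg_length: float) -> float:
    """Chord distance for a step of displacement ``theta`` (rad).

    Even in ``theta``; ``|theta|`` is clamped at pi (with a warning) because
    the chord is non-monotone beyond it.  The result lies in
    ``[0, 2 * leg_length]``.
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    a = abs(theta)
    if a > math.pi:
        warnings.warn(
            f"|theta|={a:.4g} exceeds pi; clamping to pi", RuntimeWarning, stacklevel=2
        )
        a = math.pi
    return 2.0 * leg_length * math.sin(a / 2.0)


def reset_integrators(state) -> None:
    """Zero a detector state's displacement accumulators in place.

    Called after each emitted step so that integration drift can never
    propagate across step boundaries: the next step's displacement depends
    only on samples after its own TO.
    """
    state.cum_pos = 0.0
    state.cum_neg = 0.0
    state.cand_pos_snap = 0.0
    state.cand_neg_snap = 0.0
    state.to_pos_snap = 0.0
    state.to_neg_snap = 0.0
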