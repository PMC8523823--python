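"""Excitation-to-activation dynamics.

Muscle excitation (the processed, normalized EMG envelope) is turned into
muscle activation in two stages:

1. a second-order recursive filter modelling the twitch response,

       u(t) = alpha * e(t - d) - beta1 * u(t-1) - beta2 * u(t-2)

   with beta1 = C1 + C2, beta2 = C1*C2 and alpha - beta1 - beta2 = 1, which
   pins the DC gain of the filter at exactly 1 (a sustained excitation of 1
   produces a steady-state neural activation of 1).  The poles of the filter
   are -C1 and -C2, so stability requires |C1| < 1 and |C2| < 1.  ``d`` is the
   electromechanical delay, applied as a whole-sample shift.

2. a nonlinear shaping function accounting for the curvature of the
   excitation-to-force relationship,

       a(t) = (exp(A * u(t)) - 1) / (exp(A) - 1),

   with shape factor A in [-3, 0]; A -> 0 degenerates to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivationParams",
    "neural_activation",
    "activation_nonlinearity",
    "activation_from_excitation",
]

#: shape factors closer to zero than this use the analytic linear limit a = u
_LINEAR_SHAPE_EPS = 1e-6


@dataclass(frozen=True)
class ActivationParams:
    """Recursion constants, nonlinear shape factor and electromechanical delay.

    Attributes
    ----------
    c1, c2 :
        Recursion constants; the filter poles are ``-c1`` and ``-c2``, so both
        must lie strictly inside the unit interval.
    shape_factor :
        Nonlinear shape factor A in ``[-3, 0]``.
    delay_s :
        Electromechanical delay in seconds, converted to whole samples at the
        working rate.  Default 40 ms, the conventional value for this model
        family.
    """

    c1: float
    c2: float
    shape_factor: float
    delay_s: float = 0.040

    def __post_init__(self) -> None:
        if not (abs(self.c1) < 1.0 and abs(self.c2) < 1.0):
            raise ValueError(
                f"unstable recursion: need |C1| < 1 and |C2| < 1, got "
                f"C1={self.c1}, C2={self.c2}"
            )
        if not (-3.0 <= self.shape_factor <= 0.0):
            raise ValueError(
                f"shape factor A must lie in [-3, 0], got {self.shape_factor}"
            )
        if self.delay_s < 0.0:
            raise ValueError("electromechanical delay must be >= 0")

    @property
    def beta1(self) -> float:
        return self.c1 + self.c2

    @property
    def beta2(self) -> float:
        return self.c1 * self.c2

    @property
    def alpha(self) -> float:
        # unit DC gain constraint: alpha - beta1 - beta2 = 1
        return 1.0 + self.beta1 + self.beta2

    def delay_samples(self, rate: float) -> int:
        return int(round(self.delay_s * rate))


def neural_activation(
    e: np.ndarray, params: ActivationParams, rate: float
) -> np.ndarray:
    """Run the second-order recursive twitch filter on an excitation series.

    The electromechanical delay is applied as an integer sample shift
    (``round(d * rate)``) with zero fill at the head; initial conditions are
    ``u(-1) = u(-2) = 0``.
    """
    e = np.asarray(e, dtype=float)
    if e.ndim != 1:
        raise ValueError("excitation must be a 1-D series")
    if e.size and (e.min() < -1e-12 or e.max() > 1.0 + 1e-12):
        raise ValueError("excitation values must lie in [0, 1]")

    shift = params.delay_samples(rate)
    delayed = np.zeros_like(e)
    if shift < e.size:
        delayed[shift:] = e[: e.size - shift] if shift else e

    # recursion u(t) = alpha e(t-d) - beta1 u(t-1) - beta2 u(t-2); this is an
    # IIR filter with transfer function alpha / (1 + beta1 z^-1 + beta2 z^-2)
    from scipy.signal import lfilter

    u = lfilter([params.alpha], [1.0, params.beta1, params.beta2], delayed)
    return np.asarray(u)


def activation_nonlinearity(u: np.ndarray, shape_factor: float) -> np.ndarray:
    """Map neural activation to activation, a = (e^{Au} - 1)/(e^A - 1).

    ``u`` is clipped to [0, 1] first (the recursion can transiently
    overshoot); the output is then guaranteed to lie in [0, 1] with a(0) = 0
    and a(1) = 1.  Near A = 0 the analytic limit a = u is used.
    """
    if not (-3.0 <= shape_factor <= 0.0):
        raise ValueError(f"shape factor A must lie in [-3, 0], got {shape_factor}")
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    if abs(shape_factor) < _LINEAR_SHAPE_EPS:
        return u
    return np.expm1(shape_factor * u) / np.expm1(shape_factor)


def activation_from_excitation(
    e: np.ndarray, params: ActivationParams, rate: float
) -> np.ndarray:
    """Full excitation -> activation chain (recursive filter + nonlinearity)."""
    u = neural_activation(e, params, rate)
    return activation_nonlinearity(u, params.shape_factor)
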