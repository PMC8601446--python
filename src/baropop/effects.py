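"""Saturating effect curves.

Every neurohumoral determinant in the model acts through a dimensionless
multiplier: a monotone, saturating (logistic) function of its input that is
normalized to 1 at the input's normal operating value.  The curve is

    E(x) = lower + (upper - lower) / (1 + A * exp(-k * (x - x0)))

with ``A = (upper - 1) / (1 - lower)`` chosen so that ``E(x0) = 1`` exactly.
``k > 0`` gives a multiplier increasing in ``x`` (saturating at ``upper`` as
x -> +inf), ``k < 0`` a decreasing one.  Bounds are (lower, upper) open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EffectSpec:
    """A normalized saturating effect curve.

    Parameters
    ----------
    lower, upper : float
        Saturation bounds; must bracket 1 strictly (lower < 1 < upper).
    slope : float
        Logistic rate ``k``; its sign sets the direction of the effect.
    x0 : float
        Normal operating input, at which the multiplier equals 1.
    """

    lower: float
    upper: float
    slope: float
    x0: float

    def __post_init__(self) -> None:
        if not (self.lower < 1.0 < self.upper):
            raise ValueError(
                f"saturations must bracket 1: lower={self.lower}, upper={self.upper}"
            )

    @property
    def _amplitude(self) -> float:
        return (self.upper - 1.0) / (1.0 - self.lower)

    def slope_at_normal(self) -> float:
        """dE/dx evaluated at x0 (sign matches ``slope``)."""
        a = self._amplitude
        span = self.upper - self.lower
        return self.slope * span * a / (1.0 + a) ** 2


def effect_multiplier(x, spec: EffectSpec, gain: float | np.ndarray = 1.0):
    """Evaluate a normalized effect curve.

    ``gain`` multiplies the logistic rate (it is how per-patient sensitivity
    coefficients steepen or flatten a curve without moving its anchor).
    Inputs must be finite; the result is always within (lower, upper) and
    equals 1 at ``x = spec.x0``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("effect_multiplier: non-finite input")
    return _eval(x, spec, gain)


def _eval(x, spec: EffectSpec, gain=1.0):
    """Unchecked evaluation (hot path of the equilibrium solver)."""
    a = spec._amplitude
    u = np.clip(spec.slope * gain * (x - spec.x0), -500.0, 500.0)
    return spec.lower + (spec.upper - spec.lower) / (1.0 + a * np.exp(-u))
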