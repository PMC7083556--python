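"""EZ-diffusion: closed-form mapping between diffusion parameters and the
three mid-tone summary statistics (proportion of positive responses, RT
mean, RT variance).

The EZ model assumes an unbiased start (z = 1/2).  With y = -v*a/s^2 the
forward moments are

    P+   = 1 / (1 + e^y)
    MDT  = (a^2 / 4 s^2) * tanh(y/2) / (y/2)          (mean decision time)
    VDT  = (a^4 / 2 s^4) * g(y),   g(y) = -(2 y e^y - e^{2y} + 1) / (y^3 (e^y+1)^2)

with MRT = Ter + MDT and g(0) = 1/12.  The inverse is the standard
algebraic inversion of these equations; it is exact, so the forward model
doubles as its oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ddm import DEFAULT_SCALE

__all__ = ["EZInputs", "EZEstimate", "ez_forward", "ez_inverse", "edge_correct"]


@dataclass(frozen=True)
class EZInputs:
    """Observed mid-tone summaries for one subject.

    p_pos : proportion of positive (upper-boundary) responses, in (0, 1)
            after edge correction
    mrt   : mean RT in seconds
    vrt   : RT variance in seconds^2 (denominator n - 1)
    n     : responded trial count (used for edge correction)
    """

    p_pos: float
    mrt: float
    vrt: float
    n: int = 0

    def __post_init__(self):
        if not (0.0 < self.p_pos < 1.0):
            raise ValueError("p_pos must lie strictly in (0, 1); apply edge_correct first")
        if self.mrt <= 0:
            raise ValueError("mean RT must be positive")
        if self.vrt <= 0:
            raise ValueError("RT variance must be positive")


@dataclass(frozen=True)
class EZEstimate:
    """Recovered (v, a, Ter) in the stated diffusion-scale convention."""

    v: float
    a: float
    ter: float
    s: float = DEFAULT_SCALE


def _g(y: float) -> float:
    """-(2 y e^y - e^{2y} + 1) / (y^3 (e^y + 1)^2), continuous at 0."""
    ay = abs(y)
    if ay < 1e-3:
        # series: -(N)/y^3 = 1/3 + y/3 + 11 y^2/60 + O(y^3)
        return (1.0 / 3.0 + y / 3.0 + 11.0 * y * y / 60.0) / (math.exp(y) + 1.0) ** 2
    if y > 30.0:
        # divide through by e^{2y} to avoid overflow
        num = 1.0 - 2.0 * y * math.exp(-y) - math.exp(-2.0 * y)
        return num / (y**3 * (1.0 + math.exp(-y)) ** 2)
    num = -(2.0 * y * math.exp(y) - math.exp(2.0 * y) + 1.0)
    return num / (y**3 * (math.exp(y) + 1.0) ** 2)


def _tanhc(u: float) -> float:
    """tanh(u)/u, continuous at 0."""
    if abs(u) < 1e-6:
        return 1.0 - u * u / 3.0
    return math.tanh(u) / u


def ez_forward(v: float, a: float, ter: float, s: float = DEFAULT_SCALE) -> tuple:
    """Exact first two decision-time moments and choice probability of the
    unbiased diffusion; returns (p_pos, mrt, vrt)."""
    if a <= 0 or s <= 0:
        raise ValueError("a and s must be positive")
    if ter < 0:
        raise ValueError("ter must be non-negative")
    y = -v * a / (s * s)
    p_pos = 1.0 / (1.0 + math.exp(y)) if abs(y) < 500 else (0.0 if y > 0 else 1.0)
    mdt = (a * a / (4.0 * s * s)) * _tanhc(y / 2.0)
    vdt = (a**4 / (2.0 * s**4)) * _g(y)
    return p_pos, ter + mdt, vdt


def edge_correct(p_pos: float, n: int) -> tuple:
    """Shrink degenerate response proportions so the EZ inversion exists.

    p = 0 -> 1/(2n); p = 1 -> 1 - 1/(2n); p = 1/2 -> 1/2 + 1/(2n) (flagged,
    since the drift sign is genuinely indeterminate there).  Returns
    (corrected proportion, flagged).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= p_pos <= 1.0):
        raise ValueError("p_pos must lie in [0, 1]")
    half = 1.0 / (2.0 * n)
    if p_pos == 0.0:
        # at n = 1 the shrunk value would itself be 1/2; keep it on the
        # observed side so the inversion stays defined
        return (half if half != 0.5 else 0.25), False
    if p_pos == 1.0:
        return (1.0 - half if half != 0.5 else 0.75), False
    if p_pos == 0.5:
        return min(0.5 + half, 0.75), True
    return p_pos, False


def ez_inverse(inputs: EZInputs, s: float = DEFAULT_SCALE) -> EZEstimate:
    """Closed-form EZ inversion of (p_pos, mrt, vrt) to (v, a, Ter).

    Exact inverse of :func:`ez_forward`; sign(v) = sign(p_pos - 1/2).
    """
    p, mrt, vrt = inputs.p_pos, inputs.mrt, inputs.vrt
    if p == 0.5:
        raise ValueError("p_pos must differ from 1/2; apply edge_correct first")
    L = math.log(p / (1.0 - p))
    x = L * (L * p * p - L * p + p - 0.5) / vrt
    v = math.copysign(1.0, p - 0.5) * s * x**0.25
    a = s * s * L / v
    y = -v * a / (s * s)  # equals -L
    mdt = (a * a / (4.0 * s * s)) * _tanhc(y / 2.0)
    return EZEstimate(v=v, a=a, ter=mrt - mdt, s=s)


def ez_from_trials(upper: np.ndarray, rt: np.ndarray, s: float = DEFAULT_SCALE) -> EZEstimate:
    """EZ estimate straight from responded trials.

    ``upper`` is 1 for positive (upper-boundary) responses, ``rt`` in
    seconds; RT variance uses denominator n - 1.
    """
    upper = np.asarray(upper)
    rt = np.asarray(rt, dtype=float)
    n = len(rt)
    if n < 2:
        raise ValueError("need at least 2 responded trials")
    p, _ = edge_correct(float(np.mean(upper)), n)
    inputs = EZInputs(p_pos=p, mrt=float(np.mean(rt)), vrt=float(np.var(rt, ddof=1)), n=n)
    return ez_inverse(inputs, s=s)
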