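"""Wiener diffusion decision process: choice probabilities, first-passage
densities and trial simulation.

The decision variable starts at ``z * a`` and diffuses with drift ``v`` and
infinitesimal standard deviation ``s`` between absorbing boundaries at 0
(the "low" response) and ``a`` (the "high" response).  The observed reaction
time is the first-passage time plus a non-decision offset ``t0``.

Two density expansions of the first-passage-time distribution exist: a
small-time representation (sum over image charges) and a large-time
representation (sine series).  Each evaluation picks whichever series needs
fewer terms for the requested truncation error, which is the standard
adaptive-truncation approach for this density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._accel import njit

__all__ = [
    "DDMParams",
    "SimOutcome",
    "choice_probability",
    "wfpt_density",
    "mean_decision_time",
    "simulate_trial",
    "simulate_trials",
    "simulate_dataset",
]

#: default within-trial diffusion scale; the convention in which drift rates
#: like 0.013 evidence-units/s are commensurable with the EZ literature.
DEFAULT_SCALE = 0.1


@dataclass(frozen=True)
class DDMParams:
    """Generative diffusion parameters for one subject x trial type.

    v : drift rate (evidence units / s, signed toward the upper boundary)
    a : boundary separation (evidence units), > 0
    z : starting point as a fraction of ``a``, in (0, 1)
    t0 : non-decision time in seconds, >= 0
    s : within-trial diffusion scale (evidence units / sqrt(s)), > 0
    """

    v: float
    a: float
    z: float = 0.5
    t0: float = 0.0
    s: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"starting fraction z must be in (0, 1), got {self.z}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0}")
        if not (self.s > 0):
            raise ValueError(f"diffusion scale s must be > 0, got {self.s}")

    def rescaled(self, s_new: float) -> "DDMParams":
        """Same process expressed with a different diffusion scale.

        Dividing the evidence axis by a constant leaves first-passage times
        and choice probabilities unchanged, so (v, a) scale linearly with s.
        """
        factor = s_new / self.s
        return replace(self, v=self.v * factor, a=self.a * factor, s=s_new)


@dataclass(frozen=True)
class SimOutcome:
    """One simulated trial: which boundary absorbed, and the full RT."""

    boundary: str  # "upper" | "lower"
    rt: float  # seconds, includes t0


def choice_probability(params: DDMParams) -> float:
    """Probability of absorbing at the upper boundary.

    For v != 0 this is (1 - exp(-2 v z a / s^2)) / (1 - exp(-2 v a / s^2));
    at v = 0 the limit is z.
    """
    v, a, z, s = params.v, params.a, params.z, params.s
    x = 2.0 * v * a / (s * s)
    if x == 0.0:
        return z
    if x > 0:
        return math.expm1(-x * z) / math.expm1(-x)
    # v < 0: multiply through by e^x so every exponent is negative
    return math.exp(x * (1.0 - z)) * math.expm1(x * z) / math.expm1(x)


def mean_decision_time(params: DDMParams) -> float:
    """Expected first-passage time (either boundary), excluding t0.

    Uses Wald's identity E[X_T] = v E[T] with X_T in {0, a} starting from
    z*a; the zero-drift limit is the classical z*a*(a - z*a)/s^2.
    """
    v, a, z, s = params.v, params.a, params.z, params.s
    za = z * a
    if v == 0.0:
        return za * (a - za) / (s * s)
    return (a * choice_probability(params) - za) / v


@njit(cache=True)
def _wfpt_lower_unit(t: float, v: float, a: float, w: float, eps: float) -> float:
    """First-passage density at the *lower* boundary, unit diffusion scale.

    ``t`` is decision time (> 0); ``w`` the starting fraction.  ``eps`` is
    the absolute truncation error allowed on the returned density.
    """
    if t <= 0.0:
        return 0.0
    t_norm = t / (a * a)
    # allowance on the normalized density: the result is multiplied by
    # exp(-v a w - v^2 t / 2) / a^2, so scale eps accordingly (never below
    # a hard floor to keep term counts finite).
    scale = math.exp(-v * a * w - v * v * t / 2.0) / (a * a)
    if scale <= 0.0:
        return 0.0
    eps_norm = eps / scale
    if eps_norm < 1e-14:
        eps_norm = 1e-14
    # number of terms needed by each expansion
    if math.pi * t_norm * eps_norm < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * t_norm * eps_norm) / (math.pi * math.pi * t_norm))
        if kl < 1.0 / (math.pi * math.sqrt(t_norm)):
            kl = 1.0 / (math.pi * math.sqrt(t_norm))
    else:
        kl = 1.0 / (math.pi * math.sqrt(t_norm))
    if 2.0 * math.sqrt(2.0 * math.pi * t_norm) * eps_norm < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * t_norm * math.log(2.0 * math.sqrt(2.0 * math.pi * t_norm) * eps_norm))
        if ks < math.sqrt(t_norm) + 1.0:
            ks = math.sqrt(t_norm) + 1.0
    else:
        ks = 2.0

    p = 0.0
    if ks < kl:  # small-time (image-charge) representation
        K = int(math.ceil(ks))
        k_lo = -int(math.floor((K - 1) / 2.0))
        k_hi = int(math.ceil((K - 1) / 2.0))
        for k in range(k_lo, k_hi + 1):
            p += (w + 2.0 * k) * math.exp(-((w + 2.0 * k) ** 2) / (2.0 * t_norm))
        p /= math.sqrt(2.0 * math.pi * t_norm**3)
    else:  # large-time (sine series) representation
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k * k) * (math.pi * math.pi) * t_norm / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    if p < 0.0:  # truncation can leave a tiny negative residue
        p = 0.0
    return p * scale


@njit(cache=True)
def _wfpt_vec(ts, v: float, a: float, w: float, t0: float, eps: float):
    out = np.empty(ts.shape[0])
    for i in range(ts.shape[0]):
        out[i] = _wfpt_lower_unit(ts[i] - t0, v, a, w, eps)
    return out


def wfpt_density(t, params: DDMParams, boundary: str = "upper", eps: float = 1e-7):
    """Wiener first-passage-time density at the given boundary.

    ``t`` is the observed RT (seconds, including ``t0``); scalar or array.
    Returns 0 for ``t <= t0``.  Absolute truncation error <= ``eps``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    # normalize to unit diffusion scale
    vn = params.v / params.s
    an = params.a / params.s
    if boundary == "upper":
        vn, w = -vn, 1.0 - params.z
    else:
        w = params.z
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = _wfpt_vec(ts, vn, an, w, params.t0, eps)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


@njit(cache=True)
def _simulate_kernel(n: int, v: float, a: float, za: float, t0: float, s: float,
                     dt: float, seed: int, shrink: float):
    """Euler-Maruyama first-passage simulation.

    ``shrink`` moves both absorbing thresholds inward by the standard
    continuity correction 0.5826 * s * sqrt(dt), removing the O(sqrt(dt))
    late-crossing bias of discrete-time monitoring.
    """
    np.random.seed(seed)
    rts = np.empty(n)
    upper = np.empty(n, dtype=np.int8)
    sdt = s * math.sqrt(dt)
    lo = shrink
    hi = a - shrink
    for i in range(n):
        x = za
        t = 0.0
        while True:
            x += v * dt + sdt * np.random.randn()
            t += dt
            if x >= hi:
                upper[i] = 1
                break
            if x <= lo:
                upper[i] = 0
                break
        rts[i] = t + t0
    return rts, upper


def simulate_trials(params: DDMParams, n: int, dt: float = 1e-3,
                    rng: np.random.Generator | int | None = None,
                    continuity_correction: bool = True):
    """Simulate ``n`` independent trials; returns (rt array, upper array).

    ``rt`` includes ``t0``; ``upper`` is 1 when the upper boundary absorbed.
    Reproducible given a seeded ``rng``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))
    shrink = 0.5826 * params.s * math.sqrt(dt) if continuity_correction else 0.0
    if 2.0 * shrink >= params.a:
        raise ValueError("dt too coarse for this boundary separation")
    za = params.z * params.a
    if not (shrink < za < params.a - shrink):
        raise ValueError("starting point lies outside the corrected boundaries")
    return _simulate_kernel(n, params.v, params.a, za, params.t0, params.s,
                            dt, seed, shrink)


def simulate_trial(params: DDMParams, dt: float = 1e-3,
                   rng: np.random.Generator | int | None = None) -> SimOutcome:
    """Simulate a single trial."""
    rts, upper = simulate_trials(params, 1, dt=dt, rng=rng)
    return SimOutcome(boundary="upper" if upper[0] else "lower", rt=float(rts[0]))


def simulate_dataset(params_by_trialtype: dict, schedule, dt: float = 1e-3,
                     rng: np.random.Generator | int | None = None,
                     lapse_prob: float = 0.0):
    """Simulate one outcome per scheduled trial.

    ``params_by_trialtype`` maps tone labels ("low", "mid", "high") to
    DDMParams.  For the mid tone the upper boundary is the *high-reward*
    response (stimulus coding); for unambiguous tones it is the *correct*
    response (accuracy coding).  With probability ``lapse_prob`` a trial is
    marked missed (no response).

    Returns a list of dicts with keys trial_index, tone, condition,
    scheduled_outcome, boundary (upper|lower|none), rt (seconds or nan).
    """
    rng = np.random.default_rng(rng)
    frame = schedule.frame if hasattr(schedule, "frame") else schedule
    tones = frame["tone"].to_numpy()
    missing = set(np.unique(tones)) - set(params_by_trialtype)
    if missing:
        raise KeyError(f"missing DDM parameters for trial types: {sorted(missing)}")
    out = [None] * len(frame)
    rows = frame.reset_index(drop=True)
    for tone in np.unique(tones):
        idx = np.flatnonzero(tones == tone)
        rts, upper = simulate_trials(params_by_trialtype[tone], len(idx), dt=dt, rng=rng)
        lapses = rng.random(len(idx)) < lapse_prob
        for k, i in enumerate(idx):
            row = rows.iloc[i]
            if lapses[k]:
                out[i] = dict(trial_index=int(row["trial_index"]), tone=tone,
                              condition=row.get("condition", "neutral"),
                              scheduled_outcome=row.get("scheduled_outcome", ""),
                              boundary="none", rt=float("nan"))
            else:
                out[i] = dict(trial_index=int(row["trial_index"]), tone=tone,
                              condition=row.get("condition", "neutral"),
                              scheduled_outcome=row.get("scheduled_outcome", ""),
                              boundary="upper" if upper[k] else "lower",
                              rt=float(rts[k]))
    return out
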