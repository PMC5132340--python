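"""Closed-form Wiener diffusion choice probabilities and conditional mean
decision times, plus a Monte-Carlo simulator used as the validation oracle.

The decision variable follows ``dX = mu*dt + sigma*dW`` between two absorbing
boundaries placed at 0 (alternative option) and ``A`` (default option).  The
accumulator starts at ``z = A/2 + S``: ``S = 0`` means an unbiased start at
the midpoint, positive ``S`` shifts the start toward the default boundary.
Choice is determined by which boundary is hit first; response time is the
first-passage time plus a non-decision time ``Tnd``.

With ``k = 2*mu/sigma**2`` the absorption probability at the default
boundary is::

    P(default) = (1 - exp(-k*z)) / (1 - exp(-k*A))

and the mean first-passage time conditional on absorbing at the default
boundary is::

    E[T | default] = (A*coth(k*A/2) - z*coth(k*z/2)) / mu

The alternative-boundary quantities follow from the reflection substitution
(mu, z) -> (-mu, A - z).  Both expressions reduce analytically as mu -> 0 to
``z/A`` and ``(A**2 - z**2) / (3*sigma**2)`` respectively; the code switches
to series expansions near that singularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "p_default",
    "p_alternative",
    "mean_rt",
    "p_upper",
    "cond_mean_upper",
    "simulate_paths",
    "attentional_drift",
]

# below this value of |k*A| the mu -> 0 series expansions take over
_SMALL_KA = 1e-6
# exponent clip guarding exp overflow; beyond it the asymptotic limit applies
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class DDMParams:
    """Parameters of a two-boundary Wiener diffusion with biased start.

    Parameters
    ----------
    A : float
        Boundary separation (evidence units), > 0.  The alternative boundary
        sits at 0 and the default boundary at A.
    S : float
        Signed starting-point shift from the midpoint toward the default
        boundary (evidence units); must satisfy ``|S| < A/2``.
    mu : float
        Mean drift rate (evidence units per second); positive drift favours
        the default option.
    sigma : float
        Diffusion standard deviation (evidence units per sqrt(second)), > 0.
        Fixed to 1 during fitting because of the scale degeneracy with A
        and mu.
    tnd : float
        Non-decision time in seconds (encoding + motor), >= 0.
    """

    A: float
    S: float = 0.0
    mu: float = 0.0
    sigma: float = 1.0
    tnd: float = 0.0

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"boundary separation A must be > 0, got {self.A}")
        if not self.sigma > 0:
            raise ValueError(f"diffusion SD sigma must be > 0, got {self.sigma}")
        if self.tnd < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.tnd}")
        if not abs(self.S) < self.A / 2:
            raise ValueError(
                f"starting point shift |S|={abs(self.S)} must be < A/2={self.A / 2}"
            )

    @property
    def z(self) -> float:
        """Absolute starting position between the boundaries 0 and A."""
        return self.A / 2 + self.S

    def to_dict(self) -> dict:
        return {"A": self.A, "S": self.S, "mu": self.mu, "sigma": self.sigma, "tnd": self.tnd}

    @classmethod
    def from_dict(cls, d: dict) -> "DDMParams":
        return cls(**d)


def p_upper(z, a, mu, sigma2):
    """Probability of absorption at the upper boundary ``a``; vectorized.

    Stable across the mu -> 0 singularity (analytic limit z/a) and for
    drifts large enough to overflow the exponentials (limits 0 and 1).
    """
    z = np.asarray(z, dtype=float)
    a = np.asarray(a, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k = 2.0 * mu / np.asarray(sigma2, dtype=float)
    ka = k * a
    small = np.abs(ka) < _SMALL_KA
    # correction to first order in k keeps the function smooth at the branch
    # point: P = z/a + k*z*(a-z)/(2a) + O(k^2)
    p_small = z / a + k * z * (a - z) / (2.0 * a)
    with np.errstate(over="ignore", invalid="ignore"):
        num = np.expm1(np.clip(-k * z, -_EXP_CLIP, _EXP_CLIP))
        den = np.expm1(np.clip(-ka, -_EXP_CLIP, _EXP_CLIP))
        p_gen = num / den
    # strong negative drift: both expm1 saturate; use log-space ratio
    strong_neg = -ka > _EXP_CLIP
    p_neg = np.exp(np.clip(k * (a - z), -_EXP_CLIP, 0.0))
    p = np.where(small, p_small, np.where(strong_neg, p_neg, p_gen))
    return p if p.ndim else float(p)


def _coth(x):
    """coth(x) stable for large |x| (tanh saturates to +-1 exactly)."""
    return 1.0 / np.tanh(x)


def cond_mean_upper(z, a, mu, sigma2):
    """Mean first-passage time conditional on absorption at ``a``; vectorized.

    ``(a*coth(k*a/2) - z*coth(k*z/2)) / mu`` with a series branch for
    |k*a| small where the direct expression cancels catastrophically:
    ``(a^2 - z^2)/(3*sigma^2) - k^2 (a^4 - z^4)/(180? ...)`` — the code keeps
    the leading and first correction terms.
    """
    z = np.asarray(z, dtype=float)
    a = np.asarray(a, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k = 2.0 * mu / s2
    ka = k * a
    # series branch: coth(x) = 1/x + x/3 - x^3/45 + ...
    # => E[T|upper] = (a^2 - z^2)/(3 s2) - k^2 (a^4 - z^4)/(90 s2) * (1/2)
    small = np.abs(ka) < 1e-3
    t_small = (a**2 - z**2) / (3.0 * s2) - k**2 * (a**4 - z**4) / (180.0 * s2)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        mu_safe = np.where(mu == 0.0, 1.0, mu)
        ka_h = np.clip(k * a / 2.0, -_EXP_CLIP, _EXP_CLIP)
        kz_h = np.clip(k * z / 2.0, -_EXP_CLIP, _EXP_CLIP)
        ka_h = np.where(ka_h == 0.0, 1.0, ka_h)  # dead branch, avoids 0/0
        kz_h = np.where(kz_h == 0.0, 1.0, kz_h)
        t_gen = (a * _coth(ka_h) - z * _coth(kz_h)) / mu_safe
    t = np.where(small, t_small, t_gen)
    return t if t.ndim else float(t)


def p_default(params: DDMParams) -> float:
    """Probability that the default (upper) boundary is hit first."""
    return float(p_upper(params.z, params.A, params.mu, params.sigma**2))


def p_alternative(params: DDMParams) -> float:
    """Probability that the alternative (lower) boundary is hit first."""
    return 1.0 - p_default(params)


def mean_rt(params: DDMParams, outcome: str = "default") -> float:
    """Mean response time conditional on the stated choice outcome.

    The alternative-outcome value is obtained exactly by the reflection
    substitution: drift negated, start reflected about the midpoint.
    """
    s2 = params.sigma**2
    if outcome == "default":
        t = cond_mean_upper(params.z, params.A, params.mu, s2)
    elif outcome == "alternative":
        t = cond_mean_upper(params.A - params.z, params.A, -params.mu, s2)
    else:
        raise ValueError(f"outcome must be 'default' or 'alternative', got {outcome!r}")
    return params.tnd + float(t)


@njit(cache=True, fastmath=True)
def _simulate_kernel(z, a, mu, sigma, n, dt, seed, horizon):  # pragma: no cover - jit
    np.random.seed(seed)
    out = np.empty(n, dtype=np.int64)
    rts = np.empty(n, dtype=np.float64)
    sd = sigma * np.sqrt(dt)
    drift = mu * dt
    s2dt = sigma * sigma * dt
    # beyond this product of endpoint-boundary distances the bridge
    # crossing probability is < exp(-40): skip the exponentials
    cut = 20.0 * s2dt
    max_steps = int(horizon / dt)
    blk = 512
    for i in range(n):
        x = z
        outcome = -1
        step = 0
        while step < max_steps and outcome == -1:
            m = min(blk, max_steps - step)
            eps = np.random.standard_normal(m)
            for j in range(m):
                x1 = x + drift + sd * eps[j]
                step += 1
                if x1 >= a:
                    outcome = 1
                    break
                if x1 <= 0.0:
                    outcome = 0
                    break
                # Brownian-bridge probability that the path crossed a
                # boundary within the step even though both endpoints lie
                # inside; plain endpoint tests underestimate absorption
                # by O(sqrt(dt)).
                du = (a - x) * (a - x1)
                dl = x * x1
                if du < cut or dl < cut:
                    pu = np.exp(-2.0 * du / s2dt)
                    pl = np.exp(-2.0 * dl / s2dt)
                    u = np.random.random()
                    if u < pu:
                        outcome = 1
                        break
                    if u < pu + pl:
                        outcome = 0
                        break
                x = x1
        out[i] = outcome
        rts[i] = step * dt
    return out, rts


def simulate_paths(
    params: DDMParams,
    n: int,
    dt: float = 5e-4,
    seed: int = 0,
    horizon: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama simulation of ``n`` diffusion paths.

    Returns ``(outcomes, rts)`` where outcome 1 = default boundary,
    0 = alternative boundary, -1 = not absorbed within ``horizon`` seconds
    (truncated paths are reported, never silently dropped); ``rts`` include
    the non-decision time for absorbed paths.

    Each step applies the Brownian-bridge crossing correction, removing the
    O(sqrt(dt)) absorption bias of endpoint-only tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < dt <= 0.01:
        raise ValueError("dt must be in (0, 0.01] seconds")
    out, rts = _simulate_kernel(
        params.z, params.A, params.mu, params.sigma, n, dt, int(seed) & 0x7FFFFFFF, horizon
    )
    rts = rts + np.where(out >= 0, params.tnd, 0.0)
    return out, rts


def attentional_drift(v_def, v_alt, d_def, d_alt, theta, alpha):
    """Gaze-weighted drift rate of the attentional DDM.

    ``alpha * [(v_def - theta*v_alt)*D_def - (v_alt - theta*v_def)*D_alt]
    / (D_def + D_alt)`` where D are total fixation durations and
    ``theta`` in [0, 1] discounts the momentarily unfixated option's value.
    At ``theta = 1`` this reduces to ``alpha * (v_def - v_alt)`` regardless
    of the fixation pattern.
    """
    d_def = np.asarray(d_def, dtype=float)
    d_alt = np.asarray(d_alt, dtype=float)
    total = d_def + d_alt
    if np.any(total <= 0):
        raise ValueError("trial has zero total fixation duration; unusable for aDDM")
    v_def = np.asarray(v_def, dtype=float)
    v_alt = np.asarray(v_alt, dtype=float)
    num = (v_def - theta * v_alt) * d_def - (v_alt - theta * v_def) * d_alt
    res = alpha * num / total
    return res if res.ndim else float(res)
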