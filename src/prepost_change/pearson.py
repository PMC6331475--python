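"""Random variates from the Pearson distribution system.

The Pearson system is the family of densities solving

    p'(x) / p(x) = -(x + c1) / (c0 + c1*x + c2*x**2)

for a standardized variable (mean 0, variance 1).  Given a target skewness
``g1`` and excess kurtosis ``g2`` the coefficients are fixed by the first four
moments, and the sign pattern of the quadratic denominator selects one of
eight classical types.  This module classifies the requested ``(g1, g2)`` pair
on the (beta1, beta2) plane and returns draws from the matching distribution:

====  =========================================  =========================
type  region                                     sampler
====  =========================================  =========================
0     g1 = 0, g2 = 0                             normal
I     kappa < 0 (real roots straddling 0)        shifted/scaled beta
II    g1 = 0, g2 < 0                             symmetric beta (via I)
III   c2 = 0                                     shifted/scaled gamma
IV    0 <= kappa < 1, complex roots              inverse-CDF in arctan space
V     kappa = 1 (double real root)               shifted inverse-gamma
VI    kappa > 1 (real roots, same side of 0)     shifted/scaled beta-prime
VII   g1 = 0, g2 > 0                             rescaled Student t
====  =========================================  =========================

where ``kappa = c1**2 / (4*c0*c2)``.  All types except IV reduce to a frozen
scipy.stats distribution.  Type IV has no closed-form scipy counterpart; it is
sampled exactly up to grid resolution by substituting ``x = lam + a*tan(phi)``,
under which the density becomes ``cos(phi)**(2m-2) * exp(-nu*phi)`` on the
bounded interval (-pi/2, pi/2), where a fine tabulated inverse CDF is cheap
and numerically benign (the heavy power-law tails map to the endpoints).

Negative skewness is handled by sampling the mirrored ``(-g1, g2)`` member and
negating, so every per-type construction only needs the g1 >= 0 orientation.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from ._exceptions import FeasibilityError

__all__ = [
    "check_feasibility",
    "pearson_type",
    "pearson_sampler",
    "sample_pearson",
]

# Number of interior grid points for the type-IV tabulated inverse CDF.
_TYPE_IV_GRID = 2**16 + 1


def check_feasibility(skewness: float, excess_kurtosis: float) -> None:
    """Raise :class:`FeasibilityError` if no Pearson density has these moments.

    Every distribution satisfies ``kurtosis >= skewness**2 + 1`` (raw moments),
    i.e. ``g2 >= g1**2 - 2`` in excess terms.  Equality is attained only by
    two-point distributions, which have no density, so it is rejected too.
    """
    if not (np.isfinite(skewness) and np.isfinite(excess_kurtosis)):
        raise FeasibilityError("skewness and kurtosis must be finite")
    bound = skewness**2 - 2.0
    if excess_kurtosis <= bound:
        raise FeasibilityError(
            f"(skewness={skewness}, excess_kurtosis={excess_kurtosis}) is "
            f"infeasible: excess kurtosis must exceed skewness^2 - 2 = {bound}"
        )


def _coefficients(g1: float, g2: float) -> tuple[float, float, float]:
    """Pearson ODE coefficients (c0, c1, c2) for unit-variance moments."""
    beta1 = g1**2
    beta2 = g2 + 3.0  # raw kurtosis
    denom = 10.0 * beta2 - 12.0 * beta1 - 18.0
    if abs(denom) < 1e-12:
        raise FeasibilityError(
            f"(skewness={g1}, excess_kurtosis={g2}) lies on the singular line "
            "10*beta2 - 12*beta1 - 18 = 0 of the Pearson coefficient formulas"
        )
    c0 = (4.0 * beta2 - 3.0 * beta1) / denom
    c1 = g1 * (beta2 + 3.0) / denom
    c2 = (2.0 * beta2 - 3.0 * beta1 - 6.0) / denom
    return c0, c1, c2


def pearson_type(skewness: float, excess_kurtosis: float) -> int:
    """Return the Pearson type (0-7) selected for the given shape pair."""
    check_feasibility(skewness, excess_kurtosis)
    g1, g2 = abs(float(skewness)), float(excess_kurtosis)
    if g1 == 0.0 and g2 == 0.0:
        return 0
    c0, c1, c2 = _coefficients(g1, g2)
    if abs(c2) < 1e-10:
        return 3 if g1 > 0 else 0
    if g1 == 0.0:
        return 2 if g2 < 0 else 7
    kappa = c1**2 / (4.0 * c0 * c2)
    if kappa < 0.0:
        return 1
    if abs(kappa - 1.0) < 1e-10:
        return 5
    return 4 if kappa < 1.0 else 6


def _quad_roots(c0: float, c1: float, c2: float) -> tuple[float, float]:
    """Real roots a1 < a2 of c0 + c1*x + c2*x**2."""
    disc = c1**2 - 4.0 * c0 * c2
    sq = math.sqrt(disc)
    r1 = (-c1 - sq) / (2.0 * c2)
    r2 = (-c1 + sq) / (2.0 * c2)
    return min(r1, r2), max(r1, r2)


def _partial_fraction_exponents(
    c0: float, c1: float, c2: float, a1: float, a2: float
) -> tuple[float, float]:
    """Exponents (e1, e2) of |x - a1|, |x - a2| in the Pearson density."""
    e1 = -(a1 + c1) / (c2 * (a1 - a2))
    e2 = -(a2 + c1) / (c2 * (a2 - a1))
    return e1, e2


class _TypeIVSampler:
    """Inverse-CDF sampler for Pearson type IV via the arctan substitution."""

    def __init__(self, m: float, nu: float, lam: float, a: float):
        self.m, self.nu, self.lam, self.a = m, nu, lam, a
        phi = np.linspace(-np.pi / 2.0, np.pi / 2.0, _TYPE_IV_GRID)[1:-1]
        logf = (2.0 * m - 2.0) * np.log(np.cos(phi)) - nu * phi
        f = np.exp(logf - logf.max())
        cdf = np.concatenate([[0.0], cumulative_trapezoid(f, phi)])
        cdf /= cdf[-1]
        self._phi, self._cdf = phi, cdf

    def rvs(self, size: int, random_state: np.random.Generator) -> np.ndarray:
        u = random_state.random(size)
        phi = np.interp(u, self._cdf, self._phi)
        return self.lam + self.a * np.tan(phi)


def _standardized_sampler(g1: float, g2: float):
    """Sampler object (with .rvs) for standardized moments (0, 1, g1, g2).

    Requires g1 >= 0; the caller handles mirroring for negative skewness.
    """
    if g1 == 0.0 and g2 == 0.0:
        return stats.norm()
    c0, c1, c2 = _coefficients(g1, g2)
    ptype = pearson_type(g1, g2)

    if ptype in (1, 2):
        # Beta on (a1, a2), roots straddling zero.
        a1, a2 = _quad_roots(c0, c1, c2)
        e1, e2 = _partial_fraction_exponents(c0, c1, c2, a1, a2)
        return stats.beta(e1 + 1.0, e2 + 1.0, loc=a1, scale=a2 - a1)

    if ptype == 3:
        # Linear denominator: u = c0 + c1*x follows a gamma law.
        shape = c0 / c1**2
        return stats.gamma(shape, loc=-c0 / c1, scale=c1**2 / c1)

    if ptype == 5:
        # Double root at w0 = -c1/(2*c2): shifted inverse gamma.
        w0 = -c1 / (2.0 * c2)
        alpha = 1.0 / c2 - 1.0
        beta = -(w0 + c1) / c2
        return stats.invgamma(alpha, loc=w0, scale=beta)

    if ptype == 6:
        # Real roots on the same side of zero; beta-prime on (a2, inf).
        a1, a2 = _quad_roots(c0, c1, c2)
        e1, e2 = _partial_fraction_exponents(c0, c1, c2, a1, a2)
        return stats.betaprime(e2 + 1.0, -e1 - e2 - 1.0, loc=a2, scale=a2 - a1)

    if ptype == 7:
        df = 1.0 / c2 - 1.0
        return stats.t(df, scale=math.sqrt(c0 / (c2 * df)))

    # Type IV: complete the square of the denominator.
    lam = -c1 / (2.0 * c2)
    a = math.sqrt(c0 / c2 - c1**2 / (4.0 * c2**2))
    m = 1.0 / (2.0 * c2)
    nu = (lam + c1) / (c2 * a)
    return _TypeIVSampler(m, nu, lam, a)


@lru_cache(maxsize=128)
def _cached_sampler(g1: float, g2: float):
    return _standardized_sampler(g1, g2)


def pearson_sampler(skewness: float, excess_kurtosis: float):
    """Return a frozen sampler for the standardized (g1 >= 0) member.

    Exposed mainly for inspection and testing; use :func:`sample_pearson` for
    draws with arbitrary mean/sd/skew sign.
    """
    check_feasibility(skewness, excess_kurtosis)
    return _cached_sampler(abs(float(skewness)), float(excess_kurtosis))


def sample_pearson(
    mean: float,
    sd: float,
    skewness: float,
    excess_kurtosis: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` iid variates with the requested first four moments."""
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    sampler = pearson_sampler(skewness, excess_kurtosis)
    if isinstance(sampler, _TypeIVSampler):
        z = sampler.rvs(size=n, random_state=rng)
    else:
        z = np.asarray(sampler.rvs(size=n, random_state=rng), dtype=float)
    if skewness < 0:
        z = -z
    return mean + sd * z
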