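"""Count-model families: negative binomial and double Poisson.

The negative binomial (NB) is parameterised by its mean ``mu`` and
dispersion ``phi`` with ``Var(Y) = mu + mu^2 * phi``; ``phi = 0`` recovers
the Poisson.  It can represent equi- and overdispersed counts but not
underdispersion (variance below the mean).

The double Poisson (DP) is Efron's two-parameter exponential-dispersion
extension of the Poisson.  With mean ``mu`` and dispersion ``theta`` its
variance is ``mu / theta``, so ``theta > 1`` gives underdispersion,
``theta = 1`` the Poisson, and ``0 < theta < 1`` overdispersion.  The
closed-form DP density

    f(y) = sqrt(theta) * exp(-theta*mu) * (exp(-y) y^y / y!) * (e*mu/y)^(theta*y)

does not sum exactly to one; the exact density multiplies it by a
normalising constant ``c(mu, theta)`` that is close to, but not exactly,
one.  Both the closed-form and the renormalised (exact) densities are
exposed, along with a sampler that draws from the exact density by
inverse-CDF over a truncated support.

All likelihood work is done in log space with ``gammaln`` so that counts
up to ~1e6 do not overflow.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

__all__ = [
    "nb_log_pmf",
    "dp_log_pmf",
    "dp_normalizer",
    "nb_moments",
    "dp_moments",
    "dp_support",
    "dp_pmf_vector",
    "dp_sample",
]

# NB phi at or below this is treated as exactly Poisson; beyond the Gamma(1/phi)
# terms lose more precision than the Poisson limit does.
POISSON_PHI_EPS = 1e-10

#: dispersion bounds used throughout the package
NB_PHI_MIN, NB_PHI_MAX = 1e-8, 1e4
DP_THETA_MIN, DP_THETA_MAX = 1e-4, 1e4


def _as_arrays(*args):
    arrs = np.broadcast_arrays(*[np.asarray(a, dtype=float) for a in args])
    return arrs


def _poisson_log_pmf(y, mu):
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = y * np.log(mu) - mu - gammaln(y + 1.0)
    # mu == 0: point mass at zero
    out = np.where(mu == 0.0, np.where(y == 0.0, 0.0, -np.inf), out)
    return out


def nb_log_pmf(y, mu, phi):
    """Log-PMF of the negative binomial with mean ``mu``, dispersion ``phi``.

    ``phi`` below ``POISSON_PHI_EPS`` falls back to the Poisson limit.
    Raises ``ValueError`` for negative counts or negative dispersion.
    """
    y, mu, phi = _as_arrays(y, mu, phi)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(phi < 0):
        raise ValueError("NB dispersion phi must be non-negative")
    if np.any(mu < 0):
        raise ValueError("mean mu must be non-negative")

    pois = _poisson_log_pmf(y, mu)
    phi_safe = np.where(phi <= POISSON_PHI_EPS, 1.0, phi)
    r = 1.0 / phi_safe  # NB size parameter
    with np.errstate(divide="ignore", invalid="ignore"):
        nb = (
            gammaln(y + r)
            - gammaln(y + 1.0)
            - gammaln(r)
            - r * np.log1p(mu * phi_safe)
            + y * (np.log(mu * phi_safe) - np.log1p(mu * phi_safe))
        )
    nb = np.where(mu == 0.0, np.where(y == 0.0, 0.0, -np.inf), nb)
    out = np.where(phi <= POISSON_PHI_EPS, pois, nb)
    return out if out.shape else float(out)


def _dp_log_f(y, mu, theta):
    """Closed-form DP log-density; singular y=0 factors read as 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0)), 0.0)
        # exp(-y) y^y / y!  and  (e*mu/y)^(theta*y), both == 1 at y = 0
        base = -y + ylogy - gammaln(y + 1.0)
        tilt = theta * (np.where(y > 0, y * np.log(mu), 0.0) + y - ylogy)
    out = 0.5 * np.log(theta) - theta * mu + base + tilt
    # degenerate mean: point mass at zero
    out = np.where(mu == 0.0, np.where(y == 0.0, 0.0, -np.inf), out)
    return out


def dp_log_pmf(y, mu, theta, exact=False):
    """Log-PMF of the double Poisson.

    Parameters
    ----------
    y : array_like of non-negative ints
    mu : array_like, mean (>= 0)
    theta : array_like, dispersion (> 0)
    exact : bool
        If True, renormalise by the constant ``c(mu, theta)`` obtained by
        truncated summation so the probabilities sum to one.
    """
    y, mu, theta = _as_arrays(y, mu, theta)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(theta <= 0):
        raise ValueError("DP dispersion theta must be positive")
    if np.any(mu < 0):
        raise ValueError("mean mu must be non-negative")
    out = _dp_log_f(y, mu, theta)
    if exact:
        mus = np.ravel(mu)
        thetas = np.ravel(theta)
        logc = np.empty_like(mus)
        for i, (m, t) in enumerate(zip(mus, thetas)):
            logc[i] = 0.0 if m == 0 else math.log(dp_normalizer(m, t, mode="exact"))
        out = out + logc.reshape(mu.shape)
    return out if out.shape else float(out)


def dp_support(mu, theta):
    """Upper support bound covering > 1 - 1e-10 of DP mass."""
    return int(max(50.0, math.ceil(mu + 20.0 * math.sqrt(mu / theta))))


def dp_normalizer(mu, theta, mode="approx"):
    """Normalising constant ``c(mu, theta)`` of the DP density.

    ``mode='approx'`` uses the closed form
    ``1/c = 1 + (1 - theta) / (12 mu theta) * (1 + 1/(mu theta))``,
    accurate when ``mu * theta`` is not small; ``mode='exact'`` sums the
    closed-form density over a truncated support.
    """
    if mu <= 0:
        raise ValueError("normalizer undefined for mu <= 0")
    if theta <= 0:
        raise ValueError("DP dispersion theta must be positive")
    if mode == "approx":
        inv_c = 1.0 + (1.0 - theta) / (12.0 * mu * theta) * (1.0 + 1.0 / (mu * theta))
        if inv_c <= 0:
            raise ValueError(
                f"approximate normalizer invalid at mu={mu}, theta={theta}; use mode='exact'"
            )
        return 1.0 / inv_c
    if mode == "exact":
        ymax = dp_support(mu, theta)
        y = np.arange(ymax + 1, dtype=float)
        total = float(np.exp(_dp_log_f(y, mu, theta)).sum())
        if not np.isfinite(total) or total <= 0:
            raise FloatingPointError("DP normalizer summation failed")
        return 1.0 / total
    raise ValueError(f"unknown mode {mode!r}")


def nb_moments(mu, phi):
    """(mean, variance) of NB(mu, phi): variance = mu + mu^2 phi."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("NB dispersion phi must be non-negative")
    var = mu + mu**2 * phi
    return (float(mu), float(var)) if mu.shape == () else (mu, var)


def dp_moments(mu, theta):
    """(mean, variance) of DP(mu, theta): variance = mu / theta."""
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("DP dispersion theta must be positive")
    var = mu / theta
    return (float(mu), float(var)) if mu.shape == () else (mu, var)


def dp_pmf_vector(mu, theta, tail=1e-10):
    """Exact DP probabilities on ``0..ymax``, truncated where the
    cumulative mass exceeds ``1 - tail``."""
    if mu == 0:
        return np.array([1.0])
    ymax = dp_support(mu, theta)
    y = np.arange(ymax + 1, dtype=float)
    f = np.exp(_dp_log_f(y, mu, theta))
    total = f.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("DP pmf summation failed")
    p = f / total
    cum = np.cumsum(p)
    cut = int(np.searchsorted(cum, 1.0 - tail)) + 1
    return p[:cut]


def dp_sample(mu, theta, size, rng):
    """Draw ``size`` i.i.d. counts from the exact DP(mu, theta) density.

    Inverse-CDF over the truncated support; ``rng`` is a seed or a
    ``numpy.random.Generator``.  Same seed gives identical output.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(rng)
    p = dp_pmf_vector(mu, theta)
    cdf = np.cumsum(p)
    u = rng.random(size)
    return np.searchsorted(cdf, u, side="right").astype(np.int64)
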