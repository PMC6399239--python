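"""Discrete heavy-tailed distributions on the integers ``k >= k_min``.

The tail model at the core of the package is the discrete power law

    Pr(k) = k^(-alpha) / zeta(alpha, k_min),    alpha > 1,  k >= k_min >= 1,

where ``zeta(s, a)`` is the Hurwitz zeta function (the generalized harmonic
normalizer).  The four alternative families — exponential, log-normal,
Weibull (stretched exponential) and power law with exponential cutoff — are
defined directly on the integers by normalizing their continuous density
kernels through summation over ``k >= k_min``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, special

__all__ = [
    "FAMILIES",
    "hurwitz_zeta",
    "log_hurwitz_zeta",
    "powerlaw_pmf",
    "powerlaw_logpmf",
    "powerlaw_cdf",
    "powerlaw_sf",
    "sample_powerlaw",
    "alt_log_kernel",
    "alt_log_normalizer",
    "alt_pmf",
    "alt_logpmf",
    "sample_alternative",
]

FAMILIES = ("exponential", "lognormal", "weibull", "powerlaw_cutoff")

_TAIL_TOL = 1e-12


def hurwitz_zeta(s: float, a: float) -> float:
    """Hurwitz zeta ``sum_{j>=0} (a+j)^(-s)`` for s > 1, a > 0."""
    if np.any(np.asarray(s) <= 1.0):
        raise ValueError("hurwitz_zeta requires s > 1")
    return special.zeta(s, a)


def log_hurwitz_zeta(s: float, a) -> np.ndarray:
    """``log zeta(s, a)``, stable where ``a^(-s)`` underflows.

    For large ``s`` the sum is dominated by its first term, so
    ``log zeta = -s log a + log(1 + sum_j (a/(a+j))^s)`` with a rapidly
    converging correction series.
    """
    scalar = np.isscalar(a) or np.ndim(a) == 0
    a = np.atleast_1d(np.asarray(a, dtype=float))
    with np.errstate(divide="ignore"):
        z = special.zeta(s, a)
        out = np.where(z > 0, np.log(np.where(z > 0, z, 1.0)), -np.inf)
    bad = ~np.isfinite(out)
    if np.any(bad):
        ab = a[bad]
        j = np.arange(1, 400, dtype=float)
        corr = np.log1p(((ab[:, None] / (ab[:, None] + j)) ** s).sum(axis=1))
        out[bad] = -s * np.log(ab) + corr
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Discrete power law
# ---------------------------------------------------------------------------


def _check_powerlaw(alpha: float, k_min: int) -> None:
    if alpha <= 1.0:
        raise ValueError(f"power law requires alpha > 1, got {alpha}")
    if k_min < 1:
        raise ValueError(f"power law requires k_min >= 1, got {k_min}")


def powerlaw_logpmf(k, alpha: float, k_min: int):
    """Log pmf of the discrete power law at integer ``k >= k_min``."""
    _check_powerlaw(alpha, k_min)
    k = np.asarray(k, dtype=float)
    return -alpha * np.log(k) - log_hurwitz_zeta(alpha, k_min)


def powerlaw_pmf(k, alpha: float, k_min: int):
    """``Pr(K = k) = k^(-alpha) / zeta(alpha, k_min)``."""
    return np.exp(powerlaw_logpmf(k, alpha, k_min))


def powerlaw_sf(k, alpha: float, k_min: int):
    """Survival ``Pr(K > k) = zeta(alpha, k+1) / zeta(alpha, k_min)``."""
    _check_powerlaw(alpha, k_min)
    k = np.asarray(k, dtype=float)
    return np.exp(log_hurwitz_zeta(alpha, k + 1.0) - log_hurwitz_zeta(alpha, k_min))


def powerlaw_cdf(k, alpha: float, k_min: int):
    """``Pr(K <= k)`` for integer k >= k_min."""
    return 1.0 - powerlaw_sf(k, alpha, k_min)


def sample_powerlaw(
    n: int,
    alpha: float,
    k_min: int,
    rng: np.random.Generator,
    table_cap: int = 100_000,
) -> np.ndarray:
    """Draw ``n`` iid integers from the discrete power law.

    Inverse-CDF on a precomputed cumulative table up to ``k_min + table_cap``;
    the rare draws falling beyond the table are inverted exactly by bisection
    on the zeta survival function.
    """
    _check_powerlaw(alpha, k_min)
    ks = np.arange(k_min, k_min + table_cap, dtype=float)
    pmf = np.exp(-alpha * np.log(ks)) / special.zeta(alpha, k_min)
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="left")
    out = k_min + idx
    beyond = idx >= table_cap
    if np.any(beyond):
        z0 = special.zeta(alpha, k_min)
        for i in np.nonzero(beyond)[0]:
            target = 1.0 - u[i]  # survival level, Pr(K > k) <= target
            lo = k_min + table_cap  # sf(lo-1) > target
            hi = lo
            while special.zeta(alpha, hi + 1.0) / z0 > target:
                hi *= 2
            while hi > lo:
                mid = (lo + hi) // 2
                if special.zeta(alpha, mid + 1.0) / z0 > target:
                    lo = mid + 1
                else:
                    hi = mid
            out[i] = lo
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# Alternative families (Table-style kernels, normalized by summation)
# ---------------------------------------------------------------------------


def _check_alt_params(family: str, params) -> tuple:
    params = tuple(float(p) for p in np.atleast_1d(params))
    if family == "exponential":
        (lam,) = params
        if lam <= 0:
            raise ValueError("exponential requires lambda > 0")
    elif family == "lognormal":
        mu, sigma = params
        if sigma <= 0:
            raise ValueError("lognormal requires sigma > 0")
    elif family == "weibull":
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError("weibull requires a > 0 and b > 0")
    elif family == "powerlaw_cutoff":
        alpha, lam = params
        if lam < 0:
            raise ValueError("cutoff requires lambda >= 0")
        if lam == 0 and alpha <= 1:
            raise ValueError("cutoff with lambda = 0 requires alpha > 1")
    else:
        raise ValueError(f"unknown family {family!r}")
    return params


def alt_log_kernel(k, family: str, params):
    """Log of the unnormalized density kernel evaluated at ``k``."""
    k = np.asarray(k, dtype=float)
    if family == "exponential":
        (lam,) = params
        return -lam * k
    if family == "lognormal":
        mu, sigma = params
        return -np.log(k) - (np.log(k) - mu) ** 2 / (2.0 * sigma**2)
    if family == "weibull":
        a, b = params
        return -((k / b) ** a)
    if family == "powerlaw_cutoff":
        alpha, lam = params
        return -alpha * np.log(k) - lam * k
    raise ValueError(f"unknown family {family!r}")


def _tail_integral(x0: float, family: str, params) -> float:
    """Closed-form ``integral_{x0}^inf`` of the continuous kernel.

    Used as the Euler–Maclaurin-style correction for the summation remainder
    ``sum_{k > K} kernel(k) ~ integral_{K+1/2}^inf kernel(x) dx``.
    """
    if family == "lognormal":
        mu, sigma = params
        # substitute t = (ln x - mu)/sigma
        return sigma * np.sqrt(2 * np.pi) * special.ndtr(-(np.log(x0) - mu) / sigma)
    if family == "weibull":
        a, b = params
        z = (x0 / b) ** a
        # (b/a) * Gamma(1/a, z), upper incomplete
        return (b / a) * special.gammaincc(1.0 / a, z) * special.gamma(1.0 / a)
    return 0.0


def alt_log_normalizer(family: str, params, k_min: int) -> float:
    """``log Z`` with ``Z = sum_{k >= k_min} kernel(k)``."""
    params = _check_alt_params(family, params)
    if k_min < 1:
        raise ValueError("k_min must be >= 1")

    if family == "exponential":
        (lam,) = params
        # shifted geometric: Z = e^(-lam*k_min) / (1 - e^(-lam))
        return -lam * k_min - np.log(-np.expm1(-lam))

    if family == "powerlaw_cutoff":
        alpha, lam = params
        if lam == 0.0:
            return float(log_hurwitz_zeta(alpha, k_min))
        # exact sum over a window + adaptive-quadrature tail (midpoint
        # Euler–Maclaurin); the integral is split at the kernel mode when
        # -alpha/lam lies beyond the window so quad never misses the peak
        ks = np.arange(k_min, k_min + 2048, dtype=float)
        logt = alt_log_kernel(ks, family, params)
        log_scale = float(logt.max())
        x0 = ks[-1] + 0.5
        mode = -alpha / lam if alpha < 0 else 0.0
        if mode > x0:
            log_scale = max(log_scale, -alpha * np.log(mode) - lam * mode)
        total = float(np.exp(logt - log_scale).sum())
        f = lambda x: np.exp(-alpha * np.log(x) - lam * x - log_scale)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            if mode > x0:
                t1 = integrate.quad(f, x0, 10 * mode, points=[mode], limit=200)[0]
                t2 = integrate.quad(f, 10 * mode, np.inf, limit=200)[0]
                tail = t1 + t2
            else:
                tail = integrate.quad(f, x0, np.inf, limit=200)[0]
        return log_scale + float(np.log(total + tail))

    # lognormal / weibull: exact sum over a finite window + integral tail
    if family == "lognormal":
        mu, sigma = params
        mode_hint = np.exp(mu)
    else:
        a, b = params
        mode_hint = b
    cap = int(min(2_000_000, max(k_min + 5_000, 5 * mode_hint)))
    ks = np.arange(k_min, cap + 1, dtype=float)
    logt = alt_log_kernel(ks, family, params)
    log_scale = float(logt.max())
    log_window = log_scale + float(np.log(np.exp(logt - log_scale).sum()))
    ti = _tail_integral(cap + 0.5, family, params)
    if ti <= 0.0:
        return log_window
    return float(np.logaddexp(log_window, np.log(ti)))


def alt_logpmf(k, family: str, params, k_min: int):
    params = _check_alt_params(family, params)
    return alt_log_kernel(k, family, params) - alt_log_normalizer(family, params, k_min)


def alt_pmf(k, family: str, params, k_min: int):
    """Normalized discrete pmf of an alternative family at integer ``k``."""
    return np.exp(alt_logpmf(k, family, params, k_min))


def sample_alternative(
    n: int,
    family: str,
    params,
    k_min: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` iid integers from a discretized alternative family.

    Inverse-CDF on a cumulative table extended until the residual mass is
    below 1e-12 (the residual is assigned to the last table entry).
    """
    params = _check_alt_params(family, params)
    logZ = alt_log_normalizer(family, params, k_min)
    blocks = []
    start = k_min
    chunk = 65_536
    mass = 0.0
    for _ in range(64):
        ks = np.arange(start, start + chunk, dtype=float)
        p = np.exp(alt_log_kernel(ks, family, params) - logZ)
        blocks.append(p)
        mass += p.sum()
        start += chunk
        if 1.0 - mass < 1e-12:
            break
    pmf = np.concatenate(blocks)
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    idx = np.minimum(np.searchsorted(cdf, u, side="left"), len(cdf) - 1)
    return (k_min + idx).astype(np.int64)
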