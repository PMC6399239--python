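"""Maximum-likelihood fits of the alternative degree distributions.

The four alternatives to the power law — exponential, log-normal, Weibull
(stretched exponential), and power law with exponential cutoff — are fitted
on exactly the same tail ``k >= k_min`` selected by the power-law fit, so
that log-likelihoods are directly comparable.  Reusing the power law's
``k_min`` slightly biases comparisons in the power law's favor, which is the
conservative direction for testing the scale-free hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .distributions import (
    FAMILIES,
    alt_log_kernel,
    alt_log_normalizer,
)
from .powerlaw import _as_degrees, mle_alpha

__all__ = ["AltFit", "FitFailure", "fit_alternative", "tail_loglik"]


class FitFailure(RuntimeError):
    """Optimizer failed to converge from every start."""


@dataclass(frozen=True)
class AltFit:
    """One fitted alternative family on the shared tail.

    ``params`` holds the family-specific parameters:
    exponential ``(lambda,)``; lognormal ``(mu, sigma)``; weibull ``(a, b)``;
    powerlaw_cutoff ``(alpha, lambda)``.
    """

    family: str
    params: tuple
    log_likelihood: float
    k_min: int
    n_tail: int
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.params)

    def logpmf(self, k):
        return alt_log_kernel(k, self.family, self.params) - alt_log_normalizer(
            self.family, self.params, self.k_min
        )


def tail_loglik(tail: np.ndarray, family: str, params, k_min: int) -> float:
    """Tail log-likelihood ``sum_i log pmf(k_i)`` for an alternative family."""
    kern = float(np.sum(alt_log_kernel(tail, family, params)))
    return kern - tail.size * alt_log_normalizer(family, params, k_min)


# parameter boxes; identifiable ranges for discrete degree data
_BOUNDS = {
    "lognormal": [(-30.0, 30.0), (1e-3, 25.0)],
    "weibull": [(0.05, 20.0), (1e-3, 1e6)],
    "powerlaw_cutoff": [(-5.0, 12.0), (1e-6, 60.0)],
}


def _starts(family: str, tail: np.ndarray, k_min: int) -> list[np.ndarray]:
    """Five deterministic starts: moment-matched plus dispersed."""
    logk = np.log(tail)
    m, s = float(logk.mean()), float(max(logk.std(), 0.05))
    kbar = float(tail.mean())
    if family == "lognormal":
        return [np.array(p) for p in (
            (m, s), (m, 2 * s), (m - 1.0, s), (m + 1.0, 0.5 * s), (0.0, 1.0),
        )]
    if family == "weibull":
        return [np.array(p) for p in (
            (1.0, kbar), (0.5, kbar), (2.0, kbar), (0.2, max(kbar - k_min, 0.5)),
            (1.0, 2 * kbar),
        )]
    if family == "powerlaw_cutoff":
        try:
            a0 = mle_alpha(tail, k_min)[0]
        except Exception:
            a0 = 2.0
        return [np.array(p) for p in (
            (a0, 1.0 / kbar), (a0 - 1.0, 1.0 / kbar), (1.0, 0.1),
            (0.0, 1.0 / kbar), (a0, 1e-3),
        )]
    raise ValueError(family)


def _clip(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def fit_alternative(seq, k_min: int, family: str) -> AltFit:
    """ML fit of ``family`` on the degrees ``k >= k_min`` of ``seq``.

    Two-parameter families use multi-start Nelder–Mead (five deterministic
    starts); the exponential MLE is closed-form (shifted geometric).  The
    cutoff family additionally evaluates the pure power-law boundary
    ``lambda = 0`` so its likelihood can never fall below the power law's.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    degrees = _as_degrees(seq)
    tail = np.sort(degrees[degrees >= k_min])
    min_n = 2 if family == "exponential" else 3
    if tail.size < min_n:
        raise ValueError(f"{family} fit needs >= {min_n} tail values")

    if family == "exponential":
        # pmf(k) = (1 - e^-lam) e^(-lam (k - k_min)): shifted geometric
        m = float(tail.mean() - k_min)
        if m <= 0:  # all mass at k_min
            lam = 50.0
        else:
            lam = float(np.log1p(1.0 / m))
        ll = tail_loglik(tail, family, (lam,), k_min)
        return AltFit(family, (lam,), ll, int(k_min), tail.size)

    bounds = _BOUNDS[family]

    def neg(x):
        p = tuple(_clip(np.asarray(x, dtype=float), bounds))
        try:
            return -tail_loglik(tail, family, p, k_min)
        except (ValueError, FloatingPointError, RuntimeError):
            return np.inf

    best = None
    for x0 in _starts(family, tail, k_min):
        res = optimize.minimize(
            neg, _clip(x0, bounds), method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 300},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitFailure(f"{family} fit failed from all starts")

    params = tuple(float(v) for v in _clip(best.x, bounds))
    ll = -float(best.fun)
    converged = bool(best.success)

    if family == "powerlaw_cutoff":
        # nested boundary: pure power law (lambda = 0) with its own MLE
        try:
            a_pl, ll_pl = mle_alpha(tail, k_min)
            if ll_pl >= ll:
                params, ll, converged = (a_pl, 0.0), ll_pl, True
        except Exception:
            pass

    return AltFit(family, params, ll, int(k_min), tail.size, converged)
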