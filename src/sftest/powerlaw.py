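"""Discrete power-law tail fitting.

Fits ``Pr(k) = C k^(-alpha)`` to the upper tail ``k >= k_min`` of a degree
sequence, choosing ``k_min`` by Kolmogorov–Smirnov minimization and ``alpha``
by discrete maximum likelihood on the truncated data.  The model object /
results object pair follows the statsmodels convention: build ``PowerLaw``
from data, call :meth:`PowerLaw.fit`, and work with the returned
:class:`PowerLawResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .distributions import (
    log_hurwitz_zeta,
    powerlaw_cdf,
    powerlaw_logpmf,
    sample_powerlaw,
)

__all__ = [
    "DegenerateTailError",
    "UnfittableSequenceError",
    "PowerLaw",
    "PowerLawResults",
    "mle_alpha",
    "ks_distance",
    "fit_power_law",
]

ALPHA_MIN = 1.0 + 1e-6
ALPHA_MAX = 12.0
ALPHA_TOL = 1e-6  # bracket tolerance; well inside the 1e-4 contract


class DegenerateTailError(ValueError):
    """Tail has a single distinct value: the likelihood is unbounded in alpha."""


class UnfittableSequenceError(ValueError):
    """No k_min candidate leaves at least two distinct tail values."""


def _as_degrees(seq) -> np.ndarray:
    degrees = np.asarray(getattr(seq, "degrees", seq))
    if degrees.ndim != 1 or degrees.size == 0:
        raise ValueError("degree sequence must be a non-empty 1-d array")
    if np.any(degrees < 0) or not np.issubdtype(degrees.dtype, np.integer):
        degrees = degrees.astype(np.int64)
        if np.any(degrees < 0):
            raise ValueError("degrees must be non-negative integers")
    return degrees


def _tail_loglik(alpha: float, n_tail: int, sum_log: float, k_min: int) -> float:
    z = special.zeta(alpha, k_min)
    if 0.0 < z < np.inf:  # fast path; falls back when k_min^(-alpha) underflows
        lz = np.log(z)
    else:
        lz = log_hurwitz_zeta(alpha, k_min)
    return -n_tail * lz - alpha * sum_log


def mle_alpha(seq, k_min: int) -> tuple[float, float]:
    """Discrete ML estimate of alpha on the tail ``k >= k_min``.

    Returns ``(alpha_hat, log_likelihood)``.  Raises
    :class:`DegenerateTailError` when the tail holds fewer than two distinct
    values (the likelihood then increases without bound in alpha).
    """
    degrees = _as_degrees(seq)
    tail = degrees[degrees >= k_min]
    if len(np.unique(tail)) < 2:
        raise DegenerateTailError(
            f"tail k >= {k_min} needs >= 2 distinct degree values"
        )
    n_tail = tail.size
    sum_log = float(np.log(tail).sum())
    neg = lambda a: -_tail_loglik(a, n_tail, sum_log, k_min)
    res = optimize.minimize_scalar(
        neg, bounds=(ALPHA_MIN, ALPHA_MAX), method="bounded",
        options={"xatol": ALPHA_TOL},
    )
    # the ceiling is deliberate: exponents at the bound describe tails
    # steeper than any power law of practical interest, and letting alpha
    # grow without limit would allow the model to mimic arbitrary
    # log-concave tail slices
    if res.x > ALPHA_MAX - 10 * ALPHA_TOL:
        x = ALPHA_MAX
        return float(x), float(_tail_loglik(x, n_tail, sum_log, k_min))
    return float(res.x), float(-res.fun)


def ks_distance(seq, k_min: int, alpha: float) -> float:
    """KS distance between the tail ECDF and the fitted model CDF.

    Both distributions are conditioned on ``k >= k_min``; the maximum is
    taken over the observed tail support.
    """
    degrees = _as_degrees(seq)
    tail = degrees[degrees >= k_min]
    if tail.size == 0:
        raise ValueError("empty tail")
    values, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / tail.size
    mcdf = powerlaw_cdf(values, alpha, k_min)
    return float(np.max(np.abs(ecdf - mcdf)))


@dataclass(frozen=True)
class PowerLawResults:
    """Fitted discrete power-law tail model.

    Attributes
    ----------
    k_min : selected start of the power-law region
    alpha : ML scaling exponent on ``k >= k_min``
    n_tail : number of observations in the tail
    ks : KS distance of the selected fit
    log_likelihood : tail log-likelihood at ``(k_min, alpha)``
    """

    k_min: int
    alpha: float
    n_tail: int
    ks: float
    log_likelihood: float
    n: int
    degrees: np.ndarray = field(repr=False, compare=False)

    @property
    def C(self) -> float:
        """Normalization constant ``1 / zeta(alpha, k_min)``."""
        return float(1.0 / special.zeta(self.alpha, self.k_min))

    @property
    def tail(self) -> np.ndarray:
        """The degrees the tail model was fitted to (``k >= k_min``)."""
        return self.degrees[self.degrees >= self.k_min]

    @property
    def body(self) -> np.ndarray:
        """Degrees below ``k_min`` (kept for the semi-parametric bootstrap)."""
        return self.degrees[self.degrees < self.k_min]

    def logpmf(self, k):
        return powerlaw_logpmf(k, self.alpha, self.k_min)

    def simulate(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Semi-parametric resample of the full sequence (see :mod:`sftest.gof`)."""
        from .gof import semiparametric_resample

        return semiparametric_resample(self.degrees, self, rng, size=size)

    def gof(self, n_boot: int = 1000, seed=None):
        from .gof import gof_pvalue

        return gof_pvalue(self.degrees, self, n_boot=n_boot, seed=seed)

    def compare(self, families=None, method: str = "lrt"):
        from .alternatives import fit_alternative
        from .comparisons import compare_all
        from .distributions import FAMILIES

        alts = [
            fit_alternative(self.degrees, self.k_min, fam)
            for fam in (families or FAMILIES)
        ]
        return compare_all(self.tail, self, alts, method=method)

    def summary(self) -> str:
        lines = [
            "Discrete power-law tail fit",
            "===========================",
            f"n (sequence)     {self.n:>10d}",
            f"k_min            {self.k_min:>10d}",
            f"alpha            {self.alpha:>10.4f}",
            f"n_tail           {self.n_tail:>10d}",
            f"KS distance      {self.ks:>10.4f}",
            f"log-likelihood   {self.log_likelihood:>10.3f}",
            f"C                {self.C:>10.6f}",
        ]
        return "\n".join(lines)


class PowerLaw:
    """Discrete power-law tail model for a degree sequence.

    Parameters
    ----------
    degrees : sequence of non-negative integers (or a DegreeSequence).

    Examples
    --------
    >>> rng = np.random.default_rng(0)
    >>> k = sample_powerlaw(2000, 2.5, 1, rng)
    >>> res = PowerLaw(k).fit()
    >>> 2.3 < res.alpha < 2.7
    True
    """

    def __init__(self, degrees):
        self.degrees = _as_degrees(degrees)
        self.n = self.degrees.size

    def loglike(self, alpha: float, k_min: int) -> float:
        tail = self.degrees[self.degrees >= k_min]
        return _tail_loglik(alpha, tail.size, float(np.log(tail).sum()), k_min)

    def fit(self, k_min: int | None = None) -> PowerLawResults:
        """Fit by KS-minimization over ``k_min`` (or at a fixed ``k_min``).

        Every distinct observed degree value whose tail keeps at least two
        distinct values is a candidate; for each, alpha is the tail MLE and
        the KS distance is evaluated at that alpha.  The fit with minimal KS
        distance wins; ties break toward smaller ``k_min``.
        """
        degrees = self.degrees
        if k_min is not None:
            alpha, ll = mle_alpha(degrees, k_min)
            ks = ks_distance(degrees, k_min, alpha)
            n_tail = int((degrees >= k_min).sum())
            return PowerLawResults(int(k_min), alpha, n_tail, ks, ll,
                                   self.n, degrees)

        values = np.unique(degrees)
        values = values[values >= 1]
        # need >= 2 distinct values in the tail: drop the largest value
        candidates = values[:-1] if values.size >= 2 else values[:0]
        best: PowerLawResults | None = None
        sorted_deg = np.sort(degrees)
        for km in candidates:
            km = int(km)
            try:
                alpha, ll = mle_alpha(sorted_deg, km)
            except DegenerateTailError:
                continue
            ks = ks_distance(sorted_deg, km, alpha)
            if best is None or ks < best.ks - 1e-12:
                n_tail = int((degrees >= km).sum())
                best = PowerLawResults(km, alpha, n_tail, float(ks), ll,
                                       self.n, degrees)
        if best is None:
            raise UnfittableSequenceError(
                "no k_min candidate leaves >= 2 distinct tail values"
            )
        return best


def fit_power_law(seq, k_min: int | None = None) -> PowerLawResults:
    """Functional wrapper around ``PowerLaw(seq).fit(k_min)``."""
    return PowerLaw(_as_degrees(seq)).fit(k_min=k_min)
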