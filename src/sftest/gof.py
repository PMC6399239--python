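"""Semi-parametric bootstrap goodness-of-fit test for the power-law tail.

Each bootstrap replicate draws a synthetic degree sequence of the original
size: with probability ``n_tail / n`` a value comes from the fitted discrete
power law (``k >= k_min``), otherwise it is resampled uniformly with
replacement from the observed degrees below ``k_min``.  The full fitting
procedure (k_min scan + MLE) is re-run on every replicate and the p-value is
the fraction of bootstrap KS distances at least as large as the observed one.
A sequence with ``p >= 0.1`` is deemed plausibly scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import sample_powerlaw
from .powerlaw import PowerLaw, PowerLawResults, UnfittableSequenceError, _as_degrees

__all__ = ["GofResult", "semiparametric_resample", "gof_pvalue", "PLAUSIBLE_P"]

PLAUSIBLE_P = 0.1


@dataclass(frozen=True)
class GofResult:
    p_value: float
    n_boot: int
    observed_ks: float
    plausible: bool
    n_regenerated: int = 0

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0


def semiparametric_resample(
    seq,
    fit: PowerLawResults,
    rng: np.random.Generator | int | None,
    size: int | None = None,
) -> np.ndarray:
    """One synthetic degree sequence from the fitted semi-parametric model."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    degrees = _as_degrees(seq)
    n = size if size is not None else degrees.size
    body = degrees[degrees < fit.k_min]
    p_tail = fit.n_tail / degrees.size
    from_tail = rng.random(n) < p_tail
    n_t = int(from_tail.sum())
    out = np.empty(n, dtype=np.int64)
    if n_t:
        out[from_tail] = sample_powerlaw(n_t, fit.alpha, fit.k_min, rng)
    if n - n_t:
        out[~from_tail] = rng.choice(body, size=n - n_t, replace=True)
    return out


def gof_pvalue(
    seq,
    fit: PowerLawResults,
    n_boot: int = 1000,
    seed=None,
    max_regenerate: int = 100,
) -> GofResult:
    """Bootstrap p-value for the plausibility of the fitted power law.

    Unfittable resamples (no valid ``k_min`` candidate) are regenerated from
    the next random substream; the count is reported on the result.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    degrees = _as_degrees(seq)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # one substream per replicate plus a reserve pool for regeneration
    streams = ss.spawn(n_boot + max_regenerate)
    ks_boot = np.empty(n_boot)
    regenerated = 0
    reserve = n_boot
    for i in range(n_boot):
        stream = streams[i]
        while True:
            rng = np.random.default_rng(stream)
            synth = semiparametric_resample(degrees, fit, rng)
            try:
                ks_boot[i] = PowerLaw(synth).fit().ks
                break
            except UnfittableSequenceError:
                regenerated += 1
                if reserve >= len(streams):
                    raise
                stream = streams[reserve]
                reserve += 1
    p = float(np.mean(ks_boot >= fit.ks))
    return GofResult(p, n_boot, fit.ks, p >= PLAUSIBLE_P, regenerated)
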