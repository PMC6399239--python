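"""Model comparisons: Vuong normalized LRT, nested LRT, information criteria.

For non-nested alternatives (exponential, log-normal, Weibull) the Vuong
test normalizes the log-likelihood ratio ``R = L_PL - L_Alt`` by the sample
standard deviation of the pointwise ratios; the statistic is asymptotically
standard normal when the models are equally close to the truth.  The cutoff
family contains the pure power law (``lambda = 0``), so ``R <= 0`` always
and significance is judged by ``-2R`` against a one-degree-of-freedom
chi-squared distribution.  In both cases ``p >= 0.1`` reads as inconclusive;
no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alternatives import AltFit
from .powerlaw import PowerLawResults

__all__ = [
    "ComparisonResult",
    "vuong_lrt",
    "nested_lrt",
    "ic_compare",
    "compare_all",
    "LRT_P_THRESHOLD",
]

LRT_P_THRESHOLD = 0.1
_IC_TIE_BAND = 2.0


@dataclass(frozen=True)
class ComparisonResult:
    family: str
    R: float
    p_value: float
    verdict: str  # favors_powerlaw | favors_alternative | inconclusive
    nested: bool
    degenerate: bool = False
    method: str = "lrt"

    def __post_init__(self):
        assert self.verdict in ("favors_powerlaw", "favors_alternative", "inconclusive")


def _verdict(R: float, p: float) -> str:
    if p >= LRT_P_THRESHOLD or R == 0.0:
        return "inconclusive"
    return "favors_powerlaw" if R > 0 else "favors_alternative"


def _tail_of(tail) -> np.ndarray:
    return np.asarray(getattr(tail, "degrees_tail", tail))


def vuong_lrt(tail, fit: PowerLawResults, alt: AltFit) -> ComparisonResult:
    """Vuong normalized likelihood-ratio test for a non-nested alternative."""
    if alt.family == "powerlaw_cutoff":
        raise ValueError("cutoff family is nested; use nested_lrt")
    k = _tail_of(tail)
    li = np.asarray(fit.logpmf(k)) - np.asarray(alt.logpmf(k))
    R = float(li.sum())
    n = li.size
    sigma = float(li.std(ddof=1))
    if sigma == 0.0:
        return ComparisonResult(alt.family, R, 1.0, "inconclusive", False,
                                degenerate=True)
    z = R / (sigma * np.sqrt(n))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(alt.family, R, p, _verdict(R, p), False)


def nested_lrt(tail, fit: PowerLawResults, cutoff: AltFit) -> ComparisonResult:
    """LRT against the nested power-law-with-cutoff alternative.

    ``R = L_PL - L_cutoff <= 0`` by nesting; ``-2R`` is referred to a
    chi-squared distribution with one degree of freedom.  The power law can
    never be favored here — the interesting outcome is inconclusiveness.
    """
    if cutoff.family != "powerlaw_cutoff":
        raise ValueError("nested_lrt requires the cutoff family")
    R = float(fit.log_likelihood - cutoff.log_likelihood)
    if R > 1e-8:
        raise RuntimeError(
            f"nesting violated: L_PL exceeds L_cutoff by {R:g}"
        )
    R = min(R, 0.0)
    p = float(stats.chi2.sf(-2.0 * R, df=1))
    verdict = "favors_alternative" if p < LRT_P_THRESHOLD else "inconclusive"
    return ComparisonResult("powerlaw_cutoff", R, p, verdict, True)


def ic_compare(tail, fit: PowerLawResults, alt: AltFit,
               corrected: bool | None = None) -> ComparisonResult:
    """Information-criterion comparison (likelihood penalized by parameters).

    Uses ``2p - 2L`` per model, with the small-sample correction
    ``2p(p+1)/(n-p-1)`` added when ``n/p < 40`` (or as forced by
    ``corrected``).  A difference inside the tie band ``|Delta| < 2`` is
    inconclusive; otherwise the lower criterion wins.
    """
    n = _tail_of(tail).size

    def crit(ll: float, p: int) -> float:
        c = 2.0 * p - 2.0 * ll
        use_corr = corrected if corrected is not None else (n / p < 40)
        if use_corr and n - p - 1 > 0:
            c += 2.0 * p * (p + 1) / (n - p - 1)
        return c

    c_pl = crit(fit.log_likelihood, 2)  # (k_min, alpha)
    c_alt = crit(alt.log_likelihood, 1 + alt.n_params)  # k_min inherited
    delta = c_alt - c_pl  # positive favors the power law
    R = float(fit.log_likelihood - alt.log_likelihood)
    nested = alt.family == "powerlaw_cutoff"
    if abs(delta) < _IC_TIE_BAND:
        verdict = "inconclusive"
    elif delta > 0:
        verdict = "favors_powerlaw"
    else:
        verdict = "favors_alternative"
    # report |Delta| mapped onto [0, 1] as a pseudo p so the 0.1 rule is moot
    p = 1.0 if verdict == "inconclusive" else 0.0
    return ComparisonResult(alt.family, R, p, verdict, nested, method="ic")


def compare_all(tail, fit: PowerLawResults, alt_fits, method: str = "lrt"):
    """One comparison per fitted alternative, routed by nesting.

    A family whose comparison raises is reported as a degenerate
    inconclusive result rather than aborting the remaining families.
    """
    out = []
    for alt in alt_fits:
        try:
            if method == "ic":
                out.append(ic_compare(tail, fit, alt))
            elif alt.family == "powerlaw_cutoff":
                out.append(nested_lrt(tail, fit, alt))
            else:
                out.append(vuong_lrt(tail, fit, alt))
        except Exception:
            out.append(ComparisonResult(
                alt.family, 0.0, 1.0, "inconclusive",
                alt.family == "powerlaw_cutoff", degenerate=True, method=method,
            ))
    return out
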